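"""A small, self-contained LSTM sequence regressor in NumPy.

Implements exactly what the forecaster needs: a stacked LSTM with dropout
between layers and a linear head, trained by backpropagation through time
with Adam (coupled L2 weight decay), per-timestep loss masks/weights,
gradient clipping and early stopping on validation MSE. Sized for
CPU-scale clinical cohorts (thousands of patient-days), not GPU workloads.

Gate order in the packed weight matrices is (input, forget, cell, output);
forget-gate biases are initialized to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrainingHistory:
    train_loss: list
    val_loss: list
    best_epoch: int
    best_val_loss: float


class SequenceRegressor:
    """Stacked-LSTM many-to-many regressor with a scalar output per step.

    The prediction at step ``t`` depends only on inputs at steps ``<= t``
    (strict causality by construction of the recurrence).
    """

    def __init__(self, input_size: int, hidden_size: int = 48, n_layers: int = 2,
                 dropout: float = 0.1, seed: int = 0):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        H = hidden_size
        k = 1.0 / math.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        for l in range(n_layers):
            d_in = input_size if l == 0 else H
            self.params[f"W{l}"] = rng.uniform(-k, k, size=(d_in, 4 * H))
            self.params[f"U{l}"] = rng.uniform(-k, k, size=(H, 4 * H))
            b = rng.uniform(-k, k, size=4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
        self.params["w_out"] = rng.uniform(-k, k, size=(H, 1))
        self.params["b_out"] = np.zeros(1)

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        """X: (B, T, F) -> predictions (B, T); returns (yhat, cache)."""
        B, T, _ = X.shape
        H = self.hidden_size
        cache: dict = {"X": X, "layers": [], "drop": []}
        inp = X
        for l in range(self.n_layers):
            W, U, b = self.params[f"W{l}"], self.params[f"U{l}"], self.params[f"b{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            gates, cells, hiddens, tanhc = [], [], [], []
            for t in range(T):
                z = inp[:, t] @ W + h @ U + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                gates.append((i, f, g, o))
                cells.append(c)
                tanhc.append(tc)
                hiddens.append(h)
            Hseq = np.stack(hiddens, axis=1)  # (B, T, H)
            cache["layers"].append({"inp": inp, "gates": gates, "cells": cells,
                                    "tanhc": tanhc, "H": Hseq})
            out = Hseq
            if train and self.dropout > 0 and l < self.n_layers - 1:
                keep = 1.0 - self.dropout
                m = (rng.random(out.shape) < keep) / keep
                out = out * m
                cache["drop"].append(m)
            else:
                cache["drop"].append(None)
            inp = out
        yhat = inp @ self.params["w_out"] + self.params["b_out"]  # (B, T, 1)
        cache["top"] = inp
        return yhat[..., 0], cache

    def _backward(self, cache, dY: np.ndarray) -> dict[str, np.ndarray]:
        """dY: (B, T) gradient of the loss w.r.t. predictions."""
        H = self.hidden_size
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        top = cache["top"]  # (B, T, H)
        grads["w_out"] = np.einsum("bth,bt->h", top, dY)[:, None]
        grads["b_out"] = np.array([dY.sum()])
        dInp = dY[..., None] * self.params["w_out"][:, 0]  # (B, T, H)
        for l in range(self.n_layers - 1, -1, -1):
            m = cache["drop"][l]
            if m is not None:
                dInp = dInp * m
            layer = cache["layers"][l]
            W, U = self.params[f"W{l}"], self.params[f"U{l}"]
            inp = layer["inp"]
            B, T, _ = inp.shape
            dW = np.zeros_like(W)
            dU = np.zeros_like(U)
            db = np.zeros(4 * H)
            dX = np.zeros_like(inp)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o = layer["gates"][t]
                tc = layer["tanhc"][t]
                c_prev = layer["cells"][t - 1] if t > 0 else np.zeros((B, H))
                h_prev = layer["H"][:, t - 1] if t > 0 else np.zeros((B, H))
                dh = dInp[:, t] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                     dg * (1 - g * g), do * o * (1 - o)], axis=1)
                dW += inp[:, t].T @ dz
                dU += h_prev.T @ dz
                db += dz.sum(axis=0)
                dX[:, t] = dz @ W.T
                dh_next = dz @ U.T
                dc_next = dc * f
            grads[f"W{l}"] = dW
            grads[f"U{l}"] = dU
            grads[f"b{l}"] = db
            dInp = dX
        return grads

    # ------------------------------------------------------------------
    # loss
    # ------------------------------------------------------------------

    @staticmethod
    def _mse_and_grad(yhat, y, w):
        """Weighted MSE over positions with w > 0; y may be NaN off-mask."""
        w = np.where(np.isfinite(y), w, 0.0)
        total = w.sum()
        if total <= 0:
            return 0.0, np.zeros_like(yhat)
        diff = np.where(w > 0, yhat - np.nan_to_num(y), 0.0)
        loss = float((w * diff * diff).sum() / total)
        dY = 2.0 * w * diff / total
        return loss, dY

    def evaluate_mse(self, sequences) -> float:
        """Mean masked MSE over a list of (X, y, w) triples."""
        num = den = 0.0
        for X, y, w in sequences:
            yhat, _ = self._forward(X[None])
            w = np.where(np.isfinite(y), w, 0.0)
            diff = np.where(w > 0, yhat[0] - np.nan_to_num(y), 0.0)
            num += float((w * diff * diff).sum())
            den += float(w.sum())
        return num / max(den, 1e-12)

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------

    def fit(self, train, val, learning_rate: float = 2e-3, batch_size: int = 16,
            weight_decay: float = 1e-5, max_epochs: int = 200, patience: int = 20,
            grad_clip: float = 5.0, seed: int = 0, lr_decay: float = 0.5,
            lr_patience: int = 8, min_lr: float = 1e-4,
            verbose: bool = False) -> TrainingHistory:
        """Train on lists of (X (T,F), y (T,), weight (T,)) triples.

        Selects (and restores) the epoch with the best validation MSE; the
        learning rate decays by ``lr_decay`` after ``lr_patience`` epochs
        without improvement (down to ``min_lr``), and training stops after
        ``patience`` epochs without improvement. Deterministic given
        ``seed``.
        """
        if not train:
            raise ValueError("empty training set")
        rng = np.random.default_rng(seed)
        lr = learning_rate
        lr_bad = 0
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_adam = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = TrainingHistory([], [], -1, math.inf)
        best = {k: p.copy() for k, p in self.params.items()}
        bad_epochs = 0
        for epoch in range(max_epochs):
            order = rng.permutation(len(train))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(order), batch_size):
                batch = [train[i] for i in order[start:start + batch_size]]
                T = max(len(b[1]) for b in batch)
                B = len(batch)
                X = np.zeros((B, T, self.input_size))
                y = np.full((B, T), np.nan)
                w = np.zeros((B, T))
                for j, (Xi, yi, wi) in enumerate(batch):
                    L = len(yi)
                    X[j, :L] = Xi
                    y[j, :L] = yi
                    w[j, :L] = wi
                yhat, cache = self._forward(X, train=True, rng=rng)
                loss, dY = self._mse_and_grad(yhat, y, w)
                if not math.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; check inputs "
                        "for NaNs or lower the learning rate")
                grads = self._backward(cache, dY)
                if weight_decay > 0:
                    for k in grads:
                        grads[k] = grads[k] + weight_decay * self.params[k]
                if grad_clip > 0:
                    norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                    if norm > grad_clip:
                        scale = grad_clip / norm
                        for k in grads:
                            grads[k] = grads[k] * scale
                step += 1
                for k in self.params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1 ** step)
                    vhat = v_adam[k] / (1 - beta2 ** step)
                    self.params[k] = self.params[k] - lr * mhat / (
                        np.sqrt(vhat) + eps)
                epoch_loss += loss
                n_batches += 1
            val_loss = self.evaluate_mse(val) if val else epoch_loss / max(n_batches, 1)
            history.train_loss.append(epoch_loss / max(n_batches, 1))
            history.val_loss.append(val_loss)
            if val_loss < history.best_val_loss - 1e-12:
                history.best_val_loss = val_loss
                history.best_epoch = epoch
                best = {k: p.copy() for k, p in self.params.items()}
                bad_epochs = 0
                lr_bad = 0
            else:
                bad_epochs += 1
                lr_bad += 1
                if lr_bad >= lr_patience and lr > min_lr:
                    lr = max(min_lr, lr * lr_decay)
                    lr_bad = 0
                    if verbose:
                        log.info("epoch %d: lr decayed to %.2e", epoch, lr)
            if verbose and epoch % 10 == 0:
                log.info("epoch %d train %.5f val %.5f", epoch,
                         history.train_loss[-1], val_loss)
            if bad_epochs >= patience:
                break
        self.params = best
        return history

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions for one sequence X (T, F) -> (T,)."""
        yhat, _ = self._forward(np.asarray(X, dtype=float)[None])
        return yhat[0]

    def init_state(self):
        H = self.hidden_size
        return [(np.zeros(H), np.zeros(H)) for _ in range(self.n_layers)]

    def step(self, x: np.ndarray, state):
        """Advance one timestep; returns (prediction, new_state)."""
        H = self.hidden_size
        new_state = []
        inp = np.asarray(x, dtype=float)
        for l in range(self.n_layers):
            h, c = state[l]
            z = inp @ self.params[f"W{l}"] + h @ self.params[f"U{l}"] + self.params[f"b{l}"]
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H:2 * H])
            g = np.tanh(z[2 * H:3 * H])
            o = _sigmoid(z[3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            new_state.append((h, c))
            inp = h
        y = float(inp @ self.params["w_out"][:, 0] + self.params["b_out"][0])
        return y, new_state

    # ------------------------------------------------------------------
    # (de)serialization
    # ------------------------------------------------------------------

    def state_dict(self) -> dict:
        meta = dict(input_size=self.input_size, hidden_size=self.hidden_size,
                    n_layers=self.n_layers, dropout=self.dropout)
        return {"meta": meta, "params": {k: v.copy() for k, v in self.params.items()}}

    @classmethod
    def from_state_dict(cls, state: dict) -> "SequenceRegressor":
        model = cls(**state["meta"])
        model.params = {k: np.asarray(v, dtype=float) for k, v in state["params"].items()}
        return model
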