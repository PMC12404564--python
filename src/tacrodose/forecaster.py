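"""Next-day tacrolimus trough forecasting.

`TacrolimusForecaster` is the model object: it is built from per-patient
daily feature sequences (or directly from raw tables via
:meth:`TacrolimusForecaster.from_tables`) and `fit()` trains the stacked
LSTM and returns a :class:`ForecasterResults` carrying the trained network,
predictions, regression and dose-class metrics, permutation feature
importance and a text `summary()`.

The model is strictly causal: the prediction for day ``t+1`` is a function
of feature rows with day index ``<= t`` only. Training minimizes MSE on the
(0,1)-scaled next-day trough with Adam; the epoch with the best validation
MSE is kept. When ``config.oversample`` is set, training instances whose
observed trough is below 5 or above 13 ng/mL carry loss weight 4 — the
sequence-trainer equivalent of duplicating those instances three extra
times.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ForecasterConfig
from .features import (FeatureSchema, PatientSequence, build_feature_frame,
                       build_sequences, split_cohort,
                       DOSE_BIN_FEATURES)
from .nn import SequenceRegressor, TrainingHistory
from .policy import (WindowRegistry, classification_metrics, classify_level,
                     regression_metrics, window_for)

log = logging.getLogger(__name__)

OVERSAMPLE_LOW = 5.0
OVERSAMPLE_HIGH = 13.0
OVERSAMPLE_WEIGHT = 4.0


def _train_weights(seq: PatientSequence, oversample: bool) -> np.ndarray:
    w = seq.mask.astype(float)
    if oversample:
        extreme = (seq.y_raw < OVERSAMPLE_LOW) | (seq.y_raw > OVERSAMPLE_HIGH)
        w = np.where(seq.mask & np.nan_to_num(extreme, nan=False),
                     OVERSAMPLE_WEIGHT, w)
    return w


class TacrolimusForecaster:
    """Sequence model for next-day tacrolimus C0 (ng/mL)."""

    def __init__(self, sequences: dict[str, list[PatientSequence]],
                 schema: FeatureSchema, config: ForecasterConfig | None = None):
        self.sequences = sequences
        self.schema = schema
        self.config = config or ForecasterConfig()
        self.config.validate()

    @classmethod
    def from_tables(cls, raw, config: ForecasterConfig | None = None,
                    manifest: list[str] | None = None, split_seed: int = 0,
                    test_year: int = 2024, add_noise_feature: bool = False
                    ) -> "TacrolimusForecaster":
        """Run the full feature pipeline on raw EHR-shaped tables."""
        frame = build_feature_frame(raw, manifest=manifest,
                                    add_noise_feature=add_noise_feature,
                                    noise_seed=split_seed)
        split = split_cohort(raw.patients, seed=split_seed, test_year=test_year)
        train_frame = frame[frame["patient_id"].map(split).eq("train")]
        schema = FeatureSchema.fit(train_frame, manifest=frame.attrs["manifest"])
        sequences = build_sequences(frame, schema, split)
        return cls(sequences, schema, config)

    def fit(self, verbose: bool = False) -> "ForecasterResults":
        cfg = self.config
        train = [(s.x, s.y_scaled, _train_weights(s, cfg.oversample))
                 for s in self.sequences.get("train", [])]
        train = [t for t in train if t[2].sum() > 0]
        val = [(s.x, s.y_scaled, s.mask.astype(float))
               for s in self.sequences.get("val", [])]
        val = [t for t in val if t[2].sum() > 0]
        if not train:
            raise ValueError("no training sequences with prediction days")
        net = SequenceRegressor(input_size=len(self.schema.feature_names),
                                hidden_size=cfg.hidden_size, n_layers=cfg.n_layers,
                                dropout=cfg.dropout, seed=cfg.seed)
        history = net.fit(train, val, learning_rate=cfg.learning_rate,
                          batch_size=cfg.batch_size, weight_decay=cfg.weight_decay,
                          max_epochs=cfg.max_epochs, patience=cfg.patience,
                          grad_clip=cfg.grad_clip, seed=cfg.seed, verbose=verbose)
        log.info("training done: best epoch %d, best val MSE %.5f",
                 history.best_epoch, history.best_val_loss)
        return ForecasterResults(self, net, history)


@dataclass
class ForecasterResults:
    """A trained forecaster plus everything needed to evaluate and apply it."""

    model: TacrolimusForecaster
    net: SequenceRegressor
    history: TrainingHistory

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------

    @property
    def schema(self) -> FeatureSchema:
        return self.model.schema

    def predict_sequence(self, seq: PatientSequence) -> np.ndarray:
        """Next-day C0 predictions (ng/mL) for every row of a sequence.

        Entry ``i`` predicts the trough of day ``seq.days[i] + 1`` using rows
        ``0..i`` only.
        """
        yhat = self.net.predict(seq.x)
        return np.maximum(self.schema.unscale_target(yhat), 0.0)

    def predict_next_day(self, seq: PatientSequence, upto_index: int | None = None
                         ) -> float:
        """Predicted C0 for the day after ``seq.days[upto_index]`` (default last)."""
        if len(seq) == 0:
            raise ValueError("empty sequence")
        i = len(seq) - 1 if upto_index is None else upto_index
        return float(self.predict_sequence(seq)[i])

    def _state_through(self, seq: PatientSequence, last_index: int):
        """Hidden state after consuming rows 0..last_index (exclusive of day t)."""
        state = self.net.init_state()
        for i in range(last_index):
            _, state = self.net.step(seq.x[i], state)
        return state

    def predict_under_dose(self, seq: PatientSequence, t_index: int,
                           am: float, pm: float,
                           state=None) -> float:
        """Counterfactual next-day C0 if day t's doses were (am, pm) mg.

        The candidate is substituted into day-t dose-bin features at the
        default administration times (AM -> [08:00,16:00) bin, PM ->
        [16:00,24:00) bin, nothing in [00:00,08:00)), re-scaled with the
        frozen schema, and the prediction re-run. The stored sequence is not
        mutated.
        """
        if am < 0 or pm < 0:
            raise ValueError("candidate doses must be >= 0")
        x = seq.x[t_index].copy()
        names = self.schema.feature_names
        for bin_name, dose in zip(DOSE_BIN_FEATURES, (0.0, am, pm)):
            if bin_name in names:
                x[names.index(bin_name)] = self.schema.scale_feature(bin_name, dose)
        if state is None:
            state = self._state_through(seq, t_index)
        y, _ = self.net.step(x, state)
        return float(max(self.schema.unscale_target(y), 0.0))

    # ------------------------------------------------------------------
    # evaluation
    # ------------------------------------------------------------------

    def predictions(self, split: str = "test") -> pd.DataFrame:
        """One row per prediction instance in a split."""
        rows = []
        for seq in self.model.sequences.get(split, []):
            pred = self.predict_sequence(seq)
            for i in np.flatnonzero(seq.mask):
                rows.append(dict(patient_id=seq.patient_id, organ=seq.organ,
                                 day=int(seq.days[i]),
                                 prediction_day=int(seq.days[i]) + 1,
                                 predicted_c0=float(pred[i]),
                                 actual_c0=float(seq.y_raw[i])))
        return pd.DataFrame(rows)

    def evaluate(self, split: str = "test",
                 registry: WindowRegistry | None = None) -> dict:
        """MAE/MAPE plus 3-class dose-classification metrics on a split.

        The classifier is the thresholded regression output: predicted and
        actual troughs are labeled against the patient's therapeutic window
        on the prediction day.
        """
        preds = self.predictions(split)
        if preds.empty:
            raise ValueError(f"no prediction instances in split {split!r}")
        report = regression_metrics(preds["predicted_c0"], preds["actual_c0"])
        pred_cls, true_cls = [], []
        for _, r in preds.iterrows():
            w = window_for(r["organ"], int(r["prediction_day"]), registry)
            pred_cls.append(classify_level(r["predicted_c0"], w))
            true_cls.append(classify_level(r["actual_c0"], w))
        report["classification"] = classification_metrics(pred_cls, true_cls)
        report["n_instances"] = len(preds)
        return report

    # ------------------------------------------------------------------
    # permutation feature importance (model class reliance)
    # ------------------------------------------------------------------

    def permutation_importance(self, split: str = "test", repeats: int = 10,
                               seed: int = 0) -> pd.DataFrame:
        """Error increase when one feature is shuffled across all patient-days.

        For each feature the values are permuted across the pooled
        patient-day axis of the held-out split, predictions recomputed, and
        the degradation (permuted MAE - baseline MAE, ng/mL) averaged over
        ``repeats`` distinct shuffles. Returns a frame sorted by mean
        degradation, descending.
        """
        seqs = self.model.sequences.get(split, [])
        seqs = [s for s in seqs if s.mask.any()]
        if not seqs:
            raise ValueError(f"no evaluation sequences in split {split!r}")
        lengths = [len(s) for s in seqs]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        pooled = np.concatenate([s.x for s in seqs], axis=0)

        def mae_with(x_pool):
            errs, k = [], 0
            for s, n0, n1 in zip(seqs, offsets[:-1], offsets[1:]):
                yhat = self.net.predict(x_pool[n0:n1])
                pred = np.maximum(self.schema.unscale_target(yhat), 0.0)
                errs.append(np.abs(pred[s.mask] - s.y_raw[s.mask]))
                k += 1
            return float(np.mean(np.concatenate(errs)))

        baseline = mae_with(pooled)
        rng = np.random.default_rng(seed)
        rows = []
        for j, name in enumerate(self.schema.feature_names):
            degradations = []
            for _ in range(repeats):
                perm = rng.permutation(pooled.shape[0])
                shuffled = pooled.copy()
                shuffled[:, j] = pooled[perm, j]
                degradations.append(mae_with(shuffled) - baseline)
            degradations = np.asarray(degradations)
            rows.append(dict(feature=name,
                             mean_degradation=float(degradations.mean()),
                             sd_degradation=float(degradations.std(ddof=1))
                             if repeats > 1 else 0.0))
        out = pd.DataFrame(rows).sort_values(
            "mean_degradation", ascending=False).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
        out.attrs["baseline_mae"] = baseline
        return out

    # ------------------------------------------------------------------
    # persistence and reporting
    # ------------------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + config + schema (hash embedded)."""
        state = self.net.state_dict()
        schema_json = self.schema.to_json()
        meta = dict(meta=state["meta"],
                    config=self.model.config.__dict__,
                    schema=schema_json,
                    schema_sha256=hashlib.sha256(schema_json.encode()).hexdigest(),
                    best_epoch=self.history.best_epoch,
                    best_val_mse=self.history.best_val_loss)
        np.savez(path, __meta__=json.dumps(meta), **state["params"])

    @staticmethod
    def load(path, sequences=None) -> "ForecasterResults":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {k: data[k] for k in data.files if k != "__meta__"}
        net = SequenceRegressor.from_state_dict(
            {"meta": meta["meta"], "params": params})
        schema = FeatureSchema.from_json(meta["schema"])
        cfg = ForecasterConfig(**meta["config"])
        model = TacrolimusForecaster(sequences or {}, schema, cfg)
        hist = TrainingHistory([], [], meta["best_epoch"], meta["best_val_mse"])
        return ForecasterResults(model, net, hist)

    def summary(self) -> str:
        cfg = self.model.config
        buf = io.StringIO()
        n = {k: len(v) for k, v in self.model.sequences.items()}
        print("Tacrolimus next-day C0 forecaster (stacked LSTM)", file=buf)
        print("=" * 56, file=buf)
        print(f"layers: {cfg.n_layers}  hidden: {cfg.hidden_size}  "
              f"dropout: {cfg.dropout}  lr: {cfg.learning_rate}  "
              f"batch: {cfg.batch_size}  weight decay: {cfg.weight_decay}", file=buf)
        print(f"patients per split: {n}", file=buf)
        print(f"features: {len(self.schema.feature_names)}", file=buf)
        print(f"best epoch: {self.history.best_epoch}  "
              f"best val MSE (scaled): {self.history.best_val_loss:.5f}", file=buf)
        try:
            ev = self.evaluate("test")
            print(f"test MAE: {ev['mae']:.3f} ng/mL  test MAPE: {ev['mape']:.1f}%",
                  file=buf)
            mic = ev["classification"]["micro"]
            mac = ev["classification"]["macro"]
            print(f"dose-class micro F1: {mic['f1']:.3f}  macro F1: {mac['f1']:.3f}",
                  file=buf)
        except ValueError:
            print("(no test split to evaluate)", file=buf)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# functional aliases matching the operation-style interface
# ---------------------------------------------------------------------------

def train_forecaster(sequences: dict[str, list[PatientSequence]],
                     schema: FeatureSchema,
                     config: ForecasterConfig | None = None) -> ForecasterResults:
    return TacrolimusForecaster(sequences, schema, config).fit()


def predict_next_day(results: ForecasterResults, seq: PatientSequence,
                     upto_index: int | None = None) -> float:
    return results.predict_next_day(seq, upto_index)


def predict_under_dose(results: ForecasterResults, seq: PatientSequence,
                       t_index: int, am: float, pm: float) -> float:
    return results.predict_under_dose(seq, t_index, am, pm)


def permutation_importance(results: ForecasterResults, split: str = "test",
                           repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    return results.permutation_importance(split, repeats, seed)
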