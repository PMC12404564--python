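"""Therapeutic windows, dose-class labeling, oversampling, and metrics.

Institutional target trough windows (ng/mL), piecewise-constant in days
post-transplant with one breakpoint per organ:

* kidney: 10-13 through day 90, then 8-10
* liver:   7-10 through day 365, then 5-7

Month/year breakpoints are fixed at 90 and 365 days with the earlier window
inclusive of its breakpoint day; window bounds are inclusive for
"therapeutic".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

log = logging.getLogger(__name__)

DOSE_CLASSES = ("under", "therapeutic", "over")


@dataclass(frozen=True)
class TherapeuticWindow:
    lower: float
    upper: float

    def __post_init__(self):
        if not 0 < self.lower < self.upper:
            raise ValueError(f"require 0 < lower < upper, got {self}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def __iter__(self):
        yield self.lower
        yield self.upper


class WindowRegistry:
    """Maps (organ, days post-transplant) to a therapeutic window.

    ``breaks`` maps organ -> list of (last_day_inclusive, window); the final
    entry uses ``None`` for open-ended.
    """

    DEFAULT = {
        "kidney": [(90, TherapeuticWindow(10.0, 13.0)),
                   (None, TherapeuticWindow(8.0, 10.0))],
        "liver": [(365, TherapeuticWindow(7.0, 10.0)),
                  (None, TherapeuticWindow(5.0, 7.0))],
    }

    def __init__(self, breaks: dict | None = None):
        self.breaks = breaks if breaks is not None else dict(self.DEFAULT)

    def window_for(self, organ: str, days_post_transplant: int) -> TherapeuticWindow:
        if days_post_transplant < 0:
            raise ValueError("days_post_transplant must be >= 0")
        try:
            segments = self.breaks[organ]
        except KeyError:
            raise KeyError(f"unknown organ {organ!r}; known: {sorted(self.breaks)}")
        for last_day, window in segments:
            if last_day is None or days_post_transplant <= last_day:
                return window
        raise AssertionError("registry not total")  # pragma: no cover

    def to_dict(self) -> dict:
        return {organ: [[d, [w.lower, w.upper]] for d, w in seg]
                for organ, seg in self.breaks.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "WindowRegistry":
        return cls({organ: [(day, TherapeuticWindow(*bounds)) for day, bounds in seg]
                    for organ, seg in d.items()})


_DEFAULT_REGISTRY = WindowRegistry()


def window_for(organ: str, days_post_transplant: int,
               registry: WindowRegistry | None = None) -> TherapeuticWindow:
    """Look up the target trough window for an organ and time post-transplant."""
    return (registry or _DEFAULT_REGISTRY).window_for(organ, days_post_transplant)


def classify_level(level: float, window: TherapeuticWindow) -> str:
    """Label a trough against a window: under / therapeutic / over.

    Bounds are inclusive for "therapeutic".
    """
    if level < window.lower:
        return "under"
    if level > window.upper:
        return "over"
    return "therapeutic"


def oversample_training_set(instances: pd.DataFrame | Sequence,
                            c0: Iterable[float] | str = "c0",
                            low: float = 5.0, high: float = 13.0,
                            extra_copies: int = 3):
    """Duplicate extreme-trough training instances.

    Instances with observed C0 strictly below ``low`` or strictly above
    ``high`` ng/mL receive ``extra_copies`` additional copies (4 rows total
    each, with the defaults); all others appear once. Intended for the
    training split only. Values are never modified, only multiplicities.

    ``instances`` may be a DataFrame (``c0`` names the trough column) or any
    sequence (``c0`` is then a parallel iterable of troughs, or the sequence
    itself if it is numeric).
    """
    if isinstance(instances, pd.DataFrame):
        levels = instances[c0].to_numpy(dtype=float)
        flagged = (levels < low) | (levels > high)
        reps = np.where(flagged, 1 + extra_copies, 1)
        return instances.loc[instances.index.repeat(reps)].reset_index(drop=True)
    items = list(instances)
    if isinstance(c0, str):
        levels = [float(x) for x in items]
    else:
        levels = [float(x) for x in c0]
    out = []
    for item, lv in zip(items, levels):
        k = 1 + extra_copies if (lv < low or lv > high) else 1
        out.extend([item] * k)
    return out


def regression_metrics(predicted: Sequence[float], actual: Sequence[float]
                       ) -> dict[str, float]:
    """MAE (ng/mL) and MAPE (%) between predicted and actual troughs."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted and actual must be equal-length and non-empty")
    if np.any(a <= 0):
        raise ValueError("actual troughs must be > 0 for MAPE")
    mae = float(np.mean(np.abs(p - a)))
    mape = float(np.mean(np.abs(p - a) / a) * 100.0)
    return {"mae": mae, "mape": mape}


def classification_metrics(predicted: Sequence[str], truth: Sequence[str]
                           ) -> dict:
    """Micro/macro and per-class precision, recall and F1 for the 3 classes.

    Classes absent from both predictions and truth contribute zeros to the
    macroaverage (with a warning), mirroring an imbalanced clinical test set.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth) or not truth:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    labels = list(DOSE_CLASSES)
    seen = set(predicted) | set(truth)
    for cls in labels:
        if cls not in seen:
            warnings.warn(f"class {cls!r} absent from predictions and truth; "
                          "contributes 0 to macroaverages", stacklevel=2)
    out: dict = {"per_class": {}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn zero-division warnings
        pc_p, pc_r, pc_f, support = precision_recall_fscore_support(
            truth, predicted, labels=labels, zero_division=0)
        for avg in ("micro", "macro"):
            p, r, f, _ = precision_recall_fscore_support(
                truth, predicted, labels=labels, average=avg, zero_division=0)
            out[avg] = {"precision": float(p), "recall": float(r), "f1": float(f)}
    for i, cls in enumerate(labels):
        out["per_class"][cls] = {"precision": float(pc_p[i]),
                                 "recall": float(pc_r[i]),
                                 "f1": float(pc_f[i]),
                                 "support": int(support[i])}
    return out
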