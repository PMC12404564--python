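"""End-to-end pipeline: simulate -> featurize -> train -> evaluate -> recommend.

A :class:`RunConfig` (serializable to/from YAML) plus its seeds fully
determines a run. ``run_pipeline`` writes all artifacts into one directory
and is idempotent on a completed directory unless forced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .config import CohortConfig, ForecasterConfig
from .features import (FeatureSchema, build_cohort, build_feature_frame,
                       build_sequences, split_cohort)
from .forecaster import TacrolimusForecaster
from .policy import WindowRegistry
from .recommend import build_recommendation_records, distance_reward_curve
from .simulate import generate_cohort

log = logging.getLogger(__name__)

COMPLETED_MARKER = "COMPLETED"


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    forecaster: ForecasterConfig = field(default_factory=ForecasterConfig)
    split_seed: int = 0
    test_year: int = 2024
    importance_repeats: int = 5
    reward_bin_width: float = 1.0
    registry: dict | None = None   # window-registry override, policy format

    def validate(self) -> None:
        self.cohort.validate()
        self.forecaster.validate()

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "forecaster" in d:
            d["forecaster"] = ForecasterConfig(**d["forecaster"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def window_registry(self) -> WindowRegistry | None:
        return WindowRegistry.from_dict(self.registry) if self.registry else None


def run_pipeline(config: RunConfig, outdir, force: bool = False) -> dict:
    """Execute every stage, logging row counts and filter attrition.

    Returns a dict of artifact paths plus the in-memory results object.
    Raises PipelineError naming the failed stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / COMPLETED_MARKER
    if marker.exists() and not force:
        log.info("run directory %s already completed; skipping (use force)", outdir)
        return {"outdir": outdir, "skipped": True}

    stage = "simulate"
    try:
        tables, truth = generate_cohort(config.cohort)
        tdir = outdir / "tables"
        tables.write(tdir, config.cohort)
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        log.info("simulate: %d patients, %d administrations, %d labs",
                 len(tables.patients), len(tables.administrations), len(tables.labs))

        stage = "featurize"
        selection = build_cohort(tables)
        frame = build_feature_frame(tables)
        split = split_cohort(tables.patients, seed=config.split_seed,
                             test_year=config.test_year)
        frame.to_csv(outdir / "features.csv", index=False)
        (outdir / "split.json").write_text(json.dumps(split, indent=2) + "\n")
        log.info("featurize: %d patient-days, attrition %s",
                 len(frame), selection.attrition)

        stage = "train"
        train_frame = frame[frame["patient_id"].map(split).eq("train")]
        schema = FeatureSchema.fit(train_frame, manifest=frame.attrs["manifest"])
        schema.save(outdir / "schema.json")
        sequences = build_sequences(frame, schema, split)
        model = TacrolimusForecaster(sequences, schema, config.forecaster)
        results = model.fit()
        results.save(outdir / "model.ckpt.npz")

        stage = "evaluate"
        registry = config.window_registry()
        metrics = results.evaluate("test", registry)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        importance = results.permutation_importance(
            "test", repeats=config.importance_repeats, seed=config.split_seed)
        importance.to_csv(outdir / "importance.csv", index=False)
        (outdir / "summary.txt").write_text(results.summary())

        stage = "recommend"
        records = build_recommendation_records(results, "test", registry)
        records.to_csv(outdir / "recommendations.csv", index=False)
        curve = distance_reward_curve(records, config.reward_bin_width)
        curve.to_csv(outdir / "reward_curve.csv", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    marker.write_text("ok\n")
    return {"outdir": outdir, "skipped": False, "results": results,
            "metrics": metrics, "records": records, "curve": curve,
            "importance": importance, "ground_truth": truth,
            "attrition": selection.attrition}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    CODES = {"simulate": 10, "featurize": 20, "train": 30,
             "evaluate": 40, "recommend": 50}

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = self.CODES.get(stage, 1)
        super().__init__(f"stage {stage!r} failed (code {self.code}): {cause}")


def irreducible_mae(ground_truth: pd.DataFrame, patient_ids=None) -> float:
    """MAE of the oracle predictor on the realized troughs.

    The conditional-median predictor of the generative mechanism is the
    noise-free trough ``mu``; its MAE against the realized troughs is the
    irreducible error floor any forecaster faces on this cohort.
    """
    gt = ground_truth[ground_truth["measured"]]
    if patient_ids is not None:
        gt = gt[gt["patient_id"].isin(set(patient_ids))]
    gt = gt[gt["daily_dose_prev"] > 0]
    return float((gt["trough_ng_ml"] - gt["mu_ng_ml"]).abs().mean())
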