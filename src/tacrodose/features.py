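"""Raw EHR tables -> model-ready daily sequences.

One feature row per eligible patient per calendar day, built strictly from
data timestamped on or before that day (no leakage): today's morning trough
(censor-resolved), tacrolimus dose totals in three 8-hour bins for the
current and previous day, 3-day interacting-drug exposure flags, last-known
labs/vitals (forward-filled, training-median fallback), diet, demographics
and comorbidities. The prediction target for the row of day ``t`` is the
morning trough of day ``t+1``.

Eligibility follows the study's selection: adults (>=18) with a single
transplanted organ; a day ``t`` is a prediction day when the trough was
measured on mornings ``t`` and ``t+1`` and at least one tacrolimus dose was
administered after the day-``t`` measurement.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CENSOR_MARKER = "<2"
CENSOR_VALUE = 1.0  # ng/mL stand-in for "<2 ng/mL" reports

DEFAULT_DRUG_LIST = (
    "mycophenolate mofetil",
    "antithymocyte globulin",
    "sirolimus",
    "ketoconazole",
    "fluconazole",
    "posaconazole",
    "prednisone",
)

LAB_ANALYTES = ("creatinine", "bun", "alt", "ast", "hemoglobin",
                "potassium", "glucose", "wbc")
VITAL_SIGNS = ("temp_c", "heart_rate", "sbp", "dbp")

DOSE_BIN_FEATURES = ("tacro_dose_0_8", "tacro_dose_8_16", "tacro_dose_16_24")
PREV_DOSE_BIN_FEATURES = ("tacro_dose_prev_0_8", "tacro_dose_prev_8_16",
                          "tacro_dose_prev_16_24")

STATIC_FEATURES = (
    "organ_kidney", "age", "gender_man",
    "race_white", "race_asian", "race_black", "race_other",
    "ethnicity_hispanic", "weight_kg", "height_cm",
    "hypertension", "diabetes_type1", "diabetes_type2", "diabetes_other",
)


def default_manifest(drug_list: tuple[str, ...] = DEFAULT_DRUG_LIST) -> list[str]:
    """Ordered default feature manifest (the configurable 62-variable list)."""
    names = list(STATIC_FEATURES)
    names += ["days_post_transplant", "tacro_level_today"]
    names += list(DOSE_BIN_FEATURES) + list(PREV_DOSE_BIN_FEATURES)
    names += [f"drug_{d.replace(' ', '_')}" for d in drug_list]
    names += [f"lab_{a}" for a in LAB_ANALYTES]
    names += [f"vital_{v}" for v in VITAL_SIGNS]
    names += ["diet_meals"]
    return names


#: columns imputed by forward fill + training-median fallback; everything
#: else (doses, flags, demographics) is complete by construction
def fillable_features(manifest: list[str]) -> list[str]:
    return [f for f in manifest
            if f == "tacro_level_today" or f == "diet_meals"
            or f.startswith(("lab_", "vital_"))]


class ParseError(ValueError):
    pass


def censor_resolve(text) -> float:
    """Resolve a reported trough to ng/mL; "<2" reports become 1.0."""
    if isinstance(text, float) and not np.isnan(text):
        return float(text)
    s = str(text).strip()
    if s == CENSOR_MARKER or s == f"{CENSOR_MARKER} ng/mL":
        return CENSOR_VALUE
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"unparseable tacrolimus level {text!r}")


def bin_doses(timestamps, doses, day: pd.Timestamp) -> np.ndarray:
    """Sum doses into the three half-open 8-hour bins of a calendar day.

    Bins are [00:00,08:00), [08:00,16:00), [16:00,24:00); an administration
    at exactly 08:00 falls in the middle bin. Totals conserve the daily sum.
    """
    out = np.zeros(3)
    day = pd.Timestamp(day).normalize()
    for ts, dose in zip(timestamps, doses):
        ts = pd.Timestamp(ts)
        if ts.normalize() != day:
            continue
        out[min(ts.hour // 8, 2)] += dose
    return out


# ---------------------------------------------------------------------------
# table cleaning and cohort selection
# ---------------------------------------------------------------------------

def _parse_ts(df: pd.DataFrame, col: str, label: str) -> tuple[pd.DataFrame, int]:
    ts = pd.to_datetime(df[col], errors="coerce")
    bad = ts.isna()
    if bad.any():
        log.warning("%s: rejected %d rows with malformed timestamps", label, int(bad.sum()))
    df = df.loc[~bad].copy()
    df[col] = ts[~bad]
    return df, int(bad.sum())


@dataclass
class CohortSelection:
    eligible: list[str]
    prediction_days: dict[str, list[int]]
    attrition: dict[str, int]


def build_cohort(raw) -> CohortSelection:
    """Apply the eligibility filters and find each patient's prediction days.

    Attrition is accounted exactly: patients_in = excluded + retained at each
    filter, logged flowchart-style.
    """
    patients = raw.patients.copy()
    n_in = len(patients)
    multi = patients["patient_id"].duplicated(keep=False)
    patients = patients.loc[~multi]
    n_multi = n_in - len(patients)
    adult = patients["age"] >= 18
    n_minor = int((~adult).sum())
    patients = patients.loc[adult]
    attrition = {"patients_in": n_in, "excluded_multi_organ": n_multi,
                 "excluded_age": n_minor, "retained_after_filters": len(patients)}
    assert n_in == n_multi + n_minor + len(patients)
    log.info("cohort selection: %s", attrition)

    admins, n_bad_ts = _parse_ts(raw.administrations, "timestamp", "administrations")
    neg = admins["dose_mg"] < 0
    if neg.any():
        log.warning("administrations: rejected %d rows with negative doses", int(neg.sum()))
    admins = admins.loc[~neg]
    labs, _ = _parse_ts(raw.labs, "timestamp", "labs")

    tx = pd.to_datetime(patients.set_index("patient_id")["transplant_date"])
    tacro_labs = labs[labs["analyte"] == "tacrolimus"]
    tacro_admins = admins[admins["drug"] == "tacrolimus"]

    prediction_days: dict[str, list[int]] = {}
    eligible: list[str] = []
    n_no_days = 0
    for pid, tx_date in tx.items():
        plabs = tacro_labs[tacro_labs["patient_id"] == pid]
        if plabs.empty:
            n_no_days += 1
            continue
        # morning level = first tacrolimus lab of the calendar day
        by_day = plabs.sort_values("timestamp").groupby(
            plabs["timestamp"].dt.normalize().rename("date")).first()
        level_day = {int((d - tx_date).days): row["timestamp"]
                     for d, row in by_day.iterrows()}
        padm = tacro_admins[tacro_admins["patient_id"] == pid]
        adm_days = ((padm["timestamp"].dt.normalize() - tx_date).dt.days).to_numpy()
        days = []
        for t, meas_ts in level_day.items():
            if (t + 1) not in level_day:
                continue
            same_day = padm.loc[adm_days == t, "timestamp"]
            if (same_day > meas_ts).any():
                days.append(t)
        if days:
            eligible.append(pid)
            prediction_days[pid] = sorted(days)
        else:
            n_no_days += 1
    attrition["excluded_no_prediction_days"] = n_no_days
    attrition["patients_retained"] = len(eligible)
    assert attrition["retained_after_filters"] == n_no_days + len(eligible)
    return CohortSelection(eligible, prediction_days, attrition)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

_RACE_MAP = {"White": "white", "Asian": "asian",
             "Black or African American": "black"}


def _static_row(p: pd.Series) -> dict[str, float]:
    race = _RACE_MAP.get(p["race"], "other")
    return {
        "organ_kidney": 1.0 if p["organ"] == "kidney" else 0.0,
        "age": float(p["age"]),
        "gender_man": 1.0 if p["gender"] == "man" else 0.0,
        "race_white": 1.0 if race == "white" else 0.0,
        "race_asian": 1.0 if race == "asian" else 0.0,
        "race_black": 1.0 if race == "black" else 0.0,
        "race_other": 1.0 if race == "other" else 0.0,
        "ethnicity_hispanic": 1.0 if str(p["ethnicity"]).startswith("Hispanic") else 0.0,
        "weight_kg": float(p["weight_kg"]),
        "height_cm": float(p["height_cm"]),
        "hypertension": float(p["hypertension"]),
        "diabetes_type1": 1.0 if p["diabetes_type"] == "type1" else 0.0,
        "diabetes_type2": 1.0 if p["diabetes_type"] == "type2" else 0.0,
        "diabetes_other": 1.0 if p["diabetes_type"] == "other" else 0.0,
    }


def drug_exposure_flags(drug_day_pairs: set, drug_list, day: int) -> dict[str, float]:
    """Binary flags: drug administered on any of days t-2, t-1, t.

    When predicting day ``t+1`` this is the 3-calendar-day window before the
    prediction date.
    """
    out = {}
    for drug in drug_list:
        key = f"drug_{drug.replace(' ', '_')}"
        out[key] = 1.0 if any((drug, d) in drug_day_pairs
                              for d in (day - 2, day - 1, day)) else 0.0
    return out


def build_feature_frame(raw, manifest: list[str] | None = None,
                        drug_list: tuple[str, ...] = DEFAULT_DRUG_LIST,
                        add_noise_feature: bool = False,
                        noise_seed: int = 0) -> pd.DataFrame:
    """Assemble the per-patient-day feature table.

    Returns a frame with index columns ``patient_id``, ``day`` plus the
    manifest features (raw, unscaled; missing lab/vital/diet cells are NaN
    until :class:`FeatureSchema` imputes them), and bookkeeping columns
    ``target_c0`` (next-day trough, NaN when ineligible), ``is_prediction_day``
    and ``organ``. ``add_noise_feature`` appends an iid uniform column
    (``noise_independent``) useful as a negative control for feature
    importance.
    """
    manifest = list(manifest) if manifest is not None else default_manifest(drug_list)
    sel = build_cohort(raw)
    patients = raw.patients.set_index("patient_id")

    admins, _ = _parse_ts(raw.administrations, "timestamp", "administrations")
    admins = admins[admins["dose_mg"] >= 0]
    labs, _ = _parse_ts(raw.labs, "timestamp", "labs")
    vitals, _ = _parse_ts(raw.vitals, "timestamp", "vitals")
    diet = raw.diet.copy()
    diet["date"] = pd.to_datetime(diet["date"])

    unknown = set(admins["drug"]) - set(drug_list) - {"tacrolimus"}
    if unknown:
        log.warning("ignoring administrations of drugs outside the configured "
                    "list: %s", sorted(unknown))

    rows = []
    for pid in sel.eligible:
        p = patients.loc[pid]
        tx_date = pd.Timestamp(p["transplant_date"])
        static = _static_row(p)

        padm = admins[admins["patient_id"] == pid]
        adm_day = ((padm["timestamp"].dt.normalize() - tx_date).dt.days).to_numpy()
        tacro = padm["drug"] == "tacrolimus"
        drug_day_pairs = set(zip(padm.loc[~tacro, "drug"], adm_day[~tacro.to_numpy()]))

        plabs = labs[labs["patient_id"] == pid].sort_values("timestamp")
        lab_day = ((plabs["timestamp"].dt.normalize() - tx_date).dt.days).to_numpy()
        pvit = vitals[vitals["patient_id"] == pid].sort_values("timestamp")
        vit_day = ((pvit["timestamp"].dt.normalize() - tx_date).dt.days).to_numpy()
        pdiet = diet[diet["patient_id"] == pid]
        diet_by_day = {int((d - tx_date).days): m for d, m in
                       zip(pdiet["date"], pdiet["meal_count"])}

        # per-day first tacrolimus level
        tl = plabs[plabs["analyte"] == "tacrolimus"]
        tl_day = lab_day[(plabs["analyte"] == "tacrolimus").to_numpy()]
        level_by_day = {}
        for d, v in zip(tl_day, tl["value"]):
            level_by_day.setdefault(int(d), censor_resolve(v))

        # per-day dose bins for tacrolimus
        bins_by_day: dict[int, np.ndarray] = {}
        for ts, dose, d in zip(padm.loc[tacro, "timestamp"],
                               padm.loc[tacro, "dose_mg"], adm_day[tacro.to_numpy()]):
            b = bins_by_day.setdefault(int(d), np.zeros(3))
            b[min(ts.hour // 8, 2)] += float(dose)

        pred_days = set(sel.prediction_days[pid])
        first_day = min(level_by_day)
        last_day = max(level_by_day)
        for t in range(first_day, last_day + 1):
            row = dict(patient_id=pid, day=t, organ=p["organ"])
            row.update(static)
            row["days_post_transplant"] = float(t)
            row["tacro_level_today"] = level_by_day.get(t, np.nan)
            b = bins_by_day.get(t, np.zeros(3))
            bp = bins_by_day.get(t - 1, np.zeros(3))
            for name, val in zip(DOSE_BIN_FEATURES, b):
                row[name] = float(val)
            for name, val in zip(PREV_DOSE_BIN_FEATURES, bp):
                row[name] = float(val)
            row.update(drug_exposure_flags(drug_day_pairs, drug_list, t))
            for analyte in LAB_ANALYTES:
                m = (plabs["analyte"] == analyte).to_numpy() & (lab_day == t)
                row[f"lab_{analyte}"] = (float(plabs.loc[m, "value"].iloc[-1])
                                         if m.any() else np.nan)
            for sign in VITAL_SIGNS:
                m = (pvit["sign"] == sign).to_numpy() & (vit_day == t)
                row[f"vital_{sign}"] = (float(pvit.loc[m, "value"].iloc[-1])
                                        if m.any() else np.nan)
            row["diet_meals"] = float(diet_by_day.get(t, np.nan))
            eligible_day = t in pred_days
            row["is_prediction_day"] = eligible_day
            row["target_c0"] = level_by_day.get(t + 1, np.nan) if eligible_day else np.nan
            rows.append(row)

    frame = pd.DataFrame(rows)
    if add_noise_feature:
        rng = np.random.default_rng(noise_seed)
        frame["noise_independent"] = rng.uniform(size=len(frame))
        if "noise_independent" not in manifest:
            manifest.append("noise_independent")
    missing = [f for f in manifest if f not in frame.columns]
    if missing:
        raise KeyError(f"manifest features not derivable from tables: {missing}")
    cols = ["patient_id", "day", "organ", "is_prediction_day", "target_c0"] + manifest
    frame = frame[cols].sort_values(["patient_id", "day"]).reset_index(drop=True)
    frame.attrs["manifest"] = manifest
    return frame


# ---------------------------------------------------------------------------
# schema: imputation + (0,1) scaling, fit on the training split only
# ---------------------------------------------------------------------------

@dataclass
class FeatureSchema:
    """Per-feature min/max and global medians, learned on training data.

    Transform order: within-patient forward fill of lab/vital/level/diet
    columns, training-median fallback for leading gaps, then min-max scaling
    into [0,1] with clipping for out-of-range values. The target trough is
    min-max scaled with its own training bounds (not clipped).
    """

    feature_names: list[str]
    mins: dict[str, float] = field(default_factory=dict)
    maxs: dict[str, float] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    target_min: float = 0.0
    target_max: float = 1.0

    @classmethod
    def fit(cls, train_frame: pd.DataFrame, manifest: list[str] | None = None
            ) -> "FeatureSchema":
        manifest = manifest or train_frame.attrs.get("manifest") or [
            c for c in train_frame.columns
            if c not in ("patient_id", "day", "organ", "is_prediction_day", "target_c0")]
        schema = cls(feature_names=list(manifest))
        for f in manifest:
            col = train_frame[f].to_numpy(dtype=float)
            finite = col[np.isfinite(col)]
            if finite.size == 0:
                schema.mins[f], schema.maxs[f], schema.medians[f] = 0.0, 1.0, 0.0
                continue
            schema.mins[f] = float(finite.min())
            schema.maxs[f] = float(finite.max())
            schema.medians[f] = float(np.median(finite))
        tgt = train_frame["target_c0"].to_numpy(dtype=float)
        tgt = tgt[np.isfinite(tgt)]
        if tgt.size == 0:
            raise ValueError("training frame has no targets")
        schema.target_min = float(tgt.min())
        schema.target_max = float(max(tgt.max(), schema.target_min + 1e-9))
        return schema

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Impute and scale a feature frame (must match this schema)."""
        missing = [f for f in self.feature_names if f not in frame.columns]
        if missing:
            raise KeyError(f"features absent from frame: {missing}")
        out = frame.copy()
        fill_cols = [f for f in fillable_features(self.feature_names)
                     if f in self.feature_names]
        if fill_cols:
            out[fill_cols] = (out.groupby("patient_id", sort=False)[fill_cols]
                              .ffill())
            for f in fill_cols:
                out[f] = out[f].fillna(self.medians[f])
        for f in self.feature_names:
            lo, hi = self.mins[f], self.maxs[f]
            denom = (hi - lo) if hi > lo else 1.0
            out[f] = np.clip((out[f].to_numpy(dtype=float) - lo) / denom, 0.0, 1.0)
        return out

    def scale_target(self, y):
        return (np.asarray(y, dtype=float) - self.target_min) / (
            self.target_max - self.target_min)

    def unscale_target(self, y):
        return np.asarray(y, dtype=float) * (self.target_max - self.target_min) \
            + self.target_min

    def scale_feature(self, name: str, value):
        lo, hi = self.mins[name], self.maxs[name]
        denom = (hi - lo) if hi > lo else 1.0
        return float(np.clip((value - lo) / denom, 0.0, 1.0))

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names, "mins": self.mins,
            "maxs": self.maxs, "medians": self.medians,
            "target_min": self.target_min, "target_max": self.target_max,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# patient-level split
# ---------------------------------------------------------------------------

def split_cohort(patients: pd.DataFrame, seed: int, train_frac: float = 0.9,
                 test_year: int = 2024) -> dict[str, str]:
    """Assign each patient to train/val/test.

    Patients transplanted in or after ``test_year`` all go to test; the rest
    are shuffled (seeded) into ``train_frac`` train / remainder validation.
    The split is by patient, never by day.
    """
    dates = pd.to_datetime(patients["transplant_date"])
    pids = patients["patient_id"].to_numpy()
    is_test = (dates.dt.year >= test_year).to_numpy()
    pool = sorted(pids[~is_test])
    if not pool:
        raise ValueError(f"no patients transplanted before {test_year}; "
                         "cannot form a training pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_train = int(round(train_frac * len(pool)))
    assignment = {pid: "test" for pid in pids[is_test]}
    for rank, idx in enumerate(order):
        assignment[pool[idx]] = "train" if rank < n_train else "val"
    return assignment


# ---------------------------------------------------------------------------
# sequence container for the forecaster
# ---------------------------------------------------------------------------

@dataclass
class PatientSequence:
    patient_id: str
    organ: str
    days: np.ndarray          # day index per timestep
    x: np.ndarray             # (T, F) scaled features
    y_scaled: np.ndarray      # (T,) scaled next-day trough (NaN if ineligible)
    y_raw: np.ndarray         # (T,) next-day trough ng/mL (NaN if ineligible)
    mask: np.ndarray          # (T,) bool, True on prediction days
    dose_total: np.ndarray | None = None       # (T,) raw daily total, mg
    prev_dose_total: np.ndarray | None = None  # (T,) raw previous-day total, mg

    def __len__(self):
        return len(self.days)


def build_sequences(frame: pd.DataFrame, schema: FeatureSchema,
                    split: dict[str, str] | None = None
                    ) -> dict[str, list[PatientSequence]]:
    """Scale a feature frame and group it into per-patient sequences.

    Returns ``{"train": [...], "val": [...], "test": [...]}`` (a single
    ``"all"`` bucket when ``split`` is None). Patients whose split bucket has
    no prediction days are still emitted; the loss mask handles them.
    """
    scaled = schema.transform(frame)
    buckets: dict[str, list[PatientSequence]] = (
        {"all": []} if split is None else {"train": [], "val": [], "test": []})
    feat = schema.feature_names
    for pid, g in scaled.groupby("patient_id", sort=True):
        g = g.sort_values("day")
        raw = frame.loc[g.index]
        y_raw = raw["target_c0"].to_numpy(dtype=float)
        mask = g["is_prediction_day"].to_numpy(dtype=bool) & np.isfinite(y_raw)
        dose_total = sum(raw[c].to_numpy(dtype=float) for c in DOSE_BIN_FEATURES
                         if c in raw.columns)
        prev_total = sum(raw[c].to_numpy(dtype=float) for c in PREV_DOSE_BIN_FEATURES
                         if c in raw.columns)
        seq = PatientSequence(
            patient_id=pid, organ=g["organ"].iloc[0],
            days=g["day"].to_numpy(dtype=int),
            x=g[feat].to_numpy(dtype=float),
            y_scaled=np.where(mask, schema.scale_target(np.nan_to_num(y_raw)), np.nan),
            y_raw=y_raw, mask=mask,
            dose_total=np.asarray(dose_total, dtype=float),
            prev_dose_total=np.asarray(prev_total, dtype=float))
        key = "all" if split is None else split.get(pid)
        if key in buckets:
            buckets[key].append(seq)
        elif split is not None and key is None:
            warnings.warn(f"patient {pid} missing from split assignment; dropped")
    return buckets
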