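"""Synthetic EHR-shaped transplant cohorts with known pharmacokinetic truth.

The generator emulates the structure of an inpatient kidney/liver transplant
cohort on twice-daily tacrolimus: daily morning trough (C0) draws with
lower-limit censoring at 2 ng/mL, timestamped medication administrations,
irregularly missing labs and vitals, diet orders, interacting-drug episodes,
and a simple titration policy so doses and levels co-evolve.

Troughs come from a steady-state one-compartment-style mechanism: the morning
trough on day ``d`` is ``dose(d-1) / effective_clearance(d)`` with lognormal
residual noise, where effective clearance carries a between-subject lognormal
effect, an AR(1) within-subject drift, an organ factor, and a CYP-inhibitor
factor on days with an active azole. Full PK ODEs are deliberately out of
scope; this is the simplest mechanism producing autocorrelated,
covariate-dependent troughs.

The latent per-patient-day effects are emitted alongside the tables so that
downstream code can compute the irreducible prediction error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError, PKParams
from .policy import window_for

CENSOR_LIMIT = 2.0
CENSOR_MARKER = "<2"

#: interacting drugs recorded by the simulator (besides tacrolimus itself)
INTERACTING_DRUGS = (
    "mycophenolate mofetil",
    "antithymocyte globulin",
    "sirolimus",
    "ketoconazole",
    "fluconazole",
    "posaconazole",
    "prednisone",
)
#: subset that inhibits tacrolimus clearance in the generative mechanism
CYP_INHIBITORS = ("ketoconazole", "fluconazole", "posaconazole")
#: drugs drawn for transient episodes
EPISODE_DRUGS = ("ketoconazole", "fluconazole", "posaconazole", "prednisone",
                 "antithymocyte globulin", "sirolimus")

LAB_BASELINES = {
    "creatinine": (1.4, 0.5, 0.15),   # (mean, between-pt SD, day-to-day SD)
    "bun": (25.0, 8.0, 3.0),
    "alt": (35.0, 15.0, 5.0),
    "ast": (30.0, 12.0, 4.0),
    "hemoglobin": (10.5, 1.5, 0.4),
    "potassium": (4.2, 0.4, 0.2),
    "glucose": (130.0, 30.0, 15.0),
    "wbc": (8.0, 2.5, 1.0),
}
VITAL_BASELINES = {
    "temp_c": (36.8, 0.2, 0.15),
    "heart_rate": (82.0, 10.0, 6.0),
    "sbp": (128.0, 14.0, 8.0),
    "dbp": (74.0, 9.0, 5.0),
}

RACES = ("White", "Asian", "Black or African American",
         "American Indian or Alaska Native",
         "Native Hawaiian or Other Pacific Islander", "Other or mixed race")
RACE_P = (0.46, 0.12, 0.07, 0.004, 0.006, 0.34)


@dataclass
class RawTables:
    """The five EHR-shaped tables a cohort consists of."""

    patients: pd.DataFrame
    administrations: pd.DataFrame
    labs: pd.DataFrame
    vitals: pd.DataFrame
    diet: pd.DataFrame

    _NAMES = ("patients", "administrations", "labs", "vitals", "diet")

    def write(self, outdir: str | Path, config: CohortConfig | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._NAMES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        if config is not None:
            (outdir / "cohort_config.json").write_text(
                json.dumps(config.to_dict(), indent=2) + "\n")

    @classmethod
    def read(cls, indir: str | Path) -> "RawTables":
        indir = Path(indir)
        frames = {}
        for name in cls._NAMES:
            df = pd.read_csv(indir / f"{name}.csv", dtype={"value": str}
                             if name == "labs" else None)
            frames[name] = df
        return cls(**frames)


def effective_clearance(params: PKParams, organ: str, inhibitor_active: bool,
                        subject_day_effect: float) -> float:
    """Apparent clearance for one patient-day, mg·mL/ng/day."""
    organ_factor = params.organ_effect if organ == "liver" else 1.0
    inhibitor_factor = params.inhibitor_effect if inhibitor_active else 1.0
    return params.cl_pop * organ_factor * inhibitor_factor * math.exp(subject_day_effect)


def simulate_trough(daily_dose: float, clearance: float, params: PKParams,
                    rng: np.random.Generator) -> float:
    """Draw one morning trough (ng/mL) for a given prior daily dose.

    Returns ``exp(log(dose/clearance) + eps)`` with
    ``eps ~ N(0, sigma_resid^2)``. A zero-dose day yields 0.0, which is at or
    below the censor limit and is stored censored.
    """
    params.validate()
    if not math.isfinite(daily_dose) or daily_dose < 0:
        raise ConfigurationError(f"daily_dose must be finite and >= 0, got {daily_dose!r}")
    if not math.isfinite(clearance) or clearance <= 0:
        raise ConfigurationError(f"clearance must be finite and > 0, got {clearance!r}")
    if daily_dose == 0.0:
        return 0.0
    eps = rng.normal(0.0, params.sigma_resid) if params.sigma_resid > 0 else 0.0
    return math.exp(math.log(daily_dose / clearance) + eps)


def format_level(value: float) -> str:
    """Store a trough as lab text: values at/below 2 ng/mL are censored."""
    if value <= CENSOR_LIMIT:
        return CENSOR_MARKER
    return f"{value:.2f}"


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def _split_bid(total: float) -> tuple[float, float]:
    """Split a daily total into (am, pm) on the 0.5 mg grid, |am-pm| <= 0.5."""
    half_units = int(round(total * 2))
    am = (half_units + 1) // 2
    return am / 2.0, (half_units - am) / 2.0


def generate_cohort(config: CohortConfig) -> tuple[RawTables, pd.DataFrame]:
    """Generate a cohort and its ground-truth latent table.

    Deterministic given ``config.seed``. The ground-truth table has one row
    per patient-day with a trough, carrying the latent subject effect,
    inhibitor factor, effective clearance, the noise-free trough ``mu`` and
    the realized trough, so tests can compute irreducible error.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pk = config.pk

    n = config.n_patients
    n_kidney = int(round(n * config.organ_mix))
    organs = np.array(["kidney"] * n_kidney + ["liver"] * (n - n_kidney))
    rng.shuffle(organs)

    pat_rows, admin_rows, lab_rows, vital_rows, diet_rows, truth_rows = \
        [], [], [], [], [], []

    y0, y1 = config.transplant_year_range
    lo_days, hi_days = config.days_per_patient_range

    for i in range(n):
        pid = f"P{i:05d}"
        organ = organs[i]
        year = int(rng.integers(y0, y1 + 1))
        tx_date = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365)))
        n_days = int(rng.integers(lo_days, hi_days + 1))

        age = int(np.clip(round(rng.normal(57, 12)), 16, 88))  # a few <18 to exercise filters
        gender = "man" if rng.random() < 0.63 else "woman"
        race = RACES[rng.choice(len(RACES), p=RACE_P)]
        ethnicity = ("Hispanic or Latino" if rng.random() < 0.46
                     else "Non-Hispanic or Latino")
        weight = float(np.round(math.exp(rng.normal(math.log(76.0), 0.18)), 1))
        height = float(np.round(rng.normal(169.0, 9.0), 1))
        htn = int(rng.random() < (0.865 if organ == "kidney" else 0.54))
        if rng.random() < 0.50:
            diabetes = str(rng.choice(["type2", "type1", "other"], p=[0.8, 0.15, 0.05]))
        else:
            diabetes = "none"
        pat_rows.append(dict(patient_id=pid, organ=organ,
                             transplant_date=tx_date.date().isoformat(),
                             age=age, gender=gender, race=race, ethnicity=ethnicity,
                             weight_kg=weight, height_cm=height,
                             hypertension=htn, diabetes_type=diabetes))

        # ---- latent clearance trajectory -------------------------------
        b_i = rng.normal(0.0, pk.omega_bsv) if pk.omega_bsv > 0 else 0.0
        a = rng.normal(0.0, pk.omega_iov) if pk.omega_iov > 0 else 0.0
        innov_sd = pk.omega_iov * math.sqrt(max(0.0, 1.0 - pk.rho_ar1 ** 2))

        # ---- interacting-drug schedule ---------------------------------
        drug_days: dict[str, set[int]] = {d: set() for d in INTERACTING_DRUGS}
        if rng.random() < 0.50:  # maintenance mycophenolate, whole stay
            drug_days["mycophenolate mofetil"].update(range(n_days))
        n_episodes = rng.poisson(config.drug_episode_rate * n_days / 30.0)
        for _ in range(n_episodes):
            drug = EPISODE_DRUGS[int(rng.integers(0, len(EPISODE_DRUGS)))]
            start = int(rng.integers(0, n_days))
            dur = int(rng.integers(3, 10))
            drug_days[drug].update(range(start, min(n_days, start + dur)))

        # ---- per-patient lab/vital baselines ---------------------------
        lab_state = {k: rng.normal(m, s_b) for k, (m, s_b, _) in LAB_BASELINES.items()}
        vital_state = {k: rng.normal(m, s_b) for k, (m, s_b, _) in VITAL_BASELINES.items()}

        daily_total = 4.0  # starting dose, mg/day
        prev_total = 0.0
        for d in range(n_days):
            date = tx_date + pd.Timedelta(days=d)
            a = pk.rho_ar1 * a + (rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0)
            subject_effect = b_i + a
            inhibitor_prev = d >= 1 and any(
                (d - 1) in drug_days[drug] for drug in CYP_INHIBITORS)
            cl = effective_clearance(pk, organ, inhibitor_prev, subject_effect)

            # morning trough, reflecting yesterday's dose
            measured = False
            trough = math.nan
            if d >= 1:
                trough = simulate_trough(prev_total, cl, pk, rng)
                measured = rng.random() >= config.level_skip_prob
                if measured:
                    minute = int(rng.integers(-15, 16))
                    ts = date + pd.Timedelta(hours=6, minutes=minute)
                    lab_rows.append(dict(patient_id=pid, analyte="tacrolimus",
                                         timestamp=ts.isoformat(),
                                         value=format_level(trough)))
                mu = prev_total / cl
                truth_rows.append(dict(
                    patient_id=pid, day=d, date=date.date().isoformat(),
                    organ=organ, daily_dose_prev=prev_total,
                    subject_effect=subject_effect,
                    inhibitor_factor=pk.inhibitor_effect if inhibitor_prev else 1.0,
                    effective_clearance=cl, mu_ng_ml=mu,
                    trough_ng_ml=trough, measured=measured))

            # titration on today's measured level
            if d >= 1 and measured and not math.isnan(trough):
                lo_w, hi_w = window_for(organ, d)
                if trough < lo_w:
                    daily_total = min(30.0, daily_total + 1.0)
                elif trough > hi_w:
                    daily_total = max(0.5, daily_total - 1.0)
                if rng.random() < 0.20:  # clinician variability
                    daily_total = float(np.clip(
                        daily_total + rng.choice([-2.0, -1.0, 1.0, 2.0]), 0.5, 30.0))
                daily_total = _round_half(daily_total)

            # administrations: BID tacrolimus with jittered clock times;
            # occasionally the day's doses are held (clinically routine), which
            # exercises the zero-dose/censoring path downstream
            today_total = 0.0 if rng.random() < config.hold_prob else daily_total
            am, pm = _split_bid(today_total)
            for dose, hour in ((am, 8), (pm, 20)):
                if dose <= 0:
                    continue
                minute = int(rng.integers(-90, 91))
                ts = date + pd.Timedelta(hours=hour, minutes=minute)
                admin_rows.append(dict(patient_id=pid, drug="tacrolimus",
                                       timestamp=ts.isoformat(), dose_mg=dose))
            for drug in INTERACTING_DRUGS:
                if d in drug_days[drug]:
                    ts = date + pd.Timedelta(hours=9, minutes=int(rng.integers(0, 60)))
                    admin_rows.append(dict(patient_id=pid, drug=drug,
                                           timestamp=ts.isoformat(),
                                           dose_mg=float(rng.integers(1, 10)) * 50.0
                                           if drug == "mycophenolate mofetil" else 1.0))
            prev_total = today_total

            # labs and vitals with missingness
            for analyte, (_, _, s_d) in LAB_BASELINES.items():
                lab_state[analyte] += rng.normal(0.0, s_d)
                if rng.random() >= config.missingness_rate:
                    ts = date + pd.Timedelta(hours=5, minutes=int(rng.integers(0, 45)))
                    lab_rows.append(dict(patient_id=pid, analyte=analyte,
                                         timestamp=ts.isoformat(),
                                         value=f"{max(0.1, lab_state[analyte]):.2f}"))
            for sign, (_, _, s_d) in VITAL_BASELINES.items():
                vital_state[sign] += rng.normal(0.0, s_d)
                if rng.random() >= config.missingness_rate:
                    ts = date + pd.Timedelta(hours=8, minutes=int(rng.integers(0, 60)))
                    vital_rows.append(dict(patient_id=pid, sign=sign,
                                           timestamp=ts.isoformat(),
                                           value=round(vital_state[sign], 2)))
            diet_rows.append(dict(patient_id=pid, date=date.date().isoformat(),
                                  meal_count=int(rng.integers(0, 4))))

    tables = RawTables(
        patients=pd.DataFrame(pat_rows),
        administrations=pd.DataFrame(admin_rows),
        labs=pd.DataFrame(lab_rows),
        vitals=pd.DataFrame(vital_rows),
        diet=pd.DataFrame(diet_rows),
    )
    ground_truth = pd.DataFrame(truth_rows)
    return tables, ground_truth


def noise_free_config(**overrides) -> CohortConfig:
    """A cohort config whose troughs are an exact function of observed data.

    Residual and within-subject noise are zero and there are no inhibitor
    episodes, so the next-day trough is fully determined by today's dose and
    the (level-inferable) per-patient clearance.
    """
    pk = PKParams(sigma_resid=0.0, omega_iov=0.0, rho_ar1=0.0)
    cfg = CohortConfig(pk=pk, drug_episode_rate=0.0, hold_prob=0.0, **overrides)
    return cfg
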