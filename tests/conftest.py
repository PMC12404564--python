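import pandas as pd
import pytest

from tacrodose import (CohortConfig, ForecasterConfig, TacrolimusForecaster,
                       generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared by read-only tests."""
    cfg = CohortConfig(n_patients=40, seed=7)
    tables, truth = generate_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def tiny_results():
    """A quickly trained forecaster for interface/causality tests.

    Accuracy does not matter here; recovery-quality checks train their own
    models at proper scale.
    """
    cfg = CohortConfig(n_patients=30, seed=3)
    tables, truth = generate_cohort(cfg)
    fc = ForecasterConfig(max_epochs=15, patience=15, seed=0)
    model = TacrolimusForecaster.from_tables(tables, fc, split_seed=1)
    return model.fit(), tables, truth


def make_raw_tables(patients_rows, admin_rows=(), lab_rows=(), vital_rows=(),
                    diet_rows=()):
    """Hand-built RawTables for eligibility / parsing tests."""
    from tacrodose import RawTables
    pat_cols = ["patient_id", "organ", "transplant_date", "age", "gender",
                "race", "ethnicity", "weight_kg", "height_cm", "hypertension",
                "diabetes_type"]
    defaults = dict(organ="kidney", transplant_date="2020-01-01", age=50,
                    gender="man", race="White", ethnicity="Non-Hispanic or Latino",
                    weight_kg=75.0, height_cm=170.0, hypertension=1,
                    diabetes_type="none")
    rows = []
    for r in patients_rows:
        row = dict(defaults)
        row.update(r)
        rows.append(row)
    return RawTables(
        patients=pd.DataFrame(rows, columns=pat_cols),
        administrations=pd.DataFrame(list(admin_rows),
                                     columns=["patient_id", "drug", "timestamp",
                                              "dose_mg"]),
        labs=pd.DataFrame(list(lab_rows),
                          columns=["patient_id", "analyte", "timestamp", "value"]),
        vitals=pd.DataFrame(list(vital_rows),
                            columns=["patient_id", "sign", "timestamp", "value"]),
        diet=pd.DataFrame(list(diet_rows),
                          columns=["patient_id", "date", "meal_count"]),
    )
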