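import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tacrodose import (FeatureSchema, bin_doses, build_cohort,
                       build_feature_frame, censor_resolve, split_cohort)
from tacrodose.features import ParseError, default_manifest

from conftest import make_raw_tables


class TestCensorResolve:
    @pytest.mark.parametrize("text,expected", [
        ("<2", 1.0), ("8.4", 8.4), ("2.0", 2.0), ("  <2 ", 1.0), ("12", 12.0),
    ])
    def test_values(self, text, expected):
        assert censor_resolve(text) == pytest.approx(expected)

    def test_garbage_raises(self):
        with pytest.raises(ParseError):
            censor_resolve("pending")


class TestBinDoses:
    def test_examples(self):
        day = pd.Timestamp("2020-01-05")
        ts = [pd.Timestamp("2020-01-05 06:00"), pd.Timestamp("2020-01-05 20:30")]
        assert bin_doses(ts, [2.0, 2.0], day).tolist() == [2.0, 0.0, 2.0]

    def test_half_open_boundary(self):
        day = pd.Timestamp("2020-01-05")
        b = bin_doses([pd.Timestamp("2020-01-05 08:00")], [3.0], day)
        assert b.tolist() == [0.0, 3.0, 0.0]

    def test_empty(self):
        assert bin_doses([], [], pd.Timestamp("2020-01-05")).tolist() == [0, 0, 0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 23), st.integers(0, 59),
                              st.floats(0.5, 10)), min_size=1, max_size=8))
    def test_bin_totals_conserve_daily_sum(self, admins):
        day = pd.Timestamp("2021-03-02")
        ts = [day + pd.Timedelta(hours=h, minutes=m) for h, m, _ in admins]
        doses = [d for _, _, d in admins]
        assert bin_doses(ts, doses, day).sum() == pytest.approx(sum(doses))


def _levels(pid, day_values):
    return [dict(patient_id=pid, analyte="tacrolimus",
                 timestamp=f"2020-01-{1 + d:02d} 06:00", value=str(v))
            for d, v in day_values]


class TestBuildCohort:
    def test_consecutive_levels_and_dose_after_measurement(self):
        raw = make_raw_tables(
            [dict(patient_id="A")],
            admin_rows=[dict(patient_id="A", drug="tacrolimus",
                             timestamp="2020-01-04 13:00", dose_mg=2.0)],
            lab_rows=_levels("A", [(3, 8.0), (4, 9.0)]))
        sel = build_cohort(raw)
        assert sel.prediction_days["A"] == [3]

    def test_nonconsecutive_levels_excluded(self):
        raw = make_raw_tables(
            [dict(patient_id="A")],
            admin_rows=[dict(patient_id="A", drug="tacrolimus",
                             timestamp="2020-01-04 13:00", dose_mg=2.0)],
            lab_rows=_levels("A", [(3, 8.0), (5, 9.0)]))
        sel = build_cohort(raw)
        assert sel.prediction_days == {}

    def test_dose_before_measurement_excluded(self):
        raw = make_raw_tables(
            [dict(patient_id="A")],
            admin_rows=[dict(patient_id="A", drug="tacrolimus",
                             timestamp="2020-01-04 05:00", dose_mg=2.0)],
            lab_rows=_levels("A", [(3, 8.0), (4, 9.0)]))
        assert build_cohort(raw).prediction_days == {}

    def test_minor_excluded(self):
        raw = make_raw_tables(
            [dict(patient_id="A", age=17)],
            admin_rows=[dict(patient_id="A", drug="tacrolimus",
                             timestamp="2020-01-04 13:00", dose_mg=2.0)],
            lab_rows=_levels("A", [(3, 8.0), (4, 9.0)]))
        sel = build_cohort(raw)
        assert sel.eligible == []
        assert sel.attrition["excluded_age"] == 1

    def test_attrition_accounting(self, small_cohort):
        _, tables, _ = small_cohort
        att = build_cohort(tables).attrition
        assert att["patients_in"] == (att["excluded_multi_organ"]
                                      + att["excluded_age"]
                                      + att["retained_after_filters"])
        assert att["retained_after_filters"] == (
            att["excluded_no_prediction_days"] + att["patients_retained"])


class TestSchema:
    def _frame(self, values, target=(5.0, 9.0)):
        n = len(values)
        return pd.DataFrame({
            "patient_id": ["P"] * n, "day": range(n), "organ": ["kidney"] * n,
            "is_prediction_day": [True] * n,
            "target_c0": list(np.linspace(*target, n)),
            "lab_creatinine": values,
        })

    def test_forward_fill(self):
        train = self._frame([5.0, np.nan, np.nan, 7.0])
        schema = FeatureSchema.fit(train, ["lab_creatinine"])
        out = schema.transform(train)
        # scaled with min 5 max 7: [0, 0, 0, 1]
        assert out["lab_creatinine"].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_global_median_fallback(self):
        train = self._frame([2.0, 6.0, 10.0, 6.0])
        schema = FeatureSchema.fit(train, ["lab_creatinine"])
        test = self._frame([np.nan, np.nan, np.nan, np.nan])
        out = schema.transform(test)
        # median 6 scales to (6-2)/8 = 0.5 everywhere
        assert out["lab_creatinine"].tolist() == [0.5] * 4

    def test_minmax_identity(self):
        train = self._frame([0.0, 10.0, 5.0, 10.0])
        schema = FeatureSchema.fit(train, ["lab_creatinine"])
        out = schema.transform(self._frame([5.0, 5.0, 5.0, 5.0]))
        assert out["lab_creatinine"].tolist() == [0.5] * 4

    def test_out_of_range_clips(self):
        train = self._frame([0.0, 10.0, 5.0, 10.0])
        schema = FeatureSchema.fit(train, ["lab_creatinine"])
        out = schema.transform(self._frame([-5.0, 20.0, 0.0, 10.0]))
        assert out["lab_creatinine"].tolist() == [0.0, 1.0, 0.0, 1.0]

    def test_missing_feature_hard_error(self):
        train = self._frame([1.0, 2.0, 3.0, 4.0])
        schema = FeatureSchema.fit(train, ["lab_creatinine"])
        schema.feature_names.append("lab_unknown")
        with pytest.raises(KeyError):
            schema.transform(train)

    def test_round_trip_in_unit_interval(self, small_cohort):
        _, tables, _ = small_cohort
        frame = build_feature_frame(tables)
        schema = FeatureSchema.fit(frame)
        out = schema.transform(frame)
        vals = out[schema.feature_names].to_numpy()
        assert np.isfinite(vals).all()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_json_round_trip(self, small_cohort):
        _, tables, _ = small_cohort
        frame = build_feature_frame(tables)
        schema = FeatureSchema.fit(frame)
        back = FeatureSchema.from_json(schema.to_json())
        assert back.feature_names == schema.feature_names
        assert back.target_max == schema.target_max


class TestSplit:
    def _patients(self, n_pre, n_test=0):
        rows = [dict(patient_id=f"P{i}", transplant_date=f"20{16 + i % 8}-06-01")
                for i in range(n_pre)]
        rows += [dict(patient_id=f"T{i}", transplant_date="2024-02-01")
                 for i in range(n_test)]
        return pd.DataFrame(rows)

    def test_ninety_ten(self):
        split = split_cohort(self._patients(100), seed=0)
        counts = pd.Series(split).value_counts()
        assert counts["train"] == 90 and counts["val"] == 10

    def test_test_year_goes_to_test(self):
        split = split_cohort(self._patients(20, n_test=3), seed=0)
        assert all(split[f"T{i}"] == "test" for i in range(3))

    def test_deterministic(self):
        p = self._patients(50, 5)
        assert split_cohort(p, seed=4) == split_cohort(p, seed=4)
        assert split_cohort(p, seed=4) != split_cohort(p, seed=5)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            split_cohort(self._patients(0, n_test=4), seed=0)

    def test_patient_level_no_overlap(self, small_cohort):
        _, tables, _ = small_cohort
        split = split_cohort(tables.patients, seed=3)
        frame = build_feature_frame(tables)
        by_patient = frame.groupby("patient_id").size()
        # every patient-day belongs to exactly the patient's single bucket
        assert set(split) >= set(by_patient.index)


class TestNoLeakage:
    def test_future_mutation_leaves_past_features_unchanged(self, small_cohort):
        _, tables, _ = small_cohort
        frame = build_feature_frame(tables)
        pred = frame[frame["is_prediction_day"]].iloc[0]
        pid, t = pred["patient_id"], int(pred["day"])

        mutated = type(tables)(patients=tables.patients.copy(),
                               administrations=tables.administrations.copy(),
                               labs=tables.labs.copy(), vitals=tables.vitals.copy(),
                               diet=tables.diet.copy())
        tx = pd.Timestamp(tables.patients.set_index("patient_id")
                          .loc[pid, "transplant_date"])
        ts = pd.to_datetime(mutated.labs["timestamp"])
        future = ((mutated.labs["patient_id"] == pid)
                  & (ts.dt.normalize() == tx + pd.Timedelta(days=t + 1))
                  & (mutated.labs["analyte"] != "tacrolimus"))
        assert future.any()
        mutated.labs.loc[future, "value"] = "999.0"
        frame2 = build_feature_frame(mutated)

        cols = default_manifest()
        a = frame[(frame["patient_id"] == pid) & (frame["day"] <= t)][cols]
        b = frame2[(frame2["patient_id"] == pid) & (frame2["day"] <= t)][cols]
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))
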