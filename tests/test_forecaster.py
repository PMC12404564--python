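import numpy as np
import pytest

from tacrodose import (FeatureSchema, ForecasterConfig, PatientSequence,
                       TacrolimusForecaster, recommend)
from tacrodose.features import DOSE_BIN_FEATURES
from tacrodose.forecaster import ForecasterResults


def _first_masked(results, split="test"):
    for seq in results.model.sequences[split]:
        idx = np.flatnonzero(seq.mask)
        if len(idx):
            return seq, int(idx[-1])
    raise AssertionError("no masked day in split")


class TestPrediction:
    def test_predictions_finite_nonnegative(self, tiny_results):
        results, _, _ = tiny_results
        preds = results.predictions("test")
        assert len(preds) > 0
        assert np.isfinite(preds["predicted_c0"]).all()
        assert (preds["predicted_c0"] >= 0).all()

    def test_causality_full_vs_prefix(self, tiny_results):
        """The day-(t+1) prediction from the prefix through t is unchanged by
        anything that happens after day t."""
        results, _, _ = tiny_results
        seq, i = _first_masked(results)
        full = results.net.predict(seq.x)
        prefix = results.net.predict(seq.x[:i + 1])
        assert full[i] == prefix[i]

    def test_empty_sequence_rejected(self, tiny_results):
        results, _, _ = tiny_results
        seq, _ = _first_masked(results)
        empty = PatientSequence(patient_id="x", organ="kidney",
                                days=np.array([], int),
                                x=np.zeros((0, seq.x.shape[1])),
                                y_scaled=np.array([]), y_raw=np.array([]),
                                mask=np.array([], bool))
        with pytest.raises(ValueError):
            results.predict_next_day(empty)


class TestPredictUnderDose:
    def test_actual_dose_reproduces_prediction(self, tiny_results):
        """Substituting the administered doses at the default times equals the
        factual prediction when the actual doses sat in those bins."""
        results, _, _ = tiny_results
        sch = results.schema
        cols = [sch.feature_names.index(b) for b in DOSE_BIN_FEATURES]

        def unscale(bin_name, v):
            return v * (sch.maxs[bin_name] - sch.mins[bin_name]) + sch.mins[bin_name]

        found = None
        for seq in results.model.sequences["test"]:
            for i in np.flatnonzero(seq.mask):
                if seq.x[i, cols[0]] == 0.0:  # nothing in the 0-8 h bin
                    found = (seq, int(i))
                    break
            if found:
                break
        assert found, "no test day with default-time dosing"
        seq, i = found
        am = unscale(DOSE_BIN_FEATURES[1], seq.x[i, cols[1]])
        pm = unscale(DOSE_BIN_FEATURES[2], seq.x[i, cols[2]])
        counterfactual = results.predict_under_dose(seq, i, am, pm)
        factual = float(results.predict_sequence(seq)[i])
        assert counterfactual == pytest.approx(factual, abs=1e-9)

    def test_no_mutation_of_sequence(self, tiny_results):
        results, _, _ = tiny_results
        seq, i = _first_masked(results)
        before = seq.x.copy()
        results.predict_under_dose(seq, i, 3.0, 3.0)
        np.testing.assert_array_equal(seq.x, before)

    def test_zero_dose_nonnegative(self, tiny_results):
        results, _, _ = tiny_results
        seq, i = _first_masked(results)
        assert results.predict_under_dose(seq, i, 0.0, 0.0) >= 0.0

    def test_negative_candidate_rejected(self, tiny_results):
        results, _, _ = tiny_results
        seq, i = _first_masked(results)
        with pytest.raises(ValueError):
            results.predict_under_dose(seq, i, -1.0, 2.0)


class TestRecommendIntegration:
    def test_recommend_returns_feasible_candidate(self, tiny_results):
        results, _, _ = tiny_results
        seq, i = _first_masked(results)
        prev = float(seq.prev_dose_total[i])
        rec = recommend(results, seq, i, prev)
        assert rec.recommended_total <= 1.5 * prev + 1e-9
        assert abs(rec.am - rec.pm) <= 1.0 + 1e-9
        assert rec.predicted_c0 >= 0.0


class TestPermutationImportance:
    def test_constant_feature_zero_degradation(self, tiny_results):
        results, _, _ = tiny_results
        # force one feature constant across the evaluation split
        name = results.schema.feature_names[0]
        for seq in results.model.sequences["test"]:
            seq.x[:, 0] = 0.42
        imp = results.permutation_importance("test", repeats=2, seed=0)
        row = imp[imp["feature"] == name].iloc[0]
        assert row["mean_degradation"] == pytest.approx(0.0, abs=1e-12)

    def test_report_shape_and_ranking(self, tiny_results):
        results, _, _ = tiny_results
        imp = results.permutation_importance("test", repeats=3, seed=1)
        assert set(imp["feature"]) == set(results.schema.feature_names)
        assert (imp["mean_degradation"].to_numpy()[:-1]
                >= imp["mean_degradation"].to_numpy()[1:]).all()
        assert imp["rank"].tolist() == list(range(1, len(imp) + 1))


class TestTrainingContracts:
    def _toy_sequences(self, rng, n, constant_target=None):
        seqs = []
        for k in range(n):
            T = 8
            x = rng.uniform(size=(T, 3))
            y_raw = (np.full(T, constant_target) if constant_target is not None
                     else 4.0 + 8.0 * x[:, 0])
            seqs.append(PatientSequence(
                patient_id=f"S{k}", organ="kidney", days=np.arange(1, T + 1),
                x=x, y_scaled=(y_raw - 2.0) / 14.0, y_raw=y_raw,
                mask=np.ones(T, bool)))
        return seqs

    def _schema(self):
        schema = FeatureSchema(feature_names=["f0", "f1", "f2"])
        for f in schema.feature_names:
            schema.mins[f], schema.maxs[f], schema.medians[f] = 0.0, 1.0, 0.5
        schema.target_min, schema.target_max = 2.0, 16.0
        return schema

    def test_constant_target_learned(self):
        rng = np.random.default_rng(0)
        seqs = self._toy_sequences(rng, 12, constant_target=8.0)
        model = TacrolimusForecaster(
            {"train": seqs[:10], "val": seqs[10:], "test": seqs[10:]},
            self._schema(),
            ForecasterConfig(max_epochs=300, patience=300, seed=0, oversample=False,
                             dropout=0.0, learning_rate=5e-3, batch_size=4))
        results = model.fit()
        preds = results.predictions("test")["predicted_c0"]
        assert np.abs(preds - 8.0).max() < 0.2

    def test_single_patient_training_runs(self):
        rng = np.random.default_rng(1)
        seqs = self._toy_sequences(rng, 2)
        model = TacrolimusForecaster(
            {"train": seqs[:1], "val": seqs[1:], "test": seqs[1:]},
            self._schema(), ForecasterConfig(max_epochs=3, patience=3, seed=0))
        results = model.fit()
        assert len(results.predictions("test")) > 0

    def test_empty_training_set_rejected(self):
        model = TacrolimusForecaster({"train": [], "val": [], "test": []},
                                     self._schema(), ForecasterConfig())
        with pytest.raises(ValueError):
            model.fit()

    def test_checkpoint_round_trip(self, tiny_results, tmp_path):
        results, _, _ = tiny_results
        path = tmp_path / "model.ckpt.npz"
        results.save(path)
        back = ForecasterResults.load(path)
        seq, i = _first_masked(results)
        np.testing.assert_allclose(back.net.predict(seq.x),
                                   results.net.predict(seq.x), atol=0)
        assert back.schema.feature_names == results.schema.feature_names
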