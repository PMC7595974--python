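"""Fingerprint kernel, double-CV training and population prediction."""

import numpy as np
import pytest

from analogscope.global_model import (
    ModelEvaluation,
    evaluate,
    fingerprint,
    fingerprint_matrix,
    predict_population,
    split_series_for_training,
    tanimoto_kernel,
    train_global_model,
)
from analogscope.records import CompoundRecord
from analogscope.synthetic import SeriesGeneratorSpec, generate_series, generate_va_pool


@pytest.fixture(scope="module")
def trainable_series():
    spec = SeriesGeneratorSpec(
        n_sites=3,
        substituents_per_site=7,
        n_eas=120,
        noise_sd=0.1,
        seed=11,
    )
    return generate_series(spec)


class TestKernel:
    def test_identical_nonzero_fingerprints_give_one(self):
        fp = fingerprint("c1ccccc1CCO")
        assert tanimoto_kernel(fp, fp) == pytest.approx(1.0)

    def test_disjoint_bit_sets_give_zero(self):
        a = np.zeros(8)
        b = np.zeros(8)
        a[:4] = 1
        b[4:] = 1
        assert tanimoto_kernel(a, b) == 0.0

    def test_symmetry(self):
        fa, fb = fingerprint("CCO"), fingerprint("CCN")
        assert tanimoto_kernel(fa, fb) == pytest.approx(tanimoto_kernel(fb, fa))

    def test_all_zero_pair_warns_and_returns_zero(self):
        z = np.zeros(16)
        with pytest.warns(UserWarning, match="all-zero"):
            assert tanimoto_kernel(z, z) == 0.0

    def test_kernel_matrix_positive_semidefinite(self, trainable_series):
        fps = fingerprint_matrix(trainable_series.series.analogs[:100])
        k = tanimoto_kernel(fps)
        eigvals = np.linalg.eigvalsh(k)
        assert eigvals.min() >= -1e-8

    def test_fingerprint_has_expected_shape_and_bits(self):
        fp = fingerprint("CCO")
        assert fp.shape == (2048,)
        assert fp.sum() > 0


class TestEvaluate:
    def test_perfect_predictions(self):
        class Fake:
            method = "ridge"

            def predict(self, records):
                return np.array([r.potency for r in records])

        recs = [CompoundRecord(f"r{i}", "C" * (i + 1), 5.0 + i) for i in range(3)]
        ev = evaluate(Fake(), recs)
        assert ev.r_squared == pytest.approx(1.0)
        assert ev.mae == pytest.approx(0.0)

    def test_hand_computed_three_point_example(self):
        class Fake:
            def predict(self, records):
                return np.array([5.0, 6.0, 8.0])

        recs = [CompoundRecord(f"r{i}", "C" * (i + 1), p) for i, p in enumerate([5.0, 6.0, 7.0])]
        ev = evaluate(Fake(), recs)
        assert ev.mae == pytest.approx(1 / 3)
        assert ev.r_squared == pytest.approx(0.5)

    def test_constant_prediction_gives_zero_r_squared(self):
        class Fake:
            def predict(self, records):
                return np.full(len(records), 6.0)

        recs = [CompoundRecord(f"r{i}", "C" * (i + 1), p) for i, p in enumerate([5.0, 6.0, 7.0])]
        assert evaluate(Fake(), recs).r_squared == pytest.approx(0.0)


class TestTraining:
    def test_outer_cv_recovers_additive_signal(self, trainable_series):
        model = train_global_model(
            trainable_series.series.analogs, method="svr", seed=0
        )
        assert model.outer_cv.r_squared > 0.7

    def test_permuted_labels_give_near_zero_r_squared(self, trainable_series):
        recs = trainable_series.series.analogs
        rng = np.random.default_rng(0)
        perm = rng.permutation([r.potency for r in recs])
        shuffled = [
            CompoundRecord(r.identifier, r.smiles, float(p))
            for r, p in zip(recs, perm)
        ]
        model = train_global_model(shuffled, method="svr", seed=0)
        assert model.outer_cv.r_squared < 0.2

    def test_training_set_evaluation_is_optimistic_bound(self, trainable_series):
        recs = trainable_series.series.analogs
        model = train_global_model(recs, method="svr", seed=0)
        ev = evaluate(model, recs)
        assert ev.r_squared >= model.outer_cv.r_squared

    def test_ridge_also_learns(self, trainable_series):
        model = train_global_model(
            trainable_series.series.analogs, method="ridge", seed=0
        )
        assert model.outer_cv.r_squared > 0.7

    def test_deterministic_given_seed(self, trainable_series):
        recs = trainable_series.series.analogs
        a = train_global_model(recs, method="ridge", seed=3)
        b = train_global_model(recs, method="ridge", seed=3)
        assert a.outer_cv.r_squared == b.outer_cv.r_squared
        assert a.best_params == b.best_params

    def test_single_valued_potencies_rejected(self):
        recs = [CompoundRecord(f"r{i}", "C" * (i + 1), 6.0) for i in range(40)]
        with pytest.raises(ValueError, match="degenerate"):
            train_global_model(recs, method="ridge", seed=0)

    def test_small_training_set_warns(self):
        recs = [
            CompoundRecord(f"r{i}", "C" * (i + 1), 5.0 + 0.1 * i) for i in range(10)
        ]
        with pytest.warns(UserWarning, match="training compounds"):
            train_global_model(recs, method="ridge", seed=0)


class TestSplitAndPopulation:
    def test_split_halves_series_and_keeps_background_in_train(self, trainable_series):
        eas = trainable_series.series.analogs
        bg = [CompoundRecord(f"bg{i}", "C" * (i + 2), 5.0) for i in range(10)]
        train, holdout = split_series_for_training(eas, bg, seed=1)
        assert len(holdout) + (len(train) - len(bg)) == len(eas)
        assert abs(len(holdout) - len(eas) / 2) <= 2
        assert {r.identifier for r in bg} <= {r.identifier for r in train}
        # both halves span the potency range (stratified split)
        y_tr = [r.potency for r in train[len(bg):]]
        y_ho = [r.potency for r in holdout]
        assert np.ptp(y_tr) > 0.5 * np.ptp([r.potency for r in eas])
        assert np.ptp(y_ho) > 0.5 * np.ptp([r.potency for r in eas])

    def test_training_compounds_predicted_near_their_potency(self, trainable_series):
        recs = trainable_series.series.analogs
        model = train_global_model(recs, method="svr", seed=0)
        preds = model.predict(recs[:20])
        truth = np.array([r.potency for r in recs[:20]])
        assert np.abs(preds - truth).mean() < 0.3

    def test_empty_population_gives_empty_output(self, trainable_series):
        model = train_global_model(
            trainable_series.series.analogs, method="ridge", seed=0
        )
        ranked, summary = predict_population(model, [])
        assert ranked == [] and summary == {}

    def test_ranking_descending_with_smiles_tiebreak(self, trainable_series):
        model = train_global_model(
            trainable_series.series.analogs, method="ridge", seed=0
        )
        vas = generate_va_pool(trainable_series, 60, "recombination", seed=5)
        ranked, summary = predict_population(model, vas)
        preds = [p for _, p in ranked]
        assert preds == sorted(preds, reverse=True)
        # quantile summary matches a direct quantile oracle
        vals = [p for _, p in ranked]
        q = summary["close_in_VA"]
        assert q["median"] == pytest.approx(float(np.median(vals)))
        assert q["n"] == len(vas)
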