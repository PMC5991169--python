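import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iseeg.features import SubjectFeatureVector
from iseeg.individualized_prediction import (SubjectData, compute_diffs,
                                             compute_weights, loocv_evaluate,
                                             mean_absolute_error, paired_ttest,
                                             predict_with_model,
                                             results_frame, summarize,
                                             weighted_predict)
from iseeg.lep_pain_model import LepPainModel


def make_vector(sid, values):
    idx = pd.MultiIndex.from_tuples(
        [("Cz", "full", "rms"), ("Cz", "alpha-2", "nmssd")][:len(values)],
        names=["channel", "band", "feature"])
    return SubjectFeatureVector(sid, pd.Series(list(values), index=idx))


class TestPredictWithModel:
    def test_affine_evaluation(self):
        m = LepPainModel("S", a=0.1, b=1.0, c=10.0, d=-10.0,
                         n_fast_trials=5, fit_r=1.0)
        assert predict_with_model(50.0, m) == pytest.approx(6.0)

    def test_zero_amplitude_gives_intercept(self):
        m = LepPainModel("S", a=0.1, b=1.0, c=10.0, d=-10.0,
                         n_fast_trials=5, fit_r=1.0)
        assert predict_with_model(0.0, m) == pytest.approx(1.0)

    def test_own_noise_free_trials_roundtrip(self):
        from iseeg.lep_pain_model import fit_lep_pain
        y = np.array([5.0, 6.0, 7.0, 8.0])
        x = 6.0 * y + 20.0
        m = fit_lep_pain(x, y)
        np.testing.assert_allclose(predict_with_model(x, m), y, atol=1e-9)


class TestComputeDiffs:
    def test_identical_vectors(self):
        v = make_vector("t", [3.0, 0.005])
        d = compute_diffs(v, [make_vector("a", [3.0, 0.005])],
                          list(v.values.index))
        assert d[0] == pytest.approx(0.0)

    def test_single_key_absolute_difference(self):
        test = make_vector("t", [5.0])
        train = [make_vector("a", [3.0]), make_vector("b", [9.0])]
        d = compute_diffs(test, train, [("Cz", "full", "rms")],
                          standardize=False)
        np.testing.assert_allclose(d, [2.0, 4.0])

    def test_pythagorean_unstandardized(self):
        test = make_vector("t", [0.0, 0.0])
        train = [make_vector("a", [3.0, 4.0])]
        d = compute_diffs(test, train, list(test.values.index),
                          standardize=False)
        assert d[0] == pytest.approx(5.0)

    def test_standardization_from_training_only(self):
        train = [make_vector(f"s{i}", [v, 0.0]) for i, v in
                 enumerate([1.0, 2.0, 3.0, 4.0])]
        test = make_vector("t", [10.0, 0.0])
        d = compute_diffs(test, train, list(test.values.index),
                          standardize=True)
        # z-score of 10 under train mean 2.5, sd sqrt(1.25)
        z = (10 - 2.5) / np.sqrt(1.25)
        zt = (np.array([1, 2, 3, 4]) - 2.5) / np.sqrt(1.25)
        np.testing.assert_allclose(d, np.abs(z - zt))

    def test_missing_key_raises(self):
        v = make_vector("t", [3.0])
        with pytest.raises(KeyError):
            compute_diffs(v, [v], [("Cz", "beta", "rms")])

    def test_empty_keys_raise(self):
        v = make_vector("t", [3.0])
        with pytest.raises(ValueError):
            compute_diffs(v, [v], [])


class TestComputeWeights:
    def test_hand_example(self):
        # diffs [1, 2, 3, 10]: mean 4, max 10 -> [9, 8, 7, 0]
        np.testing.assert_allclose(compute_weights([1.0, 2.0, 3.0, 10.0]),
                                   [9.0, 8.0, 7.0, 0.0])

    def test_all_equal_diffs_degenerate(self):
        np.testing.assert_allclose(compute_weights([2.0, 2.0, 2.0]),
                                   [0.0, 0.0, 0.0])

    def test_equal_to_mean_kept(self):
        # "larger than the mean" is strict; a diff equal to the mean stays
        w = compute_weights([1.0, 2.0, 3.0])
        np.testing.assert_allclose(w, [2.0, 1.0, 0.0])
        assert w[1] == pytest.approx(3.0 - 2.0)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1,
                    max_size=30))
    def test_rule_properties(self, diffs):
        diffs = np.asarray(diffs)
        w = compute_weights(diffs)
        assert (w >= 0).all()
        # above-mean diffs are zeroed
        assert (w[diffs > diffs.mean()] == 0).all()
        # nearest subject gets the largest weight
        assert w[np.argmin(diffs)] == w.max()
        # someone keeps nonzero weight unless all diffs are equal
        if np.ptp(diffs) > 0:
            assert w.max() > 0

    def test_negative_diff_raises(self):
        with pytest.raises(ValueError):
            compute_weights([-1.0, 2.0])


class TestWeightedPredict:
    def test_hand_example(self):
        # (9*5 + 8*6 + 7*7) / 24 = 142/24
        value = weighted_predict([5.0, 6.0, 7.0, 9.0], [9.0, 8.0, 7.0, 0.0])
        assert value == pytest.approx(142 / 24)

    def test_uniform_weights_mean(self):
        assert weighted_predict([1.0, 2.0, 6.0], [2.0, 2.0, 2.0]) == \
            pytest.approx(3.0)

    def test_single_nonzero_weight(self):
        assert weighted_predict([1.0, 2.0, 6.0], [0.0, 5.0, 0.0]) == 2.0

    def test_zero_weights_fallback_to_mean(self):
        assert weighted_predict([1.0, 2.0, 6.0], [0.0, 0.0, 0.0]) == \
            pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_predict([1.0, 2.0], [1.0])

    @given(st.lists(st.floats(min_value=0, max_value=9), min_size=2,
                    max_size=10))
    def test_convex_hull(self, preds):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, len(preds))
        w[rng.integers(0, len(preds))] = 0
        value = weighted_predict(preds, w)
        active = [p for p, wi in zip(preds, w) if wi > 0] or preds
        assert min(active) - 1e-9 <= value <= max(active) + 1e-9


class TestMae:
    def test_zero_for_perfect_prediction(self):
        assert mean_absolute_error([5, 6], [5, 6]) == 0.0

    def test_hand_example(self):
        assert mean_absolute_error([5.0, 6.0], [5.5, 6.5]) == pytest.approx(0.5)


class TestPairedTtest:
    def test_hand_example(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2 * sqrt(3)
        t, p = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert 0 < p < 1

    def test_antisymmetry(self):
        a, b = [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_mean_differences(self):
        t, _ = paired_ttest([1.0, -1.0, 2.0, -2.0], [0.0, 0.0, 0.0, 0.0])
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])


def synthetic_cohort_data(n_subjects, seed, heterogeneity=True):
    """Feature-level cohort: trials from exact linear models plus noise, and
    feature vectors that echo each subject's latent traits."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        magnitude = rng.uniform(5, 15) if heterogeneity else 10.0
        freq = rng.uniform(11, 13) if heterogeneity else 12.0
        d = 5 + 2 * magnitude + rng.normal(0, 1.0)
        c = 6 - 2 * (freq - 12) + rng.normal(0, 0.2)
        y = np.repeat(np.arange(5, 9), 5).astype(float)
        x = c * y + d + rng.normal(0, 1.0, y.size)
        trials = pd.DataFrame({"trial_index": np.arange(y.size),
                               "rating": y.astype(int), "n2p2_uV": x})
        nm = 2 * (1 - np.cos(2 * np.pi * freq / 1000))
        vec = make_vector(f"S{i:03d}",
                          [magnitude * (1 + rng.normal(0, 0.05)),
                           nm * (1 + rng.normal(0, 0.05))])
        subjects.append(SubjectData(f"S{i:03d}", trials, vec))
    return subjects


class TestLoocv:
    def test_perfect_cohort_zero_mae(self):
        # identical exact linear subjects: every scheme is exact
        subjects = synthetic_cohort_data(5, seed=0, heterogeneity=False)
        for s in subjects:
            s.trials["n2p2_uV"] = 6.0 * s.trials["rating"] + 25.0
        results = loocv_evaluate(subjects, feature_selection="all")
        for r in results:
            assert r.mae_individualized == pytest.approx(0.0, abs=1e-9)
            assert r.mae_conventional == pytest.approx(0.0, abs=1e-9)

    def test_excluded_subject_skipped(self):
        subjects = synthetic_cohort_data(6, seed=1)
        # cap one subject's ratings below 7 -> fails inclusion
        bad = subjects[2]
        bad.trials["rating"] = np.minimum(bad.trials["rating"], 6)
        results = loocv_evaluate(subjects, feature_selection="all")
        assert len(results) == 5
        assert all(r.subject_id != "S002" for r in results)

    def test_individualized_beats_conventional_on_heterogeneous_cohort(self):
        wins = 0
        for seed in range(10):
            subjects = synthetic_cohort_data(20, seed=seed)
            results = loocv_evaluate(subjects, feature_selection="all")
            s = summarize(results)
            wins += s["mae_individualized_mean"] < s["mae_conventional_mean"]
        assert wins >= 8

    def test_homogeneous_cohort_schemes_indistinguishable(self):
        # with no cross-subject heterogeneity, weighting brings no gain; the
        # average per-seed MAE difference stays within a few percent of the
        # conventional MAE (tiny positive bias from averaging fewer models)
        diffs, conv = [], []
        for seed in range(10):
            subjects = synthetic_cohort_data(20, seed=seed,
                                             heterogeneity=False)
            results = loocv_evaluate(subjects, feature_selection="all")
            df = results_frame(results)
            diffs.append((df["mae_individualized"]
                          - df["mae_conventional"]).mean())
            conv.append(df["mae_conventional"].mean())
        assert abs(np.mean(diffs)) < 0.1 * np.mean(conv)

    def test_too_few_subjects_raise(self):
        subjects = synthetic_cohort_data(2, seed=0)
        with pytest.raises(ValueError):
            loocv_evaluate(subjects, feature_selection="all")

    def test_reproducible(self):
        a = loocv_evaluate(synthetic_cohort_data(8, seed=5),
                           feature_selection="all")
        b = loocv_evaluate(synthetic_cohort_data(8, seed=5),
                           feature_selection="all")
        for ra, rb in zip(a, b):
            assert ra.mae_individualized == rb.mae_individualized
            assert ra.mae_conventional == rb.mae_conventional
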