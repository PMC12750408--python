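import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dyespy import (
    cosine_similarity,
    shuffle_mixture_ids,
    welch_one_tailed,
    youden_threshold,
)
from dyespy.exceptions import CalibrationError, DataError, UsageError


class TestCosineSimilarity:
    def test_closed_forms(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-9
        )

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_positive_scale_invariance_and_symmetry(self, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert cosine_similarity(scale * a, b) == pytest.approx(
            cosine_similarity(a, b), abs=1e-9
        )
        assert cosine_similarity(a, b) == pytest.approx(
            cosine_similarity(b, a), abs=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError):
            cosine_similarity([0.0, 0.0], [1.0, 1.0])


class TestWelch:
    def test_identical_samples_give_t0_p_half(self):
        x = [0.1, 0.5, 0.9]
        r = welch_one_tailed(x, list(x), "greater")
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p_one_tailed == pytest.approx(0.5, abs=1e-12)

    def test_swapping_samples_flips_sign_and_maps_p(self, rng):
        x, y = rng.normal(0.9, 0.05, 8), rng.normal(0.7, 0.05, 6)
        a = welch_one_tailed(x, y, "greater")
        b = welch_one_tailed(y, x, "greater")
        assert b.t == pytest.approx(-a.t, abs=1e-12)
        assert b.p_one_tailed == pytest.approx(1.0 - a.p_one_tailed, abs=1e-12)

    def test_matches_direct_formula_evaluation(self):
        x = np.array([0.85, 0.9, 0.95, 0.9])
        y = np.array([0.7, 0.75, 0.8, 0.72])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 4 + vy / 4
        t_expect = (x.mean() - y.mean()) / np.sqrt(se2)
        df_expect = se2**2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
        p_expect = float(stats.t.sf(t_expect, df_expect))
        r = welch_one_tailed(x, y, "greater")
        assert r.t == pytest.approx(t_expect, abs=1e-10)
        assert r.df == pytest.approx(df_expect, abs=1e-10)
        assert r.p_one_tailed == pytest.approx(p_expect, abs=1e-10)

    def test_agrees_with_scipy_welch(self, rng):
        x, y = rng.normal(1.0, 0.2, 12), rng.normal(0.8, 0.4, 9)
        r = welch_one_tailed(x, y, "greater")
        ref = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p_one_tailed == pytest.approx(ref.pvalue, abs=1e-10)

    def test_undersized_sample_rejected(self):
        with pytest.raises(UsageError):
            welch_one_tailed([1.0], [1.0, 2.0])


class TestShuffleMixtureIds:
    def test_two_distinct_ids_swap(self):
        assert shuffle_mixture_ids(["m1", "m2"], seed=0) == ["m2", "m1"]

    def test_single_sample_and_identical_ids_rejected(self):
        with pytest.raises(CalibrationError):
            shuffle_mixture_ids(["m1"], seed=0)
        with pytest.raises(CalibrationError):
            shuffle_mixture_ids(["m1", "m1", "m1"], seed=0)

    def test_no_fixed_points_and_deterministic(self):
        ids = [f"m{i}" for i in range(10)]
        a = shuffle_mixture_ids(ids, seed=42)
        b = shuffle_mixture_ids(ids, seed=42)
        assert a == b
        assert sorted(a) == sorted(ids)
        assert all(x != y for x, y in zip(a, ids))

    def test_repeated_ids_still_fully_mismatched(self):
        ids = ["m1", "m1", "m2", "m2", "m3", "m3"]
        out = shuffle_mixture_ids(ids, seed=3)
        assert all(x != y for x, y in zip(out, ids))


def brute_force_youden(true_scores, false_scores, lo=0.0, hi=1.2, step=0.0005):
    ts, fs = np.asarray(true_scores), np.asarray(false_scores)
    best = None
    for theta in np.arange(lo, hi + step, step):
        j = np.mean(ts >= theta) - np.mean(fs >= theta)
        if best is None or j > best[0] + 1e-12:
            best = (j, theta)
    return best


class TestYoudenThreshold:
    def test_perfect_separation(self):
        cal = youden_threshold([0.9, 0.95, 0.92], [0.5, 0.6, 0.4])
        assert cal.j == pytest.approx(1.0)
        assert cal.accuracy == pytest.approx(1.0)
        assert cal.fpr == 0.0 and cal.fnr == 0.0
        assert 0.6 < cal.threshold < 0.9

    def test_identical_multisets_give_zero_j(self):
        s = [0.3, 0.5, 0.7]
        cal = youden_threshold(s, list(s))
        assert cal.j == pytest.approx(0.0)

    def test_example_matches_fine_scan(self):
        true = [0.9, 0.95, 0.8]
        false = [0.85, 0.6, 0.7]
        cal = youden_threshold(true, false)
        j_scan, _ = brute_force_youden(true, false, lo=0.5, hi=1.1, step=0.001)
        assert cal.j == pytest.approx(j_scan, abs=1e-12)
        ts, fs = np.asarray(true), np.asarray(false)
        assert np.mean(ts >= cal.threshold) - np.mean(fs >= cal.threshold) == (
            pytest.approx(cal.j)
        )

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(500):
            n_t = int(rng.integers(1, 12))
            n_f = int(rng.integers(1, 12))
            true = np.round(rng.random(n_t), 3)
            false = np.round(rng.random(n_f), 3)
            cal = youden_threshold(true, false)
            j_scan, _ = brute_force_youden(true, false)
            assert cal.j == pytest.approx(j_scan, abs=1e-9)

    def test_empty_scores_rejected(self):
        with pytest.raises(CalibrationError):
            youden_threshold([], [0.5])
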