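import itertools
from math import factorial

import numpy as np
import pytest

from octtrend import classify_permutation, cohort_permutation_table, permute_slopes
from octtrend.cohort import EyeSeries
from octtrend.exceptions import ParameterError
from octtrend.slr import STABLE, WORSENING


def series(t, y, eye="e1", measure="RNFL", sector="G"):
    return EyeSeries(eye, measure, sector, np.asarray(t, float), np.asarray(y, float))


def brute_force_tail_p(t, y):
    """Exhaustive lower/upper tail probabilities by full enumeration."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    w = tc / (tc @ tc)
    obs = float(y @ w)
    slopes = [float(np.asarray(p) @ w) for p in (np.array(pi) for pi in itertools.permutations(y))]
    slopes = np.array(slopes)
    eps = 1e-9 * max(1.0, abs(obs), float(np.abs(slopes).max()))
    return np.mean(slopes <= obs + eps), np.mean(slopes >= obs - eps)


class TestPermuteSlopes:
    def test_constant_series_all_zero(self):
        s = permute_slopes(series([0, 1, 2, 3], [5, 5, 5, 5]))
        assert np.allclose(s, 0.0)

    def test_three_points_exhaustive_six_slopes(self):
        s = permute_slopes(series([0, 1, 2], [1.0, 2.0, 4.0]))
        assert len(s) == 6

    def test_exhaustive_mean_is_exactly_zero(self):
        # E over uniform permutations of sum (t_i - tbar)(y_pi(i) - ybar) = 0
        s = permute_slopes(series([0, 0.5, 1.3, 2.0, 3.1], [7.0, 3.0, 9.0, 1.0, 4.0]))
        assert len(s) == factorial(5)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)

    def test_sampled_mode_size_and_determinism(self):
        s = series(np.arange(8) * 0.5, np.arange(8.0) + np.sin(np.arange(8)))
        a = permute_slopes(s, n_perm=500, seed=3)
        b = permute_slopes(s, n_perm=500, seed=3)
        assert len(a) == 500
        assert np.array_equal(a, b)

    def test_small_n_perm_rejected_in_sampled_mode(self):
        s = series(np.arange(8) * 0.5, np.arange(8.0))
        with pytest.raises(ParameterError):
            permute_slopes(s, n_perm=50, seed=0)


class TestClassifyPermutation:
    def test_four_point_decreasing_is_stable(self, decreasing_series):
        # unique minimum among 24 orderings: p_lower = 1/24 > 0.025
        r = classify_permutation(decreasing_series)
        assert r.exhaustive and r.n_perm == 24
        assert r.p_lower == pytest.approx(1 / 24)
        assert r.observed_slope == pytest.approx(-1.0)
        assert r.label == STABLE

    def test_five_point_decreasing_is_worsening(self):
        r = classify_permutation(series([0, 1, 2, 3, 4], [5, 4, 3, 2, 1]))
        assert r.p_lower == pytest.approx(1 / 120)
        assert r.label == WORSENING

    def test_constant_series_stable_with_p_one(self):
        r = classify_permutation(series([0, 1, 2, 3], [5, 5, 5, 5]))
        assert r.p_lower == 1.0 and r.p_upper == 1.0
        assert r.label == STABLE

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for n in (4, 5, 6):
            t = np.sort(rng.uniform(0, 4, n))
            y = 60 - rng.uniform(0, 2) * t + rng.normal(0, 1, n)
            r = classify_permutation(series(t, y), n_perm=1000)
            lo, up = brute_force_tail_p(t, y)
            assert r.exhaustive
            assert r.p_lower == pytest.approx(lo, abs=1e-12)
            assert r.p_upper == pytest.approx(up, abs=1e-12)

    def test_sampled_p_converges_to_exhaustive(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 4, 6))
        y = 60 - 1.2 * t + rng.normal(0, 1.5, 6)
        s = series(t, y)
        exact = classify_permutation(s, n_perm=720)  # exhaustive (6! = 720)
        sampled = classify_permutation(s, n_perm=600, seed=1)  # forced sampling
        assert exact.exhaustive and not sampled.exhaustive
        # +1-corrected sampled p within Monte-Carlo error of the exact value
        se = np.sqrt(exact.p_lower * (1 - exact.p_lower) / 600)
        assert abs(sampled.p_lower - exact.p_lower) < 4 * se + 1 / 600

    def test_bad_cutoffs_rejected(self, decreasing_series):
        with pytest.raises(ParameterError):
            classify_permutation(decreasing_series, lower_pct=97.5, upper_pct=2.5)

    def test_superuniform_null_p(self):
        """P(p_lower <= a) <= a (+MC error) for exchangeable null series."""
        rng = np.random.default_rng(30)
        t = np.arange(10) * 0.5
        n_sim = 400
        p_lowers = np.empty(n_sim)
        for i in range(n_sim):
            y = 60 + rng.normal(0, 2, 10)
            p_lowers[i] = classify_permutation(series(t, y), n_perm=400, seed=[30, i]).p_lower
        for a in (0.01, 0.025, 0.05):
            rate = np.mean(p_lowers <= a)
            assert rate <= a + 3 * np.sqrt(a * (1 - a) / n_sim)


class TestCohortTable:
    def _batch(self, n=14):
        rng = np.random.default_rng(6)
        t = np.arange(8) * 0.5
        return [
            series(t, 60 - 0.5 * t + rng.normal(0, 1, 8), eye=f"e{i}")
            for i in range(n)
        ]

    def test_cardinality_and_reproducibility(self):
        batch = self._batch()
        a = cohort_permutation_table(batch, n_perm=200, seed=9)
        b = cohort_permutation_table(batch, n_perm=200, seed=9)
        assert len(a) == 14
        assert a.equals(b)

    def test_order_invariance(self):
        batch = self._batch()
        a = cohort_permutation_table(batch, n_perm=200, seed=9)
        b = cohort_permutation_table(list(reversed(batch)), n_perm=200, seed=9)
        assert a.equals(b)

    def test_exhaustive_results_ignore_seed(self, decreasing_series):
        a = cohort_permutation_table([decreasing_series], n_perm=1000, seed=1)
        b = cohort_permutation_table([decreasing_series], n_perm=1000, seed=2)
        assert a.equals(b)

    def test_empty_collection_rejected(self):
        with pytest.raises(ParameterError):
            cohort_permutation_table([], n_perm=200, seed=0)
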