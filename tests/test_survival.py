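"""NPMLE, longevity, bootstrap, logrank and turnover tests.

Oracles: a literal-loop EM implementation (independent of the vectorized
path), lifelines' Kaplan-Meier for right-censored data, closed-form
distribution quantities for simulated recovery, and exhaustive label
enumeration for tiny permutation distributions.
"""

import itertools

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from rootdyn.records import IntervalCensoredSet
from rootdyn.survival import (
    bootstrap_ci,
    estimate_longevity,
    finkelstein_scores,
    logrank_interval,
    logrank_scores,
    mean_longevity,
    median_longevity,
    survival_at,
    turnbull_npmle,
    turnover,
)

from conftest import grid_censor, make_interval_set


# ---------------------------------------------------------------------------
# Brute-force oracle: plain-Python Turnbull EM
# ---------------------------------------------------------------------------


def brute_force_em(intervals, tol=1e-12, max_iter=200_000):
    """Literal self-consistency iteration over explicitly enumerated
    candidate intervals (every (l, r] with l a left and r a right endpoint
    and no other endpoint strictly inside); no vectorization shared with
    the implementation under test."""
    lefts = sorted({l for l, _ in intervals})
    rights = sorted({r for _, r in intervals})
    pts = sorted(set(lefts) | set(rights))
    candidates = []
    for l in lefts:
        for r in rights:
            if r <= l:
                continue
            if any(l < p < r for p in pts):
                continue
            candidates.append((l, r))
    m = len(candidates)
    p = [1.0 / m] * m
    contains = [
        [1.0 if (L <= l and r <= R) else 0.0 for (l, r) in candidates]
        for (L, R) in intervals
    ]
    for _ in range(max_iter):
        new = [0.0] * m
        for row in contains:
            denom = sum(a * pj for a, pj in zip(row, p))
            for j in range(m):
                new[j] += row[j] * p[j] / denom
        total = sum(new)
        new = [x / total for x in new]
        if max(abs(a - b) for a, b in zip(new, p)) < tol:
            return candidates, new
        p = new
    raise RuntimeError("oracle EM did not converge")


class TestTurnbull:
    def test_exact_times_reduce_to_ecdf_complement(self):
        curve = turnbull_npmle((np.array([1.0, 2, 3]), np.array([1.0, 2, 3])))
        assert np.allclose(curve.mass, 1 / 3)
        assert survival_at(curve, 0.0) == pytest.approx(1.0)
        assert survival_at(curve, 1.0) == pytest.approx(2 / 3)
        assert survival_at(curve, 2.5) == pytest.approx(1 / 3)
        assert survival_at(curve, 3.0) == pytest.approx(0.0)

    def test_right_censored_only_equals_kaplan_meier(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 60)
        c = rng.exponential(14, 60)
        obs = np.minimum(t, c)
        event = t <= c
        curve = turnbull_npmle((obs, np.where(event, obs, np.inf)), tol=1e-11)
        km = KaplanMeierFitter().fit(obs, event)
        grid = np.sort(np.concatenate([obs, obs - 1e-9]))
        mine = np.array([survival_at(curve, x) for x in grid])
        theirs = km.survival_function_at_times(grid).to_numpy()
        assert np.max(np.abs(mine - theirs)) < 1e-8

    def test_overlapping_toy_matches_brute_force_oracle(self):
        intervals = [(0.0, 2.0), (1.0, 3.0), (2.0, 4.0)]
        cands, masses = brute_force_em(intervals)
        curve = turnbull_npmle((np.array([0.0, 1, 2]), np.array([2.0, 3, 4])), tol=1e-11)
        assert len(curve.mass) == len(cands)
        # same support (align by right endpoint, left ends match to the nudge)
        oracle = dict(zip([r for _, r in cands], masses))
        for l_oracle, (l, r, mass) in zip(
            [l for l, _ in cands],
            zip(curve.inner_left, curve.inner_right, curve.mass),
        ):
            assert l == pytest.approx(l_oracle, abs=1e-6)
            assert mass == pytest.approx(oracle[r], abs=1e-8)

    def test_loglikelihood_nondecreasing(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 80)
        left, right = grid_censor(t)
        curve = turnbull_npmle((left, right))
        assert np.all(np.diff(curve.loglik_trace) >= -1e-10)

    def test_masses_sum_to_one_and_survival_monotone(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(150, 120)
        left, right = grid_censor(t)
        curve = turnbull_npmle((left, right))
        assert curve.mass.sum() == pytest.approx(1.0, abs=1e-8)
        grid = np.linspace(0, 700, 173)
        vals = np.array([survival_at(curve, x) for x in grid])
        assert np.all(np.diff(vals) <= 1e-12)
        assert survival_at(curve, 0.0) == pytest.approx(1.0)


class TestCurveSummaries:
    def simple_curve(self):
        # S = 1 on [0,10), 0.4 on [10,20), 0 after (atoms at 10 and 20)
        return turnbull_npmle((np.array([10.0] * 6 + [20.0] * 4),
                               np.array([10.0] * 6 + [20.0] * 4)))

    def test_step_curve_median_and_mean(self):
        curve = self.simple_curve()
        assert median_longevity(curve) == pytest.approx(10.0)
        assert mean_longevity(curve) == pytest.approx(14.0)

    def test_nonunique_region_interpolates(self):
        # masses 0.2 at 5 exact; 0.6 spread over (10,20]; 0.2 at 25 exact:
        # S drops 0.8 -> 0.2 across the flagged region
        left = np.array([5.0] * 2 + [10.0] * 6 + [25.0] * 2)
        right = np.array([5.0] * 2 + [20.0] * 6 + [25.0] * 2)
        curve = turnbull_npmle((left, right))
        j = int(np.nonzero(curve.nonunique)[0][0])
        assert (curve.surv_before[j], curve.surv_after[j]) == pytest.approx((0.8, 0.2))
        assert survival_at(curve, 15.0) == pytest.approx(0.5)
        assert median_longevity(curve) == pytest.approx(15.0)

    def test_median_strict_inequality_at_plateau(self):
        # S = 0.5 exactly on [10, 30), drops at 30
        left = np.array([10.0] * 5 + [30.0] * 5)
        right = left.copy()
        curve = turnbull_npmle((left, right))
        assert survival_at(curve, 10.0) == pytest.approx(0.5)
        assert median_longevity(curve) == pytest.approx(30.0)

    def test_all_mass_at_single_time_mean_equals_it(self):
        curve = turnbull_npmle((np.array([42.0] * 5), np.array([42.0] * 5)))
        assert mean_longevity(curve, horizon=100.0) == pytest.approx(42.0)
        assert median_longevity(curve) == pytest.approx(42.0)

    def test_mean_matches_distribution_mean_on_exact_sample(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(100.0, 2000)
        curve = turnbull_npmle((t, t))
        est = mean_longevity(curve, horizon=float(t.max()))
        assert est == pytest.approx(100.0, rel=0.03)

    def test_heavy_censoring_median_undefined(self):
        left = np.array([50.0, 60, 70, 80])
        right = np.array([np.inf] * 4)
        curve = turnbull_npmle((np.concatenate([[10.0], left]),
                                np.concatenate([[20.0], right])))
        assert np.isnan(median_longevity(curve))
        assert curve.has_censored_tail


class TestBootstrap:
    def test_degenerate_data_zero_width_ci(self):
        iv = make_interval_set([50.0] * 20, [50.0] * 20)
        lo, hi, _ = bootstrap_ci(iv, lambda d: median_longevity(turnbull_npmle(d)),
                                 B=100, seed=0)
        assert lo == hi == 50.0

    def test_ci_width_shrinks_with_sample_size(self):
        """Quadrupling n should roughly halve the CI width (~1/sqrt(n))."""
        widths = {}
        for n in (100, 400):
            rng = np.random.default_rng(n)
            t = rng.exponential(200.0, n)
            left, right = grid_censor(t, end=1e9)
            iv = make_interval_set(left, right)
            lo, hi, _ = bootstrap_ci(iv, lambda d: median_longevity(turnbull_npmle(d)),
                                     B=300, seed=1)
            widths[n] = hi - lo
        ratio = widths[400] / widths[100]
        assert 0.3 < ratio < 0.8

    def test_coverage_near_nominal(self):
        """95% percentile-CI coverage for the grid-censored median.

        The percentile bootstrap is known to be slightly anticonservative
        for quantile-type statistics at this scale (measured coverage is a
        little above 0.9 rather than 0.95), so the assertion brackets the
        characterized behavior rather than exact nominal coverage.
        """
        true_med = 200.0 * np.log(2.0)
        n_datasets, covered = 200, 0
        for s in range(n_datasets):
            rng = np.random.default_rng(50_000 + s)
            t = rng.exponential(200.0, 200)
            left, right = grid_censor(t)
            iv = make_interval_set(left, right)
            lo, hi, _ = bootstrap_ci(iv, lambda d: median_longevity(turnbull_npmle(d)),
                                     B=300, seed=s)
            covered += lo <= true_med <= hi
        assert 0.87 <= covered / n_datasets <= 0.99

    def test_estimate_longevity_brackets_point(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(150.0, 150)
        left, right = grid_censor(t)
        iv = make_interval_set(left, right)
        est = estimate_longevity(iv, B=200, seed=0)
        assert est.median_ci[0] <= est.median <= est.median_ci[1]
        assert est.mean_ci[0] <= est.mean <= est.mean_ci[1]
        assert est.B == 200


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(100, 40)
        left, right = grid_censor(t)
        iv = make_interval_set(np.concatenate([left, left]),
                               np.concatenate([right, right]),
                               ["a"] * 40 + ["b"] * 40)
        res = logrank_interval(iv, n_perm=499, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(6)
        t1 = rng.exponential(50.0, 100)
        t2 = rng.exponential(200.0, 100)
        l1, r1 = grid_censor(t1)
        l2, r2 = grid_censor(t2)
        iv = make_interval_set(np.concatenate([l1, l2]), np.concatenate([r1, r2]),
                               ["a"] * 100 + ["b"] * 100)
        assert logrank_interval(iv, n_perm=999, seed=0).p_value < 0.01
        assert logrank_interval(iv, mode="asymptotic").p_value < 0.001

    def test_scores_reduce_to_classical_logrank(self):
        """On exact + right-censored data the interval scores must equal
        1 - Lambda(t) at events and -Lambda(c) at censorings (Nelson-Aalen
        Lambda), the classical logrank scores."""
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 50)
        c = rng.exponential(12, 50)
        obs = np.round(np.minimum(t, c), 2)
        event = t <= c
        iv = make_interval_set(obs, np.where(event, obs, np.inf))
        scores = logrank_scores(iv)
        uniq = np.sort(np.unique(obs[event]))
        cum, lam = 0.0, {}
        for u in uniq:
            cum += np.sum(obs[event] == u) / np.sum(obs >= u)
            lam[u] = cum

        def lam_at(x):
            keys = [u for u in uniq if u <= x]
            return lam[keys[-1]] if keys else 0.0

        classical = np.where(event,
                             1 - np.array([lam_at(x) for x in obs]),
                             -np.array([lam_at(x) for x in obs]))
        assert np.max(np.abs(scores - classical)) < 1e-6

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """Tiny two-group problem: the sampled permutation p-value must
        agree with the exact p from enumerating all label assignments."""
        left = np.array([0.0, 21, 42, 0, 42, 63])
        right = np.array([21.0, 42, 63, 21, 63, 84])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        iv = make_interval_set(left, right, labels)
        scores = logrank_scores(iv)
        c = scores - scores.mean()
        s2 = np.sum(c**2) / (len(c) - 1)

        def stat(idx_a):
            ua = c[list(idx_a)].sum()
            ub = -ua
            return (ua**2 / 3 + ub**2 / 3) / s2

        obs_stat = stat([0, 1, 2])
        exact = [stat(comb) for comb in itertools.combinations(range(6), 3)]
        p_exact = np.mean([s >= obs_stat - 1e-12 for s in exact])
        res = logrank_interval(iv, n_perm=9999, seed=3)
        assert res.statistic == pytest.approx(obs_stat)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_p_invariant_to_label_renaming(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(120, 60)
        left, right = grid_censor(t)
        g1 = np.array(["a"] * 30 + ["b"] * 30)
        g2 = np.array(["x"] * 30 + ["y"] * 30)
        p1 = logrank_interval(make_interval_set(left, right, g1), n_perm=999, seed=7).p_value
        p2 = logrank_interval(make_interval_set(left, right, g2), n_perm=999, seed=7).p_value
        assert p1 == p2

    def test_finkelstein_scores_also_separate_groups(self):
        rng = np.random.default_rng(12)
        t1 = rng.exponential(50.0, 80)
        t2 = rng.exponential(200.0, 80)
        l1, r1 = grid_censor(t1)
        l2, r2 = grid_censor(t2)
        iv = make_interval_set(np.concatenate([l1, l2]), np.concatenate([r1, r2]),
                               ["a"] * 80 + ["b"] * 80)
        assert logrank_interval(iv, scores="finkelstein", n_perm=999, seed=0).p_value < 0.01
        fs = finkelstein_scores(iv)
        assert np.isfinite(fs).all()


class TestTurnover:
    @pytest.mark.parametrize(
        "longevity, expected",
        [(235, 1.6), (200, 1.8), (204, 1.8), (234, 1.6),   # short-root medians
         (196, 1.9), (180, 2.0), (179, 2.0), (190, 1.9),   # short-root means
         (238, 1.5), (241, 1.5), (237, 1.5), (239, 1.5),   # long-root means
         (365, 1.0)],
    )
    def test_inverse_longevity_identity(self, longevity, expected):
        assert turnover(longevity) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            turnover(0.0)
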