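"""Interval-censored survival analysis for root longevity.

The death age of a minirhizotron-observed root is known only to lie in an
interval ``(L, R]`` (right-censored when ``R = inf``).  The survival
function is estimated by the nonparametric maximum-likelihood estimator
(NPMLE): probability mass can live only on the *maximal intersections*
("Turnbull intervals") of the observation intervals, and the masses are
found by Turnbull's self-consistency (EM) iteration.  Where a Turnbull
interval has positive width the NPMLE is non-unique inside it; following
the convention of plotting such regions as descending slopes, this module
linearly interpolates the survival curve across them and flags them.

On exact event times the NPMLE reduces to the empirical survivor function,
and on exact-plus-right-censored data to the Kaplan-Meier product-limit
estimator; both reductions are enforced by the test suite against
independent implementations.

The k-sample comparison uses a weighted-logrank score test: each subject
receives the expected classical logrank score given its interval,

    c_i = E[ 1 - Lambda(T) | T in (L_i, R_i] ]
        = sum_j a_ij p_j (1 - Lambda_j) / sum_j a_ij p_j,

where ``p_j`` are the pooled NPMLE masses, ``a_ij`` indicates that Turnbull
interval ``j`` is contained in subject ``i``'s observation interval, and
``Lambda_j = sum_{l<=j} d_l / n_l`` is the discrete Nelson-Aalen cumulative
hazard with ``d_l = p_l`` and at-risk fraction ``n_l = 1 - sum_{m<l} p_m``
(sample size cancels).  On exact/right-censored data these are exactly the
classical logrank scores (1 - Lambda at an event, -Lambda at a censoring
time), the same construction that underlies interval-censored logrank
scores in the grouped-data (Sun-type) formulation.  Significance comes from
a label-permutation test by default, or a chi-square approximation with
k - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records import IntervalCensoredSet

__all__ = [
    "SurvivalCurve",
    "turnbull_npmle",
    "survival_at",
    "median_longevity",
    "mean_longevity",
    "bootstrap_ci",
    "logrank_interval",
    "LogrankResult",
    "turnover",
    "LongevityEstimate",
    "estimate_longevity",
]


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Turnbull (maximal-intersection) intervals and the self-consistency EM
# ---------------------------------------------------------------------------


def _shifted_bounds(left: np.ndarray, right: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-interval representation of ``(L, R]`` observations.

    Half-open intervals are mapped to closed ones by nudging the exclusive
    left bound up by an epsilon smaller than any gap between distinct
    endpoint values; exact observations (``L == R``) stay degenerate.
    """
    finite = np.unique(np.concatenate([left, right[np.isfinite(right)]]))
    gaps = np.diff(finite)
    eps = (gaps[gaps > 0].min() / 1e6) if np.any(gaps > 0) else 1e-9
    lo = np.where(left < right, left + eps, left)
    return lo, right.astype(float), eps


def _maximal_intersections(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gentleman-Geyer scan: a maximal intersection starts at a left
    endpoint immediately followed (in sorted order, lefts before rights at
    ties) by a right endpoint."""
    pts = np.concatenate([lo, hi])
    is_right = np.concatenate([np.zeros(lo.size, bool), np.ones(hi.size, bool)])
    order = np.lexsort((is_right, pts))
    pts, is_right = pts[order], is_right[order]
    starts, ends = [], []
    for i in range(len(pts) - 1):
        if not is_right[i] and is_right[i + 1]:
            starts.append(pts[i])
            ends.append(pts[i + 1])
    return np.array(starts), np.array(ends)


@dataclass
class SurvivalCurve:
    """NPMLE survival curve over Turnbull intervals.

    ``inner_left``/``inner_right`` bound each Turnbull interval on the
    original timeline (open-left, closed-right; equal bounds = exact atom;
    ``inner_right[-1]`` may be ``inf`` when mass sits beyond the last
    observation).  ``surv_before[j]``/``surv_after[j]`` are the survival
    values entering and leaving interval ``j``; between intervals the curve
    is flat, and inside a positive-width interval it is non-unique
    (``nonunique[j]``) and rendered as a straight descending slope.
    """

    inner_left: np.ndarray
    inner_right: np.ndarray
    mass: np.ndarray
    n: int
    n_iter: int
    loglik: float
    loglik_trace: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.surv_before = 1.0 - np.concatenate([[0.0], np.cumsum(self.mass)[:-1]])
        self.surv_after = 1.0 - np.cumsum(self.mass)

    @property
    def nonunique(self) -> np.ndarray:
        return self.inner_right > self.inner_left

    @property
    def has_censored_tail(self) -> bool:
        return bool(np.isinf(self.inner_right[-1])) or self.surv_after[-1] > 1e-8

    @property
    def last_finite_boundary(self) -> float:
        finite = self.inner_right[np.isfinite(self.inner_right)]
        if finite.size:
            return float(finite[-1])
        return float(self.inner_left[-1])


def turnbull_npmle(
    data: IntervalCensoredSet | tuple[np.ndarray, np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> SurvivalCurve:
    """Turnbull self-consistency (EM) NPMLE for interval-censored data.

    Iterates ``p_j <- mean_i a_ij p_j / sum_k a_ik p_k`` until the largest
    mass change falls below ``tol``.  The log-likelihood is tracked and
    asserted non-decreasing (a guaranteed property of EM; violation would
    indicate an implementation fault).
    """
    if isinstance(data, tuple):
        left, right = (np.asarray(a, dtype=float) for a in data)
    else:
        left, right = data.left, data.right
    if left.size == 0:
        raise ValueError("need at least one interval")
    lo, hi, eps = _shifted_bounds(left, right)
    starts, ends = _maximal_intersections(lo, hi)
    m, n = starts.size, lo.size
    # a_ij: Turnbull interval j lies inside observation interval i
    alpha = (lo[:, None] <= starts[None, :]) & (hi[:, None] >= ends[None, :])
    if not np.all(alpha.any(axis=1)):  # cannot happen by construction
        raise ValueError("observation interval contains no maximal intersection")
    alpha = alpha.astype(float)
    p = np.full(m, 1.0 / m)
    trace = []
    for it in range(1, max_iter + 1):
        denom = alpha @ p
        trace.append(float(np.sum(np.log(denom))))
        if len(trace) >= 2 and trace[-1] < trace[-2] - 1e-10:
            raise AssertionError("EM log-likelihood decreased")
        p_new = (alpha / denom[:, None]).mean(axis=0) * p
        p_new /= p_new.sum()
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"Turnbull EM did not converge in {max_iter} iterations "
            f"(last max mass change {delta:.3g})",
            np.array(trace),
        )
    # report bounds on the original scale (undo the epsilon nudge)
    inner_left = np.where(starts < ends, starts - eps, starts)
    return SurvivalCurve(
        inner_left=inner_left,
        inner_right=ends,
        mass=p,
        n=n,
        n_iter=it,
        loglik=trace[-1],
        loglik_trace=np.array(trace),
    )


# ---------------------------------------------------------------------------
# Curve evaluation, median, restricted mean
# ---------------------------------------------------------------------------


def survival_at(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Evaluate the NPMLE survival curve at time(s) ``t``.

    Step function where the NPMLE is unique; linear descending slope inside
    flagged non-unique (positive-width) Turnbull intervals.  Right
    continuous at exact atoms, so ``S(t)`` includes mass at ``t``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    ql, pr = curve.inner_left, curve.inner_right
    sb, sa = curve.surv_before, curve.surv_after
    out = np.empty(t_arr.shape)
    for i, ti in enumerate(t_arr):
        j = np.searchsorted(pr, ti, side="left")
        if j >= len(pr):
            out[i] = sa[-1]
        elif ti == pr[j]:  # right-continuous: mass at an atom is included
            out[i] = sa[j]
        elif ti <= ql[j]:
            out[i] = sb[j]
        elif np.isinf(pr[j]):
            out[i] = sb[j]  # slope into an unbounded tail is undefined; hold
        else:
            frac = (ti - ql[j]) / (pr[j] - ql[j])
            out[i] = sb[j] + frac * (sa[j] - sb[j])
    return out if np.ndim(t) else float(out[0])


def median_longevity(curve: SurvivalCurve) -> float:
    """Smallest time at which the survival curve goes below 0.5.

    Strict inequality: a plateau exactly at 0.5 does not define the median;
    the first drop below it does.  Inside a non-unique interval the linear
    slope is used, so the 0.5 crossing point is returned.  ``nan`` when the
    curve never goes below 0.5 (heavy censoring).
    """
    sb, sa = curve.surv_before, curve.surv_after
    below = np.nonzero(sa < 0.5)[0]
    if below.size == 0:
        return float("nan")
    j = below[0]
    ql, pr = curve.inner_left[j], curve.inner_right[j]
    if pr == ql or np.isinf(pr):
        return float(pr) if np.isfinite(pr) else float("nan")
    # linear slope from (ql, sb) to (pr, sa); sb >= 0.5 > sa here
    return float(ql + (sb[j] - 0.5) / (sb[j] - sa[j]) * (pr - ql))


def mean_longevity(curve: SurvivalCurve, horizon: float | None = None) -> float:
    """Integral of the survival curve from 0 to ``horizon``.

    Non-unique regions contribute their trapezoid (the ad-hoc descending
    slope).  ``horizon`` defaults to the last finite Turnbull boundary,
    giving a *restricted* mean when the curve carries a censored tail.
    """
    if horizon is None:
        horizon = curve.last_finite_boundary
    sb, sa = curve.surv_before, curve.surv_after
    total = 0.0
    prev_t, prev_s = 0.0, 1.0
    for j in range(len(curve.mass)):
        ql = max(curve.inner_left[j], 0.0)
        pr = curve.inner_right[j]
        if ql >= horizon:
            break
        total += max(ql - prev_t, 0.0) * prev_s  # flat stretch before interval j
        if pr == curve.inner_left[j]:  # exact atom: step, no width
            prev_t, prev_s = ql, sa[j]
            continue
        if not np.isfinite(pr):  # unbounded tail: slope undefined, hold S
            total += (horizon - ql) * sb[j]
            prev_t, prev_s = horizon, sb[j]
            break
        hi = min(pr, horizon)
        s_hi = sb[j] + (hi - ql) / (pr - ql) * (sa[j] - sb[j])
        total += (hi - ql) * (sb[j] + s_hi) / 2.0
        prev_t = hi
        prev_s = sa[j] if hi >= pr else s_hi
    if horizon > prev_t:
        total += (horizon - prev_t) * prev_s
    return float(total)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    data: IntervalCensoredSet,
    statistic,
    B: int = 3000,
    level: float = 0.95,
    seed: int | None = None,
    cluster: np.ndarray | None = None,
):
    """Percentile bootstrap CI for ``statistic(IntervalCensoredSet)``.

    Resamples roots with replacement (the default unit); pass ``cluster``
    (e.g. seedling ids) for a cluster bootstrap that resamples whole
    seedlings instead.  Returns ``(lo, hi, replicates)``.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.empty(B)
    if cluster is not None:
        cluster = np.asarray(cluster)
        uniq = np.unique(cluster)
        members = [np.nonzero(cluster == c)[0] for c in uniq]
    for b in range(B):
        if cluster is None:
            idx = rng.integers(0, n, size=n)
        else:
            picked = rng.integers(0, len(members), size=len(members))
            idx = np.concatenate([members[k] for k in picked])
        sub = IntervalCensoredSet(
            data.root_id[idx], data.group[idx], data.left[idx], data.right[idx],
            data.age_origin,
        )
        reps[b] = statistic(sub)
    a = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(reps, [a, 1.0 - a])
    return float(lo), float(hi), reps


@dataclass
class LongevityEstimate:
    """Median and restricted-mean longevity with bootstrap percentile CIs."""

    group: str
    n: int
    median: float
    median_ci: tuple[float, float]
    mean: float
    mean_ci: tuple[float, float]
    B: int
    seed: int | None
    restricted: bool


def estimate_longevity(
    data: IntervalCensoredSet,
    group: str = "",
    B: int = 3000,
    level: float = 0.95,
    seed: int | None = None,
) -> LongevityEstimate:
    """Point estimates plus bootstrap CIs for one group. ``B=0`` skips CIs."""
    curve = turnbull_npmle(data)
    med = median_longevity(curve)
    mea = mean_longevity(curve)
    if B > 0:
        med_ci = bootstrap_ci(data, lambda d: median_longevity(turnbull_npmle(d)), B, level, seed)[:2]
        mean_ci = bootstrap_ci(data, lambda d: mean_longevity(turnbull_npmle(d)), B, level,
                               None if seed is None else seed + 1)[:2]
    else:
        med_ci = (float("nan"), float("nan"))
        mean_ci = (float("nan"), float("nan"))
    return LongevityEstimate(
        group=group, n=len(data), median=med, median_ci=med_ci,
        mean=mea, mean_ci=mean_ci, B=B, seed=seed,
        restricted=curve.has_censored_tail,
    )


# ---------------------------------------------------------------------------
# Weighted logrank k-sample test for interval-censored data
# ---------------------------------------------------------------------------


def logrank_scores(data: IntervalCensoredSet | tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Per-subject expected logrank scores under the pooled NPMLE.

    See the module docstring for the formula.  Scores have (approximately)
    zero mean by construction; they are centered exactly before testing.
    """
    if isinstance(data, tuple):
        left, right = (np.asarray(a, dtype=float) for a in data)
    else:
        left, right = data.left, data.right
    curve = turnbull_npmle((left, right))
    # containment: Turnbull interval j = (inner_left, inner_right] lies inside
    # subject i's (L_i, R_i] iff L_i <= inner_left and R_i >= inner_right;
    # exact atoms (L == R) match a degenerate Turnbull atom at the same point.
    L, R = left, right
    il, ir = curve.inner_left, curve.inner_right
    atom_i = L == R
    alpha = np.where(
        atom_i[:, None],
        (il[None, :] <= L[:, None]) & (ir[None, :] >= L[:, None]),
        (L[:, None] <= il[None, :]) & (R[:, None] >= ir[None, :]),
    )
    p = curve.mass
    n_at_risk = curve.surv_before  # fraction at risk entering interval j
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard_inc = np.where(n_at_risk > 0, p / n_at_risk, 0.0)
    Lam = np.cumsum(hazard_inc)
    num = alpha @ (p * (1.0 - Lam))
    den = alpha @ p
    scores = np.empty(L.size)
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    if np.any(~ok):
        # censored past all mass: classical censored score -Lambda(L)
        for i in np.nonzero(~ok)[0]:
            j = np.searchsorted(ir, L[i], side="right")
            scores[i] = -Lam[min(j, len(Lam)) - 1] if j > 0 else 0.0
    return scores


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    mode: str
    group_labels: np.ndarray
    group_score_sums: np.ndarray
    n_perm: int | None = None
    seed: int | None = None


def _quadratic_stat(scores: np.ndarray, group_codes: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    c = scores - scores.mean()
    sums = np.bincount(group_codes, weights=c, minlength=k)
    counts = np.bincount(group_codes, minlength=k)
    s2 = np.sum(c**2) / (len(c) - 1)
    if s2 <= 0:
        return 0.0, sums
    return float(np.sum(sums**2 / counts) / s2), sums


def logrank_interval(
    data: IntervalCensoredSet,
    scores: str = "sun",
    mode: str = "permutation",
    n_perm: int = 9999,
    seed: int | None = None,
) -> LogrankResult:
    """k-sample weighted logrank test for interval-censored groups.

    ``scores="sun"`` uses the expected-logrank (Sun-type) scores from the
    pooled NPMLE; ``scores="finkelstein"`` uses the grouped proportional-
    hazards scores ``(S_L log S_L - S_R log S_R) / (S_L - S_R)``.  The test
    statistic is the permutation-form quadratic ``sum_g U_g^2 / n_g``
    scaled by the score variance; ``mode="permutation"`` permutes group
    labels (p = (1 + #{T* >= T}) / (n_perm + 1)), ``mode="asymptotic"``
    refers it to chi-square with k - 1 df.
    """
    labels, codes = np.unique(data.group, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    if scores == "sun":
        c = logrank_scores(data)
    elif scores == "finkelstein":
        c = finkelstein_scores(data)
    else:
        raise ValueError(f"unknown scores {scores!r}")
    stat, sums = _quadratic_stat(c, codes, k)
    if np.allclose(np.var(c), 0.0):
        return LogrankResult(0.0, 1.0, k - 1, mode, labels, sums, None, seed)
    if mode == "asymptotic":
        p = float(stats.chi2.sf(stat, k - 1))
        return LogrankResult(stat, p, k - 1, mode, labels, sums)
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    cc = c - c.mean()
    counts = np.bincount(codes, minlength=k)
    s2 = np.sum(cc**2) / (len(cc) - 1)
    n = len(cc)
    # label permutation == permuting the score vector against fixed labels;
    # group sums taken over contiguous segments after ordering by group code
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = cc[perm_idx]  # (n_perm, n)
    order = np.argsort(codes, kind="stable")
    bounds = np.cumsum(counts)[:-1]
    seg = np.split(np.arange(n), bounds)
    sums_perm = np.stack([permuted[:, order[s]].sum(axis=1) for s in seg], axis=1)
    perm_stats = np.sum(sums_perm**2 / counts[None, :], axis=1) / s2
    p = (1.0 + np.sum(perm_stats >= stat - 1e-12)) / (n_perm + 1.0)
    return LogrankResult(stat, float(p), k - 1, mode, labels, sums, n_perm, seed)


def finkelstein_scores(data: IntervalCensoredSet | tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Grouped proportional-hazards logrank scores
    ``(S(L) log S(L) - S(R) log S(R)) / (S(L) - S(R))`` with S from the
    pooled NPMLE and ``0 log 0 = 0``."""
    if isinstance(data, tuple):
        left, right = (np.asarray(a, dtype=float) for a in data)
    else:
        left, right = data.left, data.right
    curve = turnbull_npmle((left, right))

    def xlogx(s):
        s = np.asarray(s, dtype=float)
        return np.where(s > 0, s * np.log(np.clip(s, 1e-300, None)), 0.0)

    sL = np.array([survival_at(curve, l) for l in left])
    sR = np.array([0.0 if np.isinf(r) else survival_at(curve, r) for r in right])
    # exact atoms: use left limit for S(L-)
    atom = left == right
    if np.any(atom):
        sL[atom] = np.array([survival_at(curve, l - 1e-9) for l in left[atom]])
    diff = sL - sR
    out = np.where(diff > 1e-12, (xlogx(sL) - xlogx(sR)) / np.where(diff > 1e-12, diff, 1.0), 0.0)
    return out


# ---------------------------------------------------------------------------
# Fine-root turnover
# ---------------------------------------------------------------------------


def turnover(longevity_days: float, year_days: float = 365.0, ndigits: int | None = 1):
    """Fine-root turnover rate: how many times per year the population is
    computationally replaced, i.e. ``year_days / longevity_days``.

    Applied to the median longevity this is FRT_inv_med, to the mean
    FRT_inv_mean.  Reported to one decimal by default (``ndigits=None``
    for the raw ratio)."""
    if not longevity_days > 0:
        raise ValueError("longevity must be positive")
    rate = year_days / longevity_days
    return rate if ndigits is None else round(rate, ndigits)
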