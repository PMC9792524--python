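"""Monogenic gene-pool size estimation from recurrence, and cohort design.

The genetic-architecture model: a pool of ``p`` disease genes, each equally
likely to be the monogenic cause in a solved case. Drawing ``n`` gene hits
uniformly with replacement from the pool, the recurrence rate

    r = (# genes drawn >= 2 times) / (# distinct genes drawn)

is strictly decreasing in ``p`` for fixed ``n``, so the observed recurrence
among unrelated cases identifies the pool size. The estimator grid-searches
p over 1..1000, simulating the expected r at each value (1000 replicates by
default) and minimizing |mean r - r_obs|; a closed form for the expected
numbers of distinct and recurrent genes serves as the analytic oracle.

False discoveries among the hits bias r. Two bracketing placement models
bound the effect: FPs that always land on unique background genes (never
recur; dilutes r) and FPs drawn from the same pool as true hits (behave
like true hits; r unchanged).

Cohort projections invert the same model: simulate cohorts of size n where
each case carries a discoverable cause with probability d, and find the
minimal n at which at least a target fraction of the pool has been seen in
>= k cases.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

R_DEFINITIONS = ("recurrent_over_distinct", "recurrent_over_draws")


@dataclasses.dataclass
class RecurrenceModel:
    """Parameters of one recurrence simulation."""

    p: int
    n_draws: int
    r_definition: str = "recurrent_over_distinct"
    reps: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p < 1 or self.n_draws < 1:
            raise ValueError("p and n_draws must be >= 1")
        if self.r_definition not in R_DEFINITIONS:
            raise ValueError(f"r_definition must be one of {R_DEFINITIONS}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def expected_recurrence_closed_form(
    p: int, n: int, r_definition: str = "recurrent_over_distinct"
) -> tuple[float, float, float]:
    """Expected (distinct, recurrent, r) for n uniform draws from p genes.

    With P0 = (1-1/p)^n the chance a given gene is never drawn and
    P1 = (n/p)(1-1/p)^(n-1) the chance it is drawn exactly once:
    E[distinct] = p(1-P0), E[recurrent] = p(1-P0-P1). The returned r is the
    ratio of expectations, the deterministic analogue of the simulated
    statistic (exact as reps -> inf up to the ratio-of-means approximation).
    """
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    if r_definition not in R_DEFINITIONS:
        raise ValueError(f"r_definition must be one of {R_DEFINITIONS}")
    # per-gene hit count is Binomial(n, 1/p); survival functions keep the
    # tail probabilities accurate where 1 - P0 - P1 cancels catastrophically
    e_distinct = p * float(stats.binom.sf(0, n, 1.0 / p))
    e_recurrent = p * float(stats.binom.sf(1, n, 1.0 / p))
    if r_definition == "recurrent_over_distinct":
        r = e_recurrent / e_distinct if e_distinct > 0 else 0.0
    else:
        r = e_recurrent / n
    return e_distinct, e_recurrent, r


def _distinct_recurrent(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row counts of distinct values and values seen >= 2 times."""
    s = np.sort(draws, axis=1)
    reps = s.shape[0]
    new = np.ones(s.shape, dtype=bool)
    new[:, 1:] = s[:, 1:] != s[:, :-1]
    nxt_new = np.ones(s.shape, dtype=bool)
    nxt_new[:, :-1] = new[:, 1:]
    distinct = new.sum(axis=1)
    singletons = (new & nxt_new).sum(axis=1)  # runs of length exactly 1
    return distinct, distinct - singletons


def _simulated_r(
    p: int,
    n: int,
    reps: int,
    rng: np.random.Generator,
    r_definition: str,
    fdr: float = 0.0,
    fp_model: str = "never_recur",
) -> float:
    """Mean simulated recurrence rate over ``reps`` replicates.

    With ``fdr`` > 0 a deterministic fraction of the n hits are false
    positives. Under ``never_recur`` they occupy unique background genes:
    they inflate the distinct count but can never recur. Under
    ``same_pool`` they are indistinguishable from true hits.
    """
    n_fp = int(round(n * fdr)) if fp_model == "never_recur" else 0
    n_true = n - n_fp
    if n_true < 1:
        raise ValueError("fdr too high: no true hits remain")
    draws = rng.integers(0, p, size=(reps, n_true))
    distinct, recurrent = _distinct_recurrent(draws)
    if r_definition == "recurrent_over_distinct":
        r = recurrent / (distinct + n_fp)
    else:
        r = recurrent / n
    return float(r.mean())


def simulate_recurrence(model: RecurrenceModel) -> float:
    """Monte Carlo mean recurrence rate; converges to the closed form."""
    rng = np.random.default_rng(model.seed)
    return _simulated_r(model.p, model.n_draws, model.reps, rng, model.r_definition)


@dataclasses.dataclass
class PoolEstimate:
    """Grid-search pool-size estimate."""

    p_hat: int
    grid: np.ndarray
    objective_curve: np.ndarray  # |mean r - r_obs| per grid point
    at_boundary: bool
    r_obs: float
    n_draws: int
    r_definition: str = "recurrent_over_distinct"


def estimate_pool_size(
    r_obs: float,
    n_draws: int,
    grid: Sequence[int] | None = None,
    reps: int = 1000,
    seed: int | None = None,
    r_definition: str = "recurrent_over_distinct",
) -> PoolEstimate:
    """Estimate the pool size whose expected recurrence matches ``r_obs``.

    Argmin of |mean simulated r - r_obs| over the grid (default 1..1000,
    step 1); ties break toward the smallest pool. ``at_boundary`` flags an
    estimate pinned to either grid end, which signals a misspecified grid.
    """
    if not 0 <= r_obs <= 1:
        raise ValueError("r_obs must lie in [0,1]")
    grid_arr = np.asarray(grid if grid is not None else np.arange(1, 1001), dtype=int)
    if grid_arr.ndim != 1 or len(grid_arr) == 0 or (grid_arr < 1).any():
        raise ValueError("grid must be a non-empty 1-D array of pool sizes >= 1")
    rng = np.random.default_rng(seed)
    curve = np.array(
        [
            abs(_simulated_r(int(p), n_draws, reps, rng, r_definition) - r_obs)
            for p in grid_arr
        ]
    )
    idx = int(np.argmin(curve))  # first minimum = smallest p on ties
    return PoolEstimate(
        p_hat=int(grid_arr[idx]),
        grid=grid_arr,
        objective_curve=curve,
        at_boundary=idx in (0, len(grid_arr) - 1),
        r_obs=r_obs,
        n_draws=n_draws,
        r_definition=r_definition,
    )


@dataclasses.dataclass
class AdjustedPoolEstimate(PoolEstimate):
    """Pool estimate after accounting for false discoveries among hits."""

    fdr: float = 0.0
    fp_model: str = "never_recur"
    relative_change: float = 0.0


def adjust_for_fdr(
    estimate: PoolEstimate,
    fdr: float,
    fp_model: str = "never_recur",
    reps: int = 1000,
    seed: int | None = None,
) -> AdjustedPoolEstimate:
    """Re-estimate the pool size assuming a fraction ``fdr`` of hits are FPs.

    Under the default ``never_recur`` placement, expected recurrence is no
    longer monotone in p (it rises to a mode near the true-hit count before
    falling), so the grid argmin is restricted to the decreasing branch —
    pools larger than the closed-form mode — the only regime compatible
    with a pool exceeding the number of hits.
    """
    if not 0 <= fdr < 1:
        raise ValueError("fdr must lie in [0,1)")
    if fp_model not in ("never_recur", "same_pool"):
        raise ValueError("fp_model must be 'never_recur' or 'same_pool'")
    if fdr == 0:
        return AdjustedPoolEstimate(
            p_hat=estimate.p_hat,
            grid=estimate.grid,
            objective_curve=estimate.objective_curve,
            at_boundary=estimate.at_boundary,
            r_obs=estimate.r_obs,
            n_draws=estimate.n_draws,
            r_definition=estimate.r_definition,
            fdr=0.0,
            fp_model=fp_model,
            relative_change=0.0,
        )
    grid_arr = estimate.grid
    n = estimate.n_draws
    rng = np.random.default_rng(seed)
    curve = np.array(
        [
            abs(
                _simulated_r(int(p), n, reps, rng, estimate.r_definition, fdr, fp_model)
                - estimate.r_obs
            )
            for p in grid_arr
        ]
    )
    if fp_model == "never_recur":
        # closed-form adjusted r over the grid to locate the mode
        n_fp = int(round(n * fdr))
        n_true = n - n_fp
        analytic = np.array(
            [
                expected_recurrence_closed_form(int(p), n_true, "recurrent_over_distinct")[1]
                / (
                    expected_recurrence_closed_form(int(p), n_true)[0] + n_fp
                    if estimate.r_definition == "recurrent_over_distinct"
                    else n
                )
                for p in grid_arr
            ]
        )
        lo = int(np.argmax(analytic))
    else:
        lo = 0
    idx = lo + int(np.argmin(curve[lo:]))
    p_hat = int(grid_arr[idx])
    return AdjustedPoolEstimate(
        p_hat=p_hat,
        grid=grid_arr,
        objective_curve=curve,
        at_boundary=idx in (0, len(grid_arr) - 1),
        r_obs=estimate.r_obs,
        n_draws=n,
        r_definition=estimate.r_definition,
        fdr=fdr,
        fp_model=fp_model,
        relative_change=(p_hat - estimate.p_hat) / estimate.p_hat,
    )


def fp_recurrence_bounds(p: int, n: int, fdr: float) -> tuple[float, float]:
    """Closed-form bracket on expected recurrence under FP contamination.

    ``r_low``: FP hits occupy unique background genes and never recur —
    true hits drop to n(1-fdr) while the distinct denominator keeps the
    n*fdr FP genes. ``r_high``: FP hits are drawn from the pool itself and
    are indistinguishable from true hits. Always r_low <= r_high.
    """
    if not 0 <= fdr < 1:
        raise ValueError("fdr must lie in [0,1)")
    _, _, r_high = expected_recurrence_closed_form(p, n)
    n_fp = n * fdr
    n_true = max(n - n_fp, 1.0)
    p0 = (1 - 1 / p) ** n_true
    p1 = (n_true / p) * (1 - 1 / p) ** (n_true - 1)
    e_distinct = p * (1 - p0)
    e_recurrent = p * (1 - p0 - p1)
    r_low = e_recurrent / (e_distinct + n_fp)
    return float(r_low), float(r_high)


@dataclasses.dataclass
class ProjectionResult:
    """Minimal cohort size for a recurrence-coverage target."""

    n_required: int
    discovery_rate: float
    coverage_target: float
    recurrence_k: int
    pool_size: int
    curve: dict[int, float]  # cohort size -> mean fraction of pool seen >= k times


def _coverage(
    n: int, pool: int, d: float, k: int, reps: int, seed_seq: tuple[int, ...]
) -> float:
    """Mean fraction of pool genes hit >= k times in a cohort of size n.

    Seeded per (base seed, n) so a given n evaluates identically regardless
    of the search path.
    """
    rng = np.random.default_rng(seed_seq + (n,))
    m = rng.binomial(n, d, size=reps)  # discoverable hits per replicate
    total = int(m.sum())
    genes = rng.integers(0, pool, size=total)
    rep_ids = np.repeat(np.arange(reps), m)
    counts = np.bincount(rep_ids * pool + genes, minlength=reps * pool).reshape(reps, pool)
    return float((counts >= k).mean())


def projection_oracle_n(pool_size: int, discovery_rate: float, coverage_target: float = 0.5, recurrence_k: int = 2) -> float:
    """Poisson-approximation cohort size: solve P(Pois(lambda) >= k) = target
    with lambda = n*d/pool. Analytic oracle for the simulation."""
    from scipy.optimize import brentq

    f = lambda lam: 1 - stats.poisson.cdf(recurrence_k - 1, lam) - coverage_target
    lam = brentq(f, 1e-9, 1e3)
    return pool_size * lam / discovery_rate


def project_cohort_size(
    pool_size: int,
    discovery_rate: float,
    coverage_target: float = 0.5,
    recurrence_k: int = 2,
    reps: int = 1000,
    seed: int | None = None,
) -> ProjectionResult:
    """Minimal cohort size to observe >= ``coverage_target`` of the pool
    recurrently (>= ``recurrence_k`` cases per gene).

    Each case carries a discoverable monogenic cause with probability
    ``discovery_rate``, the gene uniform over the pool. Bisection on the
    (monotone in expectation) coverage curve, then a +-5 linear scan guards
    Monte Carlo noise near the crossing.
    """
    if not 0 < discovery_rate <= 1:
        raise ValueError("discovery_rate must lie in (0,1]")
    if pool_size < 1 or recurrence_k < 1 or reps < 1:
        raise ValueError("pool_size, recurrence_k and reps must be >= 1")
    if not 0 < coverage_target < 1:
        raise ValueError(
            "coverage_target must lie in (0,1): a full finite pool is never "
            "covered with certainty"
        )
    seed_seq = (0,) if seed is None else (int(seed),)
    curve: dict[int, float] = {}

    def g(n: int) -> float:
        if n not in curve:
            curve[n] = _coverage(n, pool_size, discovery_rate, recurrence_k, reps, seed_seq)
        return curve[n]

    n0 = max(int(projection_oracle_n(pool_size, discovery_rate, coverage_target, recurrence_k)), 1)
    lo, hi = max(n0 // 2, 1), max(2 * n0, 2)
    while g(hi) < coverage_target:
        lo, hi = hi, hi * 2
        if hi > 10**8:
            raise RuntimeError("coverage target unreachable within search cap")
    while g(lo) >= coverage_target and lo > 1:
        hi, lo = lo, max(lo // 2, 1)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if g(mid) >= coverage_target:
            hi = mid
        else:
            lo = mid
    # final linear scan around the bisection answer
    candidates = [n for n in range(max(hi - 5, 1), hi + 6) if g(n) >= coverage_target]
    n_req = min(candidates) if candidates else hi
    return ProjectionResult(
        n_required=int(n_req),
        discovery_rate=discovery_rate,
        coverage_target=coverage_target,
        recurrence_k=recurrence_k,
        pool_size=pool_size,
        curve=dict(sorted(curve.items())),
    )
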