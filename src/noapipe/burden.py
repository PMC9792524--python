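"""Exact 2x2 tests for carrier burden and cohort-level comparisons.

Carrier proportions between cases and controls are compared with Fisher's
exact test (two-sided by the minimum-likelihood convention). Significance
in the two-stage design (gene discovery in a first cohort, association in
the combined cohorts) uses a Bonferroni threshold for the number of genes
effectively screened in the first stage; with 20,000 single-gene tests and
alpha = 0.05 the threshold is p < 2.5e-6, i.e. exome-wide significance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = group, cols = carrier / non-carrier."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self, haldane: bool = False) -> float:
        """Sample odds ratio; ``inf`` for zero cells unless ``haldane``
        applies the 0.5 continuity correction."""
        a, b, c, d = (float(x) for x in (self.a, self.b, self.c, self.d))
        if haldane:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        if b * c == 0:
            return float("inf") if a * d > 0 else float("nan")
        return (a * d) / (b * c)


def fisher_exact(
    table: ContingencyTable | np.ndarray, alternative: str = "two_sided"
) -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    The two-sided p sums the point probabilities of all tables (with the
    observed margins) no more likely than the observed one — the
    minimum-likelihood convention. An all-zero table has no information and
    returns p = 1 with a warning.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    arr = table.to_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if arr.sum() == 0:
        warnings.warn("all-zero contingency table: p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(arr, alternative=_ALTERNATIVES[alternative])
    return float(min(p, 1.0))


@dataclasses.dataclass
class BurdenResult:
    """Per-gene burden test outcome."""

    gene_id: str
    table: ContingencyTable
    p_two_sided: float
    p_one_sided: float  # alternative: carriers enriched in cases
    odds_ratio: float
    significant_two_stage: bool


def two_stage_threshold(n_first_stage_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / (number of first-stage gene tests)."""
    if n_first_stage_genes <= 0 or alpha <= 0:
        raise ValueError("n_first_stage_genes and alpha must be positive")
    return alpha / n_first_stage_genes


def carrier_burden_test(
    gene_id: str,
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    threshold: float = 2.5e-6,
    haldane: bool = False,
) -> BurdenResult:
    """Fisher exact test on carrier proportions for one gene.

    Significance is strict (``p < threshold``) per the two-stage design.
    Only single-variant (hom/hemizygous) genotype carriers belong here;
    compound-heterozygous carriers cannot be counted on the control side
    and must be excluded upstream.
    """
    if case_carriers > n_cases or control_carriers > n_controls:
        raise ValueError("carriers cannot exceed cohort size")
    if min(case_carriers, n_cases, control_carriers, n_controls) < 0:
        raise ValueError("counts must be non-negative")
    table = ContingencyTable(
        a=case_carriers,
        b=n_cases - case_carriers,
        c=control_carriers,
        d=n_controls - control_carriers,
    )
    p2 = fisher_exact(table, "two_sided")
    p1 = fisher_exact(table, "greater")
    return BurdenResult(
        gene_id=gene_id,
        table=table,
        p_two_sided=p2,
        p_one_sided=p1,
        odds_ratio=table.odds_ratio(haldane=haldane),
        significant_two_stage=bool(p2 < threshold),
    )


def binomial_novel_ko_test(
    k_observed: int, n_trials: int, rate_expected: float
) -> float:
    """One-tailed (lower) exact binomial probability P(X <= k).

    Generic comparison of an observed count against an expected rate, e.g.
    novel predicted knockouts among controls vs the case-derived rate.
    """
    if not 0 <= k_observed <= n_trials:
        raise ValueError("need 0 <= k_observed <= n_trials")
    if not 0 <= rate_expected <= 1:
        raise ValueError("rate_expected must lie in [0,1]")
    return float(stats.binom.cdf(k_observed, n_trials, rate_expected))
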