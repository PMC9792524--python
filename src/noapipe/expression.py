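"""Tissue-specificity classification and expression-component profiling.

Genes are classified by the five-fold rules used for bulk tissue panels:
*tissue enriched* (one tissue at least five-fold above every other tissue),
*group enriched* (five-fold higher average in a group of 2-7 tissues than
in every remaining tissue) and *tissue enhanced* (five-fold above the mean
of all tissues), with that precedence.

"Molecular subform" statistics summarize how a query gene set distributes
over the latent expression components of a single-cell decomposition: per
component, the count of query genes among its top-loading genes; Pearson
correlations between such profiles; a Pearson-Filon Z test for comparing
two dependent correlations that share a profile; and hypergeometric
enrichment of a query set in one component's gene set.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class SpecificityRule:
    """Fold-change rules for tissue specificity classes."""

    fold: float = 5.0
    group_min: int = 2
    group_max: int = 7

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if not 2 <= self.group_min <= self.group_max:
            raise ValueError("need 2 <= group_min <= group_max")


def classify_tissue_specificity(
    matrix: pd.DataFrame, rule: SpecificityRule | None = None
) -> pd.Series:
    """Classify each gene (column) of a tissues-by-genes TPM matrix.

    Precedence: tissue_enriched > group_enriched > tissue_enhanced > none.
    The group search scans rank-contiguous top-k tissue sets for
    k = group_min..group_max (the optimal five-fold group is always
    rank-contiguous). All-zero profiles are 'none'.
    """
    rule = rule or SpecificityRule()
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("TPM values must be non-negative")
    n_tissues = vals.shape[0]
    if n_tissues < rule.group_max + 1:
        raise ValueError(
            f"need at least group_max+1 = {rule.group_max + 1} tissues, got {n_tissues}"
        )
    s = np.sort(vals, axis=0)[::-1]  # per-gene descending profiles
    top = s[0]
    positive = top > 0
    enriched = positive & (top >= rule.fold * s[1])
    grand_mean = vals.mean(axis=0)
    enhanced = positive & (top >= rule.fold * grand_mean)
    group = np.zeros(vals.shape[1], dtype=bool)
    csum = np.cumsum(s, axis=0)
    for k in range(rule.group_min, rule.group_max + 1):
        group |= positive & (csum[k - 1] / k >= rule.fold * s[k])
    out = np.where(
        enriched,
        "tissue_enriched",
        np.where(group, "group_enriched", np.where(enhanced, "tissue_enhanced", "none")),
    )
    return pd.Series(out, index=matrix.columns, name="testis_class")


SIDES = ("positive", "negative", "both", "magnitude")


def component_gene_sets(
    loadings: pd.DataFrame, top_n: int = 250, sides: str = "both"
) -> dict[str, set[str]]:
    """Top-loading gene set per component of a components-by-genes matrix.

    ``sides='positive'``/``'negative'`` take the top ``top_n`` genes by
    signed loading on that side; ``'both'`` is their union (the convention
    of taking the top genes from each side of a component); ``'magnitude'``
    ranks by absolute loading. Ties break deterministically by gene id.
    """
    if sides not in SIDES:
        raise ValueError(f"sides must be one of {SIDES}")
    if top_n > loadings.shape[1]:
        raise ValueError("top_n cannot exceed the number of genes")
    if not np.isfinite(loadings.to_numpy(dtype=float)).all():
        raise ValueError("loadings must be finite")
    # stable gene-id order makes the sort tie-break deterministic
    mat = loadings[sorted(loadings.columns)]
    out: dict[str, set[str]] = {}
    for comp, row in mat.iterrows():
        if sides == "positive":
            picked = row.sort_values(ascending=False, kind="stable").index[:top_n]
        elif sides == "negative":
            picked = row.sort_values(ascending=True, kind="stable").index[:top_n]
        elif sides == "magnitude":
            picked = row.abs().sort_values(ascending=False, kind="stable").index[:top_n]
        else:  # both
            pos = row.sort_values(ascending=False, kind="stable").index[:top_n]
            neg = row.sort_values(ascending=True, kind="stable").index[:top_n]
            picked = pos.union(neg)
        out[str(comp)] = set(picked)
    return out


def profile_counts(
    query_genes: Iterable[str], component_sets: Mapping[str, set[str]]
) -> pd.Series:
    """Count of query genes inside each component's gene set.

    The per-component count profile is the fingerprint used to compare
    gene lists (disease genes, model-organism genes, control genes) across
    expression programs. Additive over disjoint query sets.
    """
    q = set(query_genes)
    return pd.Series(
        {comp: len(q & genes) for comp, genes in component_sets.items()},
        name="gene_count",
    ).sort_index()


@dataclasses.dataclass(frozen=True)
class DependentCorrelations:
    """Two correlations sharing variable j, plus the non-shared correlation.

    ``r_jk`` and ``r_jh`` both involve profile j (e.g. disease genes vs two
    comparison sets); ``r_kh`` correlates the non-shared pair; ``n`` is the
    number of paired observations (components).
    """

    r_jk: float
    r_jh: float
    r_kh: float
    n: int

    def __post_init__(self) -> None:
        for r in (self.r_jk, self.r_jh, self.r_kh):
            if not -1 <= r <= 1:
                raise ValueError("correlations must lie in [-1,1]")
        if self.n < 4:
            raise ValueError("need n >= 4")


def pearson_filon_test(dc: DependentCorrelations) -> tuple[float, float]:
    """Z test for equality of two dependent overlapping correlations.

    Fisher-z form (ZPF): the difference of the z-transformed correlations is
    scaled by its null standard error, using the Pearson-Filon covariance
    term evaluated at the pooled correlation. Returns (z, two-sided p).
    Degenerate |r| = 1 inputs are rejected (the transform diverges).
    """
    if 1.0 in (abs(dc.r_jk), abs(dc.r_jh)):
        raise ValueError("|r| = 1: Fisher transform undefined")
    rbar = (dc.r_jk + dc.r_jh) / 2.0
    # covariance of the two correlations under the null r_jk = r_jh = rbar
    cov = (
        dc.r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - dc.r_kh**2)
    ) / (1 - rbar**2) ** 2
    dz = np.arctanh(dc.r_jk) - np.arctanh(dc.r_jh)
    z = dz * np.sqrt((dc.n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def component_enrichment(
    query_genes: Iterable[str], component_set: Iterable[str], universe_size: int
) -> float:
    """Upper-tail hypergeometric p for the query/component overlap.

    Probability of observing at least the overlap when ``len(query)`` genes
    are drawn without replacement from a universe containing
    ``len(component_set)`` component genes.
    """
    q, comp = set(query_genes), set(component_set)
    if universe_size < len(q | comp):
        raise ValueError("universe_size smaller than the union of the sets")
    overlap = len(q & comp)
    return float(stats.hypergeom.sf(overlap - 1, universe_size, len(comp), len(q)))


@dataclasses.dataclass
class ProfileComparison:
    """Correlation structure of two count profiles against a reference."""

    r_ab: float
    r_a_ref: float | None = None
    r_b_ref: float | None = None
    z: float | None = None
    p_pearson_filon: float | None = None


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance profile: correlation undefined", stacklevel=3)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def profile_comparison(
    profile_a: Sequence[float] | pd.Series,
    profile_b: Sequence[float] | pd.Series,
    profile_ref: Sequence[float] | pd.Series | None = None,
) -> ProfileComparison:
    """Pearson correlations between component count profiles.

    With a shared reference profile, also tests whether the reference
    correlates differently with a than with b (Pearson-Filon on the
    dependent correlations r_a_ref vs r_b_ref, sharing the reference).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    res = ProfileComparison(r_ab=_corr(a, b))
    if profile_ref is not None:
        ref = np.asarray(profile_ref, dtype=float)
        if ref.shape != a.shape:
            raise ValueError("reference profile must have equal length")
        res.r_a_ref = _corr(ref, a)
        res.r_b_ref = _corr(ref, b)
        if not (np.isnan(res.r_a_ref) or np.isnan(res.r_b_ref) or np.isnan(res.r_ab)):
            dc = DependentCorrelations(
                r_jk=res.r_a_ref, r_jh=res.r_b_ref, r_kh=res.r_ab, n=len(a)
            )
            res.z, res.p_pearson_filon = pearson_filon_test(dc)
    return res
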