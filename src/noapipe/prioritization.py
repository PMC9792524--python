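"""Recessive-variant prioritization cascade for azoospermia exome findings.

Stage 1 removes individual findings on variant-level evidence: genotype
p-value (PSAP-style) and population allele frequency, recurrence of
identical homozygous/hemizygous genotypes across individuals, recurrence or
cis configuration of compound-heterozygous pairs, and genes enriched for
many distinct rare qualifying variants. Stage 2 applies inheritance-mode
aware aggregation criteria tied to gene annotations: loss of function,
prior infertility evidence, elevated testis expression, and premeiotic
single-cell expression. Finally, genes with surviving findings in both the
case and a control cohort are subtracted from both.

Every rule is evaluated as a predicate on the *input* table, so the
surviving set is independent of rule order; the audit trail records the
first matching rule per dropped finding in the documented order.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .burden import ContingencyTable
from .synthetic_data import AUTOSOMES

logger = logging.getLogger(__name__)

RECESSIVE_MODELS = frozenset({"AR_hom", "AR_comphet", "XL", "YL"})
HOM_HEMI_MODELS = frozenset({"AR_hom", "XL", "YL"})

#: Stage-1 rule names in documented application order.
STAGE1_RULES = (
    "non_recessive",
    "psap_p",
    "popmax_maf",
    "recurrent_hom_hemi",
    "recurrent_comphet_pair",
    "cis_comphet",
    "comphet_proximity",
    "gene_enrichment",
)


@dataclasses.dataclass
class FilterConfig:
    """Thresholds of the prioritization cascade.

    Defaults reproduce the discovery-cohort settings: genotype p <= 1e-3,
    popmax MAF <= 0.01, identical hom/hemi genotypes in at most 3
    individuals, identical compound-het pairs in at most 1 case, genes with
    more than 3 individuals carrying distinct very-rare pathogenic variants
    (p < 1e-4) removed, and premeiotic expression > 0.5 TPM required for
    genes without elevated testis expression. ``comphet_min_distance_bp=10``
    additionally drops het pairs within 10 bp (a replication-cohort
    matching rule); the default 0 disables it.
    """

    psap_p_max: float = 1e-3
    popmax_maf_max: float = 0.01
    identical_hom_hemi_max_individuals: int = 3
    identical_comphet_pair_max_individuals: int = 1
    gene_enrichment_psap_p: float = 1e-4
    gene_enrichment_max_individuals: int = 3
    comphet_min_distance_bp: int = 0
    premeiotic_tpm_min: float = 0.5
    recessive_only: bool = True

    def __post_init__(self) -> None:
        for name in (
            "identical_hom_hemi_max_individuals",
            "identical_comphet_pair_max_individuals",
            "gene_enrichment_max_individuals",
            "comphet_min_distance_bp",
            "premeiotic_tpm_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("psap_p_max", "gene_enrichment_psap_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0,1]")
        if not 0 <= self.popmax_maf_max <= 1:
            raise ValueError("popmax_maf_max must lie in [0,1]")


@dataclasses.dataclass
class PrioritizationResult:
    """Surviving findings with a complete audit trail.

    ``audit`` assigns every input finding either ``'pass'`` or the first
    rule that removed it, so ``|input| == |surviving| + |dropped|`` always
    holds. ``detection_rate`` is filled by :func:`detection_summary`.
    """

    surviving: pd.DataFrame
    audit: pd.Series
    config: FilterConfig
    detection_rate: dict = dataclasses.field(default_factory=dict)

    @property
    def surviving_genes(self) -> set[str]:
        return set(self.surviving["gene_id"].unique())

    def gene_to_cases(self) -> dict[str, list[str]]:
        return {
            g: sorted(df["sample_id"].unique())
            for g, df in self.surviving.groupby("gene_id")
        }

    def rule_counts(self) -> pd.Series:
        return self.audit.value_counts()


def _stage1_masks(
    findings: pd.DataFrame, case_ids: pd.Index | None, cfg: FilterConfig
) -> dict[str, pd.Series]:
    """Boolean drop-masks per stage-1 rule, each evaluated on the full input."""
    f = findings
    masks: dict[str, pd.Series] = {}

    masks["non_recessive"] = (
        ~f["model"].isin(RECESSIVE_MODELS)
        if cfg.recessive_only
        else pd.Series(False, index=f.index)
    )
    masks["psap_p"] = f["psap_p"] > cfg.psap_p_max
    masks["popmax_maf"] = f["popmax_maf"] > cfg.popmax_maf_max

    hom = f["model"].isin(HOM_HEMI_MODELS)
    carriers = f[hom].groupby("genotype_key")["sample_id"].nunique()
    hot_keys = carriers[carriers > cfg.identical_hom_hemi_max_individuals].index
    masks["recurrent_hom_hemi"] = hom & f["genotype_key"].isin(hot_keys)

    chet = f["model"] == "AR_comphet"
    chet_in_cases = chet & (
        f["sample_id"].isin(case_ids) if case_ids is not None else True
    )
    pair_carriers = f[chet_in_cases].groupby("genotype_key")["sample_id"].nunique()
    hot_pairs = pair_carriers[
        pair_carriers > cfg.identical_comphet_pair_max_individuals
    ].index
    masks["recurrent_comphet_pair"] = chet & f["genotype_key"].isin(hot_pairs)

    phase = f["phase"].fillna("unknown") if "phase" in f else pd.Series("unknown", index=f.index)
    n_unknown = int((chet & (phase == "unknown")).sum())
    if n_unknown:
        logger.info("retained %d comphet pairs with unknown phase", n_unknown)
    masks["cis_comphet"] = chet & (phase == "cis")

    dist = pd.to_numeric(f.get("pair_distance_bp"), errors="coerce")
    masks["comphet_proximity"] = chet & (dist < cfg.comphet_min_distance_bp)

    # genes where many individuals carry *distinct* very-rare qualifying
    # variants; identical-genotype pile-ups are the recurrence rules' job
    q = (f["psap_p"] < cfg.gene_enrichment_psap_p) & (
        f["popmax_maf"] < cfg.popmax_maf_max
    )
    per_gene = f[q].groupby("gene_id").agg(
        n_ind=("sample_id", "nunique"), n_keys=("genotype_key", "nunique")
    )
    hot_genes = per_gene[
        (per_gene["n_ind"] > cfg.gene_enrichment_max_individuals)
        & (per_gene["n_keys"] >= 2)
    ].index
    masks["gene_enrichment"] = f["gene_id"].isin(hot_genes)
    return masks


def apply_variant_filters(
    findings: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    cfg: FilterConfig | None = None,
) -> PrioritizationResult:
    """Stage 1: variant-level, genotype-recurrence and gene-enrichment filters.

    ``cohort`` (sample table with ``status``) restricts the compound-het
    pair-recurrence count to case samples; without it all samples count.
    Compound-het findings lacking phase are treated as phase-unknown and
    retained (logged), never silently dropped.
    """
    cfg = cfg or FilterConfig()
    if cohort is not None:
        known = set(cohort["sample_id"])
        unknown = set(findings["sample_id"]) - known
        if unknown:
            raise ValueError(f"findings reference unknown samples: {sorted(unknown)[:5]}")
    case_ids = (
        pd.Index(cohort.loc[cohort["status"] == "case", "sample_id"])
        if cohort is not None
        else None
    )
    masks = _stage1_masks(findings, case_ids, cfg)
    audit = pd.Series("pass", index=findings.index, dtype=object)
    for rule in STAGE1_RULES:
        hit = masks[rule] & (audit == "pass")
        audit[hit] = rule
    surviving = findings[audit == "pass"].copy()
    return PrioritizationResult(surviving=surviving, audit=audit, config=cfg)


#: Stage-2 rule names.
STAGE2_RULES = ("aggregation_autosomal", "aggregation_x", "aggregation_y", "premeiotic_tpm")


def apply_aggregation_criteria(
    stage1: PrioritizationResult,
    genes: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> PrioritizationResult:
    """Stage 2: inheritance-mode aware aggregation of plausible disease genes.

    Autosomal findings must be LoF, in a known-infertility gene, or in a
    gene with elevated testis expression. X-linked findings require
    elevated testis expression *and* (LoF or known infertility); Y-linked
    findings must be LoF. Any kept finding in a gene without elevated
    testis expression additionally needs premeiotic single-cell expression
    above ``premeiotic_tpm_min``.
    """
    cfg = cfg or stage1.config
    f = stage1.surviving
    ann = genes.set_index("gene_id")
    missing = set(f["gene_id"]) - set(ann.index)
    if missing:
        raise ValueError(f"findings reference unknown genes: {sorted(missing)[:5]}")
    chrom = f["gene_id"].map(ann["chromosome"])
    bad = ~chrom.isin(list(AUTOSOMES) + ["X", "Y"])
    if bad.any():
        raise ValueError(f"unknown chromosome labels: {sorted(chrom[bad].unique())}")

    lof = f["consequence"] == "lof"
    known = f["gene_id"].map(ann["known_infertility"]).astype(bool)
    elevated = f["gene_id"].map(ann["testis_class"]) != "none"
    tpm = f["gene_id"].map(ann["premeiotic_tpm"])

    autosomal = chrom.isin(AUTOSOMES)
    on_x = chrom == "X"
    on_y = chrom == "Y"

    keep = (
        (autosomal & (lof | known | elevated))
        | (on_x & elevated & (lof | known))
        | (on_y & lof)
    )

    audit = stage1.audit.copy()
    drop_agg = ~keep
    audit[f.index[drop_agg & autosomal]] = "aggregation_autosomal"
    audit[f.index[drop_agg & on_x]] = "aggregation_x"
    audit[f.index[drop_agg & on_y]] = "aggregation_y"

    # premeiotic-expression backstop for genes without elevated testis
    # expression; Y-linked findings are exempt (their criterion is LoF only)
    drop_tpm = keep & ~elevated & ~on_y & ~(tpm > cfg.premeiotic_tpm_min)
    audit[f.index[drop_tpm]] = "premeiotic_tpm"

    surviving = f[keep & ~drop_tpm].copy()
    return PrioritizationResult(surviving=surviving, audit=audit, config=cfg)


def subtract_shared_genes(
    case_result: PrioritizationResult, control_result: PrioritizationResult
) -> tuple[PrioritizationResult, PrioritizationResult]:
    """Remove genes with surviving findings in both cohorts from both.

    A conservative step against platform artifacts: genuinely shared genes
    are unlikely to be case-specific disease causes. Output gene sets are
    disjoint by construction.
    """
    shared = case_result.surviving_genes & control_result.surviving_genes

    def cut(res: PrioritizationResult) -> PrioritizationResult:
        drop = res.surviving["gene_id"].isin(shared)
        audit = res.audit.copy()
        audit[res.surviving.index[drop]] = "shared_with_other_cohort"
        return PrioritizationResult(
            surviving=res.surviving[~drop].copy(), audit=audit, config=res.config
        )

    return cut(case_result), cut(control_result)


def detection_summary(
    result: PrioritizationResult, cohort: pd.DataFrame
) -> tuple[dict[str, dict], ContingencyTable]:
    """Per-stratum detection rates and the consanguineous-vs-outbred 2x2.

    The rate in a stratum is the fraction of its cases with at least one
    surviving finding. Empty strata get rate NaN and are flagged. The
    returned table is rows = (consanguineous, outbred) x cols =
    (solved, unsolved), ready for an exact carrier-proportion test.
    """
    cases = cohort[cohort["status"] == "case"]
    solved_ids = set(result.surviving["sample_id"])
    out: dict[str, dict] = {}
    counts: dict[str, tuple[int, int]] = {}
    for name, stratum in (
        ("consanguineous", cases[cases["consanguineous"]]),
        ("outbred", cases[~cases["consanguineous"]]),
    ):
        n = len(stratum)
        k = int(stratum["sample_id"].isin(solved_ids).sum())
        counts[name] = (k, n - k)
        out[name] = {
            "n_cases": n,
            "n_solved": k,
            "rate": (k / n) if n else float("nan"),
            "empty_stratum": n == 0,
        }
        if n == 0:
            logger.warning("detection rate undefined for empty stratum %r", name)
    table = ContingencyTable(
        a=counts["consanguineous"][0],
        b=counts["consanguineous"][1],
        c=counts["outbred"][0],
        d=counts["outbred"][1],
    )
    result.detection_rate = {k: v["rate"] for k, v in out.items()}
    return out, table
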