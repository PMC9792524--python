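"""Synthetic cohorts with planted truth for azoospermia gene-discovery statistics.

Every input the downstream modules consume — annotated variant findings,
gene annotations, cohort tables, ROH segments, expression-component
loadings, piRNA length histograms and tissue expression matrices — can be
generated here with known ground truth, so the whole pipeline is testable
without any sequencing data.

The genetic model is monogenic-recessive: each affected man carries at most
one causal gene, drawn uniformly from a fixed pool of disease genes, and is
"solved" with a stratum-specific discovery rate (much higher in
consanguineous men). False-positive findings — genotypes that pass every
filter but are unrelated to disease — are added to cases and controls at a
configurable per-individual rate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y")
TESTIS_CLASSES = ("tissue_enriched", "group_enriched", "tissue_enhanced", "none")
MODELS = ("AR_hom", "AR_comphet", "XL", "YL")

#: Total autosomal length used as the FROH denominator (bp).
AUTOSOME_LENGTH_BP = 2_880_000_000

#: piRNA read-length support (nt), inclusive.
PIRNA_MIN_LEN = 25
PIRNA_MAX_LEN = 45
#: Reads strictly shorter than this are "mature" piRNAs.
PIRNA_MATURE_CUTOFF = 32

# Study conditions used as generator defaults: detection-rate strata of the
# discovery cohort (76.4% of 72 consanguineous cases solved vs 14.9% of the
# 852 others) and the ~6% background rate of spurious prioritized genotypes
# seen in non-reproductive controls.
DEFAULT_DISCOVERY_RATES = {"consanguineous": 0.764, "outbred": 0.149}
DEFAULT_FP_RATE = 0.06


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

DEFAULT_CLASS_PROPORTIONS = {
    # roughly the HPA testis picture: ~10% of genes with elevated testis
    # expression, split across the three specificity classes
    "tissue_enriched": 0.05,
    "group_enriched": 0.02,
    "tissue_enhanced": 0.04,
    "none": 0.89,
}

DEFAULT_CHROM_WEIGHTS = dict(
    {c: 0.042 for c in AUTOSOMES}, X=0.066, Y=0.01
)  # ~92.4% autosomal


def generate_gene_universe(
    n_genes: int,
    class_proportions: Mapping[str, float] | None = None,
    seed: int | None = None,
    chrom_weights: Mapping[str, float] | None = None,
    known_infertility_rate: float = 0.05,
) -> pd.DataFrame:
    """Generate a table of gene annotations.

    Columns: ``gene_id``, ``chromosome`` (``'1'``..``'22'``, ``'X'``,
    ``'Y'``), ``is_lof_tolerant_context``, ``testis_class``,
    ``known_infertility``, ``premeiotic_tpm``.

    ``class_proportions`` are simplex weights over the four testis
    specificity classes; ``premeiotic_tpm`` is log-normal so that a
    realistic fraction of genes clears the 0.5-TPM premeiotic-expression
    rule used in aggregation.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1 (empty gene universe rejected)")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    if set(props) != set(TESTIS_CLASSES):
        raise ValueError(f"class_proportions must have keys {TESTIS_CLASSES}")
    p = np.array([props[c] for c in TESTIS_CLASSES], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("class_proportions must be non-negative and sum to 1")

    weights = dict(chrom_weights or DEFAULT_CHROM_WEIGHTS)
    if set(weights) - set(CHROMOSOMES):
        raise ValueError("chrom_weights contains unknown chromosome labels")
    w = np.array([weights.get(c, 0.0) for c in CHROMOSOMES], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("chrom_weights must be non-negative with positive sum")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    gene_id = np.array([f"G{i:06d}" for i in range(1, n_genes + 1)])
    chromosome = rng.choice(CHROMOSOMES, size=n_genes, p=w)
    testis_class = rng.choice(TESTIS_CLASSES, size=n_genes, p=p)
    known_infertility = rng.random(n_genes) < known_infertility_rate
    premeiotic_tpm = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    is_lof_tolerant_context = rng.random(n_genes) < 0.1
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "chromosome": chromosome,
            "is_lof_tolerant_context": is_lof_tolerant_context,
            "testis_class": testis_class,
            "known_infertility": known_infertility,
            "premeiotic_tpm": premeiotic_tpm,
        }
    )


def aggregation_ready_genes(genes: pd.DataFrame, premeiotic_tpm_min: float = 0.5) -> pd.Series:
    """Gene ids in which a LoF finding survives the aggregation criteria.

    Autosomal LoF always meets criterion (1) but still needs premeiotic
    expression when the gene has no elevated testis expression; X-linked
    findings additionally require testis-elevated expression; Y-linked LoF
    always passes. Causal pools drawn from this set guarantee that planted
    truth is never rejected by the cascade.
    """
    cls_ok = genes["testis_class"] != "none"
    tpm_ok = cls_ok | (genes["premeiotic_tpm"] > premeiotic_tpm_min)
    on_x = genes["chromosome"] == "X"
    ok = tpm_ok & (~on_x | cls_ok)
    return genes.loc[ok, "gene_id"]


# ---------------------------------------------------------------------------
# cohort + findings + truth
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TruthTable:
    """Planted ground truth: causal gene per case, truth flag per finding."""

    case_causal: pd.DataFrame  # sample_id, causal_gene_id (NA if unsolved)
    finding_truth: pd.Series  # is_planted_true, aligned with findings index

    def recurrence(self) -> tuple[float, int]:
        """Observed recurrence among planted-true causal genes.

        Returns ``(r, n_hits)`` with ``r`` = recurrent distinct genes /
        distinct genes, the statistic the pool-size estimator inverts.
        """
        hits = self.case_causal["causal_gene_id"].dropna()
        if hits.empty:
            return float("nan"), 0
        counts = hits.value_counts()
        return float((counts >= 2).sum() / len(counts)), int(len(hits))


def _finding_row(
    rng: np.random.Generator,
    sample_id: str,
    gene: pd.Series,
    key: str,
    force_lof: bool = False,
) -> dict:
    chrom = gene["chromosome"]
    if chrom == "X":
        model, lof = "XL", True
    elif chrom == "Y":
        model, lof = "YL", True
    else:
        model = "AR_hom" if rng.random() < 0.7 else "AR_comphet"
        # a missense finding only meets the aggregation criteria when the
        # gene carries infertility evidence or elevated testis expression
        missense_ok = bool(gene["known_infertility"]) or gene["testis_class"] != "none"
        lof = force_lof or not missense_ok or rng.random() < 0.5
    comphet = model == "AR_comphet"
    return {
        "sample_id": sample_id,
        "gene_id": gene["gene_id"],
        "model": model,
        "genotype_key": key,
        "consequence": "lof" if lof else "missense",
        "popmax_maf": 10.0 ** rng.uniform(-5, np.log10(0.01)),
        "psap_p": 10.0 ** rng.uniform(-6, -3),
        "phase": "trans" if comphet else pd.NA,
        "pair_distance_bp": int(rng.integers(50, 100_000)) if comphet else pd.NA,
    }


def generate_cohort(
    genes: pd.DataFrame,
    pool_gene_ids: Sequence[str],
    n_cases: int,
    n_controls: int,
    consang_fraction: float = 72 / 924,
    case_discovery_rate_by_stratum: Mapping[str, float] | None = None,
    fp_rate: float = DEFAULT_FP_RATE,
    seed: int | None = None,
    fp_within_pool: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate individuals, variant findings and the planted truth table.

    Each case independently receives one planted causal finding with its
    stratum's discovery rate, the causal gene uniform over the pool.
    False-positive findings (passing every filter, unrelated to disease)
    are added to cases and controls with per-individual probability
    ``fp_rate``; they land on genes outside the causal pool unless
    ``fp_within_pool`` is set. Male sex-chromosome genotypes are always
    hemizygous (models XL/YL) — no heterozygous X/Y calls are emitted.
    """
    rates = dict(case_discovery_rate_by_stratum or DEFAULT_DISCOVERY_RATES)
    if not {"consanguineous", "outbred"} <= set(rates):
        raise ValueError("discovery rates must cover 'consanguineous' and 'outbred'")
    for k, v in rates.items():
        if not 0 <= v <= 1:
            raise ValueError(f"discovery rate {k}={v} outside [0,1]")
    if not 0 <= fp_rate <= 1:
        raise ValueError("fp_rate outside [0,1]")
    if not 0 <= consang_fraction <= 1:
        raise ValueError("consang_fraction outside [0,1]")
    pool = pd.Index(pool_gene_ids).unique()
    if not pool.isin(genes["gene_id"]).all():
        raise ValueError("pool_gene_ids must be a subset of the gene universe")
    if len(pool) == 0 and any(v > 0 for v in rates.values()):
        raise ValueError("empty causal pool with non-zero discovery rate")

    rng = np.random.default_rng(seed)
    gene_by_id = genes.set_index("gene_id", drop=False)

    n_consang = int(round(n_cases * consang_fraction))
    individuals = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(1, n_cases + n_controls + 1)],
            "sex": "male",
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "consanguineous": [True] * n_consang
            + [False] * (n_cases - n_consang + n_controls),
        }
    )

    rows: list[dict] = []
    truth_flags: list[bool] = []
    causal: list[object] = []
    key_counter = 0

    cases = individuals[individuals["status"] == "case"]
    for _, ind in cases.iterrows():
        stratum = "consanguineous" if ind["consanguineous"] else "outbred"
        if len(pool) and rng.random() < rates[stratum]:
            g = gene_by_id.loc[pool[rng.integers(len(pool))]]
            key_counter += 1
            rows.append(_finding_row(rng, ind["sample_id"], g, f"V{key_counter:07d}"))
            truth_flags.append(True)
            causal.append(g["gene_id"])
        else:
            causal.append(pd.NA)

    # false positives: pass every filter but are not causal
    fp_universe = aggregation_ready_genes(genes)
    if not fp_within_pool:
        fp_universe = fp_universe[~fp_universe.isin(pool)]
    fp_universe = fp_universe.to_numpy()
    if fp_rate > 0 and len(fp_universe) == 0:
        raise ValueError("no genes available for false-positive placement")
    for _, ind in individuals.iterrows():
        if fp_rate > 0 and rng.random() < fp_rate:
            g = gene_by_id.loc[fp_universe[rng.integers(len(fp_universe))]]
            key_counter += 1
            rows.append(
                _finding_row(rng, ind["sample_id"], g, f"V{key_counter:07d}", force_lof=True)
            )
            truth_flags.append(False)

    findings = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene_id",
            "model",
            "genotype_key",
            "consequence",
            "popmax_maf",
            "psap_p",
            "phase",
            "pair_distance_bp",
        ],
    )
    truth = TruthTable(
        case_causal=pd.DataFrame(
            {"sample_id": cases["sample_id"].to_numpy(), "causal_gene_id": causal}
        ),
        finding_truth=pd.Series(truth_flags, index=findings.index, name="is_planted_true"),
    )
    return individuals, findings, truth


# ---------------------------------------------------------------------------
# ROH segments
# ---------------------------------------------------------------------------

# Five ROH length classes on the natural-log scale (bp). Means correspond to
# ~50 kb, 150 kb, 400 kb, 1.5 Mb and 8 Mb; class 5 captures recent
# consanguinity. Adjacent means are >= 3.9 planted sds apart so nearest-mean
# assignment is near-perfect.
DEFAULT_ROH_CLASS_PARAMS = (
    (np.log(5.0e4), 0.25, 0.40),
    (np.log(1.5e5), 0.25, 0.27),
    (np.log(4.0e5), 0.25, 0.18),
    (np.log(1.5e6), 0.25, 0.10),
    (np.log(8.0e6), 0.25, 0.05),
)

DEFAULT_SEGMENTS_PER_CLASS = {1: 25, 2: 15, 3: 8, 4: 4, 5: 0}


def generate_roh(
    individuals: pd.DataFrame,
    class_params: Sequence[tuple[float, float, float]] | None = None,
    segments_per_class: Mapping[int, int] | None = None,
    seed: int | None = None,
    froh_threshold: float = 0.03,
    autosome_length_bp: int = AUTOSOME_LENGTH_BP,
) -> pd.DataFrame:
    """Generate per-sample ROH segments from a 5-class log-length mixture.

    Consanguineous individuals receive additional class-5 (longest-class)
    segments until their planted class-5 total exceeds
    ``1.5 * froh_threshold * autosome_length_bp``, guaranteeing a planted
    FROH above the labelling threshold. Intervals are 0-based half-open and
    non-overlapping within each (sample, chromosome). The ``true_class``
    column is planted truth for parameter-recovery tests, not an output of
    any inference.
    """
    params = tuple(class_params or DEFAULT_ROH_CLASS_PARAMS)
    if len(params) != 5:
        raise ValueError("exactly 5 mixture components required")
    for mean, sd, weight in params:
        if sd <= 0:
            raise ValueError("component sd must be > 0")
        if weight < 0:
            raise ValueError("component weight must be >= 0")
    per_class = dict(
        DEFAULT_SEGMENTS_PER_CLASS if segments_per_class is None else segments_per_class
    )
    order = np.argsort([m for m, _, _ in params])  # class index by mean
    longest = int(order[-1])  # 0-based index of class 5

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for _, ind in individuals.iterrows():
        cursors: dict[str, int] = {}
        lengths: list[int] = []
        classes: list[int] = []
        for ci, (mean, sd, _) in enumerate(params):
            n = int(per_class.get(ci + 1, 0))
            if n:
                lengths.extend(np.exp(rng.normal(mean, sd, size=n)).astype(int) + 1)
                classes.extend([ci + 1] * n)
        if bool(ind.get("consanguineous", False)):
            target = 1.5 * froh_threshold * autosome_length_bp
            mean, sd, _ = params[longest]
            total = sum(
                l for l, c in zip(lengths, classes) if c == longest + 1
            )
            while total < target:
                l = int(np.exp(rng.normal(mean, sd))) + 1
                lengths.append(l)
                classes.append(longest + 1)
                total += l
        for l, c in zip(lengths, classes):
            chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
            start = cursors.get(chrom, int(rng.integers(0, 1_000_000)))
            rows.append((ind["sample_id"], chrom, start, start + l, c))
            cursors[chrom] = start + l + int(rng.integers(1, 500_000))
    return pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start", "end", "true_class"]
    )


# ---------------------------------------------------------------------------
# component loadings
# ---------------------------------------------------------------------------


def generate_loadings(
    gene_ids: Sequence[str],
    n_components: int,
    planted_sets: Mapping[str, Sequence[str]] | None = None,
    noise_sd: float = 0.1,
    seed: int | None = None,
    planted_loading: float = 5.0,
) -> pd.DataFrame:
    """Components-by-genes loadings with planted gene modules.

    Planted genes get a high positive loading (``planted_loading`` plus a
    small positive jitter) on their component; the background is zero-mean
    Gaussian noise. Component ids are ``C1..Cn``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    gene_ids = list(gene_ids)
    comp_ids = [f"C{i}" for i in range(1, n_components + 1)]
    planted = {k: list(v) for k, v in (planted_sets or {}).items()}
    for comp, gs in planted.items():
        if comp not in comp_ids:
            raise ValueError(f"planted component {comp!r} outside C1..C{n_components}")
        missing = set(gs) - set(gene_ids)
        if missing:
            raise ValueError(f"planted genes not in universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    mat = rng.normal(0.0, noise_sd, size=(n_components, len(gene_ids)))
    loadings = pd.DataFrame(mat, index=comp_ids, columns=gene_ids)
    for comp, gs in planted.items():
        jitter = np.abs(rng.normal(0.0, planted_loading / 10.0, size=len(gs)))
        loadings.loc[comp, gs] = planted_loading + jitter
    return loadings


# ---------------------------------------------------------------------------
# piRNA histograms
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PiRNAHistogram:
    """Read counts per length (25..45 nt) plus the spike-in count."""

    counts: pd.Series  # index = length (nt), values = non-negative counts
    spike_in_count: int

    def __post_init__(self) -> None:
        idx = self.counts.index.to_numpy()
        if len(idx) and ((idx < PIRNA_MIN_LEN).any() or (idx > PIRNA_MAX_LEN).any()):
            raise ValueError(f"lengths must lie in [{PIRNA_MIN_LEN},{PIRNA_MAX_LEN}]")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if self.spike_in_count <= 0:
            raise ValueError("spike_in_count must be positive")

    def total(self) -> float:
        return float(self.counts.sum())


# mature piRNAs peak at 29-30 nt; immature (unprocessed) reads spread 32-45 nt
_MATURE_LENGTHS = np.arange(PIRNA_MIN_LEN, PIRNA_MATURE_CUTOFF)
_MATURE_W = np.array([1, 2, 5, 10, 14, 10, 6], dtype=float)
_IMMATURE_LENGTHS = np.arange(PIRNA_MATURE_CUTOFF, PIRNA_MAX_LEN + 1)
_IMMATURE_W = np.linspace(5.0, 1.0, len(_IMMATURE_LENGTHS))


def generate_pirna_pair(
    mature_fraction_case: float,
    mature_fraction_control: float,
    n_reads: int = 100_000,
    spike_in_count: int = 1_000,
    seed: int | None = None,
) -> tuple[PiRNAHistogram, PiRNAHistogram]:
    """Case/control piRNA length histograms with planted mature fractions.

    Each read is mature (<32 nt) with the requested probability; lengths
    within the mature and immature ranges follow fixed unimodal shapes.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    for f in (mature_fraction_case, mature_fraction_control):
        if not 0 <= f <= 1:
            raise ValueError("mature fractions must lie in [0,1]")
    rng = np.random.default_rng(seed)

    def one(frac: float) -> PiRNAHistogram:
        n_mat = rng.binomial(n_reads, frac)
        counts = pd.Series(0, index=np.arange(PIRNA_MIN_LEN, PIRNA_MAX_LEN + 1))
        counts.loc[_MATURE_LENGTHS] += rng.multinomial(n_mat, _MATURE_W / _MATURE_W.sum())
        counts.loc[_IMMATURE_LENGTHS] += rng.multinomial(
            n_reads - n_mat, _IMMATURE_W / _IMMATURE_W.sum()
        )
        return PiRNAHistogram(counts=counts, spike_in_count=spike_in_count)

    return one(mature_fraction_case), one(mature_fraction_control)


# ---------------------------------------------------------------------------
# tissue expression matrix
# ---------------------------------------------------------------------------

#: Default tissue-panel size, matching the 37-tissue bulk RNA-seq panel the
#: specificity classes were originally defined on.
DEFAULT_N_TISSUES = 37


def _enhanced_profile(rng: np.random.Generator, n: int, fold: float = 5.0) -> np.ndarray:
    """One tissue >= fold x overall mean, but no tissue/group enrichment.

    Built as a decaying chain where every top-k group (k = 2..7) narrowly
    fails the group rule; infeasible below ~10 tissues, hence the generator
    guard.
    """
    vals = [60.0, 13.0]
    for _ in range(6):  # positions 3..8
        vals.append(1.15 * float(np.mean(vals)) / fold)
    vals.extend([vals[-1] * 0.9] * (n - len(vals)))
    v = np.array(vals[:n])
    assert v[0] >= fold * v.mean(), "enhanced construction failed"
    return v


def generate_tissue_matrix(
    planted_classes: Mapping[str, str],
    n_tissues: int = DEFAULT_N_TISSUES,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tissues-by-genes TPM matrix realizing the planted specificity classes.

    Rows are tissues ``T01..``, columns genes. Each gene's profile is
    constructed so the five-fold specificity classifier recovers its
    planted class; tissue order is randomized per gene. Profiles carry a
    +-2% multiplicative jitter, small enough to preserve every class-rule
    margin.
    """
    if n_tissues < 8:
        raise ValueError("n_tissues must be >= 8 (group classes need 2-7 + 1 tissues)")
    bad = set(planted_classes.values()) - set(TESTIS_CLASSES)
    if bad:
        raise ValueError(f"unknown specificity classes: {sorted(bad)}")
    if "tissue_enhanced" in planted_classes.values() and n_tissues < 10:
        raise ValueError(
            "planting tissue_enhanced needs >= 10 tissues: with fewer, a "
            "5-fold-over-mean tissue is necessarily tissue- or group-enriched"
        )
    rng = np.random.default_rng(seed)
    tissues = [f"T{i:02d}" for i in range(1, n_tissues + 1)]
    cols = {}
    for gene, cls in planted_classes.items():
        if cls == "tissue_enriched":
            v = rng.uniform(2.0, 10.0, size=n_tissues)
            v[0] = 5.5 * v[1:].max()
        elif cls == "group_enriched":
            g = int(rng.integers(2, min(7, n_tissues - 1) + 1))
            v = np.full(n_tissues, 2.0)
            v[:g] = 40.0
        elif cls == "tissue_enhanced":
            v = _enhanced_profile(rng, n_tissues)
        else:  # none: flat
            v = rng.uniform(8.0, 12.0, size=n_tissues)
        v = v * rng.uniform(0.98, 1.02, size=n_tissues)
        cols[gene] = rng.permutation(v)
    return pd.DataFrame(cols, index=tissues)
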