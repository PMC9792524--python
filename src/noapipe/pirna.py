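"""piRNA length-distribution statistics.

Mature piRNAs are ~26-31 nt; defective processing of the long precursor
transcripts shifts the testis small-RNA length distribution toward longer
immature species. The maturity statistic is the fraction of reads strictly
shorter than 32 nt within the 25-45 nt piRNA window. Case/control
comparisons use the exact hypergeometric (one-sided Fisher) test on raw
read counts; spike-in normalization rescales counts for visualization and
cross-library comparison but cannot change the mature fraction.
"""

from __future__ import annotations

import dataclasses
import warnings

import pandas as pd

from .burden import ContingencyTable, fisher_exact
from .synthetic_data import PIRNA_MATURE_CUTOFF, PiRNAHistogram


@dataclasses.dataclass
class MaturityResult:
    """Case/control piRNA maturity comparison."""

    mature_fraction_case: float
    mature_fraction_control: float
    fold_change: float  # control / case
    p_hypergeometric: float
    table: ContingencyTable


def _counts(hist: PiRNAHistogram | pd.Series) -> pd.Series:
    return hist.counts if isinstance(hist, PiRNAHistogram) else hist


def spike_normalize(hist: PiRNAHistogram) -> pd.Series:
    """Counts divided by the spike-in count; length support unchanged."""
    if hist.spike_in_count <= 0:
        raise ValueError("spike_in_count must be positive")
    return hist.counts.astype(float) / float(hist.spike_in_count)


def mature_fraction(
    hist: PiRNAHistogram | pd.Series, cutoff: int = PIRNA_MATURE_CUTOFF
) -> float:
    """Fraction of reads strictly shorter than ``cutoff`` nt.

    Undefined (NaN, with a warning) when the histogram is empty.
    """
    counts = _counts(hist)
    total = float(counts.sum())
    if total == 0:
        warnings.warn("empty histogram: mature fraction undefined", stacklevel=2)
        return float("nan")
    mature = float(counts[counts.index < cutoff].sum())
    return mature / total


def compare_maturity(
    case_hist: PiRNAHistogram | pd.Series,
    control_hist: PiRNAHistogram | pd.Series,
    cutoff: int = PIRNA_MATURE_CUTOFF,
) -> MaturityResult:
    """Test for reduced piRNA maturity in the case sample.

    Builds the 2x2 of (mature, immature) x (case, control) raw read counts
    and computes the one-sided hypergeometric probability that the case
    carries as few or fewer mature reads (alternative: case maturity lower).
    ``fold_change`` is control fraction / case fraction.
    """
    cc, kc = _counts(case_hist), _counts(control_hist)
    ct, kt = float(cc.sum()), float(kc.sum())
    if ct <= 0 or kt <= 0:
        raise ValueError("both histograms must contain reads")
    cm = int(cc[cc.index < cutoff].sum())
    km = int(kc[kc.index < cutoff].sum())
    table = ContingencyTable(a=cm, b=int(ct) - cm, c=km, d=int(kt) - km)
    p = fisher_exact(table, "less")
    fc = cm / ct
    fk = km / kt
    return MaturityResult(
        mature_fraction_case=fc,
        mature_fraction_control=fk,
        fold_change=(fk / fc) if fc > 0 else float("inf"),
        p_hypergeometric=p,
        table=table,
    )
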