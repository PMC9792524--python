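"""Consanguinity from runs of homozygosity (ROH).

ROH segment lengths are heavy-tailed mixtures: short runs reflect ancient
shared haplotypes, the longest class recent parental relatedness. A
five-component Gaussian mixture on log segment length separates the
classes; FROH — the fraction of the autosomal genome covered by the
longest class (class 5), after excluding hemizygous (CNV-deleted) regions —
is the consanguinity proxy, with individuals labelled consanguineous above
a configurable threshold (default FROH > 0.03, roughly second-cousin
offspring).

The mixture fit is a plain 1-D EM with k-means++-style initialization and
restarts; it tracks the log-likelihood per iteration so monotone
convergence is assertable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .synthetic_data import AUTOSOME_LENGTH_BP

_MIN_SD = 1e-6


class DegenerateComponentError(RuntimeError):
    """A mixture component collapsed onto a point (sd -> 0)."""


@dataclasses.dataclass
class MixtureFit:
    """Fitted 1-D Gaussian mixture on log segment length.

    Components are sorted by mean, so index k-1 ('class 5' for k=5) is the
    longest-length class. ``loglik_trace`` holds the (non-decreasing)
    per-iteration log-likelihoods of the selected restart.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    loglik_trace: np.ndarray
    posteriors: np.ndarray  # n_obs x k responsibilities
    labels: np.ndarray  # hard assignment, 1-based class index

    @property
    def k(self) -> int:
        return len(self.means)

    def classify(self, lengths: np.ndarray) -> np.ndarray:
        """Hard class labels (1-based, sorted by mean) for new lengths."""
        x = np.log(np.asarray(lengths, dtype=float))
        log_r = self._log_resp(x)
        return np.argmax(log_r, axis=1) + 1

    def _log_resp(self, x: np.ndarray) -> np.ndarray:
        lp = (
            np.log(self.weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(self.sds)[None, :]
            - 0.5 * ((x[:, None] - self.means[None, :]) / self.sds[None, :]) ** 2
        )
        return lp


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        if d2.sum() == 0:
            raise DegenerateComponentError("all observations identical")
        centers.append(x[rng.choice(len(x), p=d2 / d2.sum())])
    return np.sort(np.array(centers))


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    means = _kmeanspp_init(x, k, rng)
    sds = np.full(k, max(x.std() / k, _MIN_SD))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    for _ in range(max_iter):
        lp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        norm = logsumexp(lp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(lp - norm[:, None])
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise DegenerateComponentError("empty component")
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if (sds < _MIN_SD).any():
            raise DegenerateComponentError("component sd collapsed")
        weights = nk / len(x)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return means, sds, weights, trace


def fit_length_mixture(
    lengths: np.ndarray | pd.Series,
    k: int = 5,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a k-component Gaussian mixture to log segment lengths.

    Best of ``n_restarts`` EM runs by log-likelihood; degenerate runs
    (collapsed components) are retried with fresh initializations up to a
    2x budget before failing. Components are returned sorted by mean and
    segments hard-assigned by maximum posterior.
    """
    x = np.log(np.asarray(lengths, dtype=float))
    if (~np.isfinite(x)).any():
        raise ValueError("lengths must be positive and finite")
    if len(x) < 5 * k:
        raise ValueError(f"need at least 5k = {5 * k} observations, got {len(x)}")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    successes, attempts = 0, 0
    budget = 2 * n_restarts
    while successes < n_restarts and attempts < budget:
        attempts += 1
        try:
            means, sds, weights, trace = _em_once(x, k, rng, max_iter, tol)
        except DegenerateComponentError:
            continue
        successes += 1
        if best is None or trace[-1] > best[3][-1]:
            best = (means, sds, weights, trace)
    if best is None:
        raise DegenerateComponentError(
            f"all {attempts} EM runs degenerate (are the lengths all equal?)"
        )
    means, sds, weights, trace = best
    order = np.argsort(means)
    fit = MixtureFit(
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        log_likelihood=trace[-1],
        loglik_trace=np.array(trace),
        posteriors=np.empty((0, k)),
        labels=np.empty(0, dtype=int),
    )
    log_r = fit._log_resp(x)
    norm = logsumexp(log_r, axis=1)
    fit.posteriors = np.exp(log_r - norm[:, None])
    fit.labels = np.argmax(fit.posteriors, axis=1) + 1
    return fit


@dataclasses.dataclass
class FrohResult:
    """Class-5 autosomal homozygosity fraction for one sample."""

    sample_id: str
    class5_total_bp: int
    autosome_length_bp: int
    froh: float
    excluded_bp: int


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 0-based half-open intervals (n x 2)."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def _overlap_bp(start: int, end: int, regions: np.ndarray) -> int:
    """Total overlap of [start, end) with merged regions."""
    if len(regions) == 0:
        return 0
    lo = np.maximum(regions[:, 0], start)
    hi = np.minimum(regions[:, 1], end)
    return int(np.clip(hi - lo, 0, None).sum())


def froh(
    sample_segments: pd.DataFrame,
    mixture: MixtureFit,
    autosome_length_bp: int = AUTOSOME_LENGTH_BP,
    hemizygous_regions: pd.DataFrame | None = None,
    sample_id: str | None = None,
) -> FrohResult:
    """FROH from the longest ROH class for one sample.

    ``sample_segments`` needs columns chromosome/start/end (0-based
    half-open). Segments are assigned to mixture classes by posterior; only
    the longest class (class k) contributes. Any overlap with hemizygous
    regions (CNV deletions, same coordinate convention, columns
    chromosome/start/end) is subtracted before dividing by the autosome
    length.
    """
    if autosome_length_bp <= 0:
        raise ValueError("autosome_length_bp must be positive")
    seg = sample_segments
    if (seg["end"] <= seg["start"]).any():
        raise ValueError("segments must satisfy end > start")
    sid = sample_id or (
        str(seg["sample_id"].iloc[0]) if "sample_id" in seg and len(seg) else ""
    )
    if len(seg) == 0:
        return FrohResult(sid, 0, autosome_length_bp, 0.0, 0)
    lengths = (seg["end"] - seg["start"]).to_numpy()
    labels = mixture.classify(lengths)
    class5 = seg[labels == mixture.k]

    regions_by_chrom: dict[str, np.ndarray] = {}
    if hemizygous_regions is not None and len(hemizygous_regions):
        if (hemizygous_regions["end"] <= hemizygous_regions["start"]).any():
            raise ValueError("hemizygous regions must satisfy end > start")
        for chrom, grp in hemizygous_regions.groupby("chromosome"):
            regions_by_chrom[str(chrom)] = _merge_intervals(
                grp[["start", "end"]].to_numpy()
            )

    total = 0
    excluded = 0
    for _, row in class5.iterrows():
        length = int(row["end"] - row["start"])
        cut = _overlap_bp(
            int(row["start"]),
            int(row["end"]),
            regions_by_chrom.get(str(row["chromosome"]), np.empty((0, 2))),
        )
        total += length - cut
        excluded += cut
    return FrohResult(
        sample_id=sid,
        class5_total_bp=total,
        autosome_length_bp=autosome_length_bp,
        froh=total / autosome_length_bp,
        excluded_bp=excluded,
    )


def froh_all(
    segments: pd.DataFrame,
    mixture: MixtureFit,
    autosome_length_bp: int = AUTOSOME_LENGTH_BP,
    hemizygous_regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample FROH table for a multi-sample segment table."""
    rows = []
    for sid, grp in segments.groupby("sample_id"):
        res = froh(grp, mixture, autosome_length_bp, hemizygous_regions, str(sid))
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def label_consanguineous(
    froh_results: pd.DataFrame | list[FrohResult], threshold: float = 0.03
) -> pd.Series:
    """Boolean consanguinity label per sample: FROH strictly above threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    if isinstance(froh_results, list):
        froh_results = pd.DataFrame([dataclasses.asdict(r) for r in froh_results])
    return pd.Series(
        (froh_results["froh"] > threshold).to_numpy(),
        index=froh_results["sample_id"],
        name="consanguineous",
    )
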