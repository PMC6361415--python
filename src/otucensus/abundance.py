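"""Good-Turing relative abundances, census coverage, and MRA histograms.

Within one sample with N reads total, the relative abundance of an OTU seen
r times is estimated by the Good-Turing frequency estimator

    alpha = ((r + 1) / N) * (N_{r+1} / N_r),

where N_r is the number of OTUs with exactly r reads in that sample.  The
estimator discounts observed frequencies to leave probability mass for unseen
OTUs and is more robust than the naive r/N.  When the next count class is
empty (N_{r+1} = 0, always the case for the most abundant class), we fall
back to the maximum-likelihood frequency r/N rather than impose a smoothing
scheme.

An OTU's mean relative abundance (MRA) is its per-sample alpha averaged over
ALL samples, counting zero where the OTU was not detected.  Averaging
per-sample estimates (rather than pooling reads) avoids biasing the MRA
toward OTUs that happen to occur in deeply sequenced samples.

Census-wide coverage uses Good's formula on the rarest retained class:
doubletons (OTUs with exactly two reads, since singletons are filtered out).
P_1 = 2 N_2 / N estimates the probability that a fresh read hits a
one-read-class OTU, and P >= 1 - 2 P_1 bounds the probability that a fresh
read hits an OTU already in the census.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleCountTable

logger = logging.getLogger("otucensus")

__all__ = [
    "AbundanceEstimate",
    "CoverageReport",
    "MRAHistogram",
    "good_turing_abundance",
    "mean_relative_abundance",
    "goods_coverage",
    "census_coverage",
    "bin_mra_histogram",
]


@dataclass
class AbundanceEstimate:
    """Per-OTU mean relative abundance (zeros included in the average)."""

    mra: pd.Series  # index = OTU ids
    n_samples: int


@dataclass
class CoverageReport:
    n_reads: int
    n_doubletons: int

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("total read count must be positive")
        if 2 * self.n_doubletons > self.n_reads:
            raise ValueError(
                "inconsistent inputs: doubletons account for more reads than the total"
            )

    @property
    def p1(self) -> float:
        """Estimated probability that a fresh read hits a one-read-class OTU."""
        return 2.0 * self.n_doubletons / self.n_reads

    @property
    def coverage_bound(self) -> float:
        """Lower bound on the probability that a fresh read hits a census OTU."""
        return 1.0 - 2.0 * self.p1


@dataclass
class MRAHistogram:
    """Log10-binned OTU counts of mean relative abundance, full and rarefied."""

    edges_log10: np.ndarray  # strictly increasing, equal width
    f: np.ndarray            # OTUs per bin, full census
    f_r: np.ndarray          # OTUs per bin, rarefied census
    n_zero_full: int = 0
    n_zero_rarefied: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.edges_log10) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def centers_log10(self) -> np.ndarray:
        return 0.5 * (self.edges_log10[:-1] + self.edges_log10[1:])

    @property
    def centers(self) -> np.ndarray:
        return 10.0 ** self.centers_log10

    @property
    def bin_width_log10(self) -> float:
        return float(self.edges_log10[1] - self.edges_log10[0])


def good_turing_abundance(sample_counts) -> tuple[np.ndarray, np.ndarray]:
    """Good-Turing relative abundances for one sample.

    Parameters
    ----------
    sample_counts : array-like of int
        Per-OTU read counts in a single sample (zeros allowed).

    Returns
    -------
    alpha : ndarray
        Estimated relative abundance per OTU (0 where the count is 0).
    fallback : ndarray of bool
        True where the r/N fallback was used (empty next count class).
    """
    r = np.asarray(sample_counts, dtype=np.int64)
    if (r < 0).any():
        raise ValueError("negative read count")
    N = int(r.sum())
    if N == 0:
        raise ValueError("empty sample: no reads")
    nr = np.bincount(r)  # nr[k] = number of OTUs with exactly k reads
    nr_next = np.zeros_like(nr)
    nr_next[:-1] = nr[1:]
    alpha = np.zeros(len(r), dtype=float)
    fallback = np.zeros(len(r), dtype=bool)
    pos = r > 0
    rp = r[pos]
    has_next = nr_next[rp] > 0
    a = np.where(
        has_next,
        (rp + 1) / N * nr_next[rp] / nr[rp],
        rp / N,
    )
    alpha[pos] = a
    fb = np.zeros(len(rp), dtype=bool)
    fb[~has_next] = True
    fallback[pos] = fb
    return alpha, fallback


def mean_relative_abundance(table: SampleCountTable) -> AbundanceEstimate:
    """MRA per OTU: per-sample Good-Turing abundances averaged over all
    samples, with zeros for samples where the OTU is absent."""
    if table.n_samples == 0 or table.n_otus == 0:
        raise ValueError("empty count table")
    counts = table.counts.to_numpy()
    total = np.zeros(table.n_otus, dtype=float)
    for j in range(table.n_samples):
        col = counts[:, j]
        if col.sum() == 0:
            logger.warning("sample %s has zero reads; contributes zero abundances",
                           table.sample_ids[j])
            continue
        alpha, _ = good_turing_abundance(col)
        total += alpha
    mra = pd.Series(total / table.n_samples, index=table.otu_ids)
    return AbundanceEstimate(mra=mra, n_samples=table.n_samples)


def goods_coverage(doubleton_count: int, total_reads: int) -> CoverageReport:
    """Good's coverage of the census from the doubleton count N_2 (OTUs with
    exactly two reads census-wide) and the total read count N."""
    return CoverageReport(n_reads=int(total_reads), n_doubletons=int(doubleton_count))


def census_coverage(table: SampleCountTable) -> CoverageReport:
    """Convenience wrapper: tally doubletons and total reads from a (filtered)
    census table and apply Good's formula."""
    per_otu = table.counts.to_numpy().sum(axis=1)
    return goods_coverage(int((per_otu == 2).sum()), int(per_otu.sum()))


def bin_mra_histogram(
    mras: AbundanceEstimate,
    mras_rarefied: AbundanceEstimate,
    bin_width_log10: float = 0.25,
) -> MRAHistogram:
    """Histogram both MRA sets on one shared equal-width log10 grid.

    Edges are aligned to integer multiples of the bin width so that the grid
    is independent of the data range.  OTUs with zero MRA are excluded (their
    count is reported, not imputed).
    """
    if bin_width_log10 <= 0:
        raise ValueError("bin width must be positive")
    full = mras.mra.to_numpy()
    rare = mras_rarefied.mra.to_numpy()
    n_zero_full = int((full <= 0).sum())
    n_zero_rare = int((rare <= 0).sum())
    logf = np.log10(full[full > 0])
    logr = np.log10(rare[rare > 0]) if (rare > 0).any() else np.array([])
    if logf.size == 0:
        raise ValueError("all full-census MRAs are zero")
    lo = min(logf.min(), logr.min() if logr.size else np.inf)
    hi = max(logf.max(), logr.max() if logr.size else -np.inf)
    first = np.floor(lo / bin_width_log10)
    last = np.ceil(hi / bin_width_log10)
    if last == hi / bin_width_log10:  # right-open bins: make room for the max
        last += 1
    edges = np.arange(first, last + 1) * bin_width_log10
    f, _ = np.histogram(logf, bins=edges)
    f_r, _ = np.histogram(logr, bins=edges) if logr.size else (np.zeros(len(edges) - 1, dtype=int), None)
    return MRAHistogram(
        edges_log10=edges, f=f.astype(np.int64), f_r=np.asarray(f_r, dtype=np.int64),
        n_zero_full=n_zero_full, n_zero_rarefied=n_zero_rare,
    )
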