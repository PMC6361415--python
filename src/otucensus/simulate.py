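"""Synthetic global-census generator.

Emulates the count-level statistical structure the downstream analysis
assumes: a fixed pool of S_true extant OTUs whose global relative abundances
are drawn from a log-normal distribution (natural-log scale) and renormalized
to sum to one; a hierarchy of studies each containing several samples;
per-sample abundances obtained by perturbing the global abundances with an
independent multiplicative log-normal factor (and renormalizing); and read
counts drawn as independent Poisson variables with rate depth x per-sample
relative abundance.  A binomial-thinning rarefier produces the half-depth
twin census used to calibrate the discovery model.

One seed drives a hierarchical RNG stream (census -> study -> sample), so
study- or sample-level subsets are reproducible on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleCountTable

__all__ = ["CensusConfig", "CensusTruth", "generate_census", "rarefy_census"]

# refuse to allocate count matrices beyond this many cells
MEMORY_GUARD_CELLS = 200_000_000


@dataclass
class CensusConfig:
    """Parameters of a synthetic census.

    mu and sigma are the natural-log mean and SD of the (unnormalized) global
    relative-abundance distribution; only sigma matters after renormalization,
    while mu shifts uniformly.  sample_noise_sigma is the SD of the per-sample
    multiplicative log-normal perturbation (0 = identical composition in every
    sample).
    """

    s_true: int = 5000
    mu: float = -14.0
    sigma: float = 1.5
    n_studies: int = 40
    samples_per_study: int | list[int] = 10
    depth_per_sample: int = 50_000
    sample_noise_sigma: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.s_true < 1:
            raise ValueError("s_true must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.depth_per_sample < 1:
            raise ValueError("depth must be >= 1")
        if self.sample_noise_sigma < 0:
            raise ValueError("sample_noise_sigma must be >= 0")

    @property
    def samples_by_study(self) -> list[int]:
        if isinstance(self.samples_per_study, int):
            return [self.samples_per_study] * self.n_studies
        if len(self.samples_per_study) != self.n_studies:
            raise ValueError("samples_per_study list must have one entry per study")
        return list(self.samples_per_study)


@dataclass
class CensusTruth:
    """Ground truth of a generated census: per-OTU global relative abundance
    and (once the detection filter has been applied) the retained flag."""

    abundance: pd.Series  # index = OTU ids, sums to 1
    retained: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        total = float(self.abundance.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"true abundances must sum to 1 (got {total})")


def generate_census(config: CensusConfig) -> tuple[SampleCountTable, CensusTruth]:
    """Draw a full synthetic census; deterministic given ``config.seed``."""
    n_samples = sum(config.samples_by_study)
    if config.s_true * n_samples > MEMORY_GUARD_CELLS:
        raise MemoryError(
            f"census of {config.s_true} OTUs x {n_samples} samples exceeds the "
            f"memory guard of {MEMORY_GUARD_CELLS} cells"
        )
    root = np.random.SeedSequence(config.seed)
    census_ss, *study_ss = root.spawn(1 + config.n_studies)
    rng = np.random.default_rng(census_ss)

    raw = np.exp(rng.normal(config.mu, config.sigma, size=config.s_true))
    truth = raw / raw.sum()
    otu_ids = [f"otu{j:06d}" for j in range(config.s_true)]

    counts = np.empty((config.s_true, n_samples), dtype=np.int64)
    sample_ids: list[str] = []
    study_of_sample: dict[str, str] = {}
    col = 0
    for si, (n_s, ss) in enumerate(zip(config.samples_by_study, study_ss)):
        study_id = f"study{si:03d}"
        sample_streams = ss.spawn(n_s)
        for k, sss in enumerate(sample_streams):
            srng = np.random.default_rng(sss)
            if config.sample_noise_sigma > 0:
                pert = truth * np.exp(
                    srng.normal(0.0, config.sample_noise_sigma, size=config.s_true)
                )
                pert /= pert.sum()
            else:
                pert = truth
            counts[:, col] = srng.poisson(config.depth_per_sample * pert)
            sid = f"{study_id}_s{k:03d}"
            sample_ids.append(sid)
            study_of_sample[sid] = study_id
            col += 1

    table = SampleCountTable(
        pd.DataFrame(counts, index=otu_ids, columns=sample_ids), study_of_sample
    )
    return table, CensusTruth(abundance=pd.Series(truth, index=otu_ids))


def rarefy_census(
    table: SampleCountTable, keep_fraction: float, seed: int | None = None
) -> SampleCountTable:
    """Binomial thinning: keep each read independently with probability
    ``keep_fraction``.  With keep_fraction = 0.5 this emulates randomly
    discarding half of all quality-filtered reads."""
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must lie in (0, 1]")
    if keep_fraction == 1.0:
        return SampleCountTable(table.counts.copy(), dict(table.study_of_sample))
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(table.counts.to_numpy(), keep_fraction)
    return SampleCountTable(
        pd.DataFrame(thinned.astype(np.int64), index=table.otu_ids, columns=table.sample_ids),
        dict(table.study_of_sample),
    )
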