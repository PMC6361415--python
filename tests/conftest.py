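import numpy as np
import pandas as pd
import pytest

from otucensus import CensusConfig, SampleCountTable, generate_census


@pytest.fixture
def tiny_table() -> SampleCountTable:
    """Two OTUs, two samples, one study."""
    counts = pd.DataFrame(
        {"s1": [3, 1], "s2": [0, 2]}, index=["A", "B"], dtype=np.int64
    )
    return SampleCountTable(counts, {"s1": "study1", "s2": "study1"})


@pytest.fixture
def census_factory():
    """Factory for small synthetic censuses with sensible defaults."""

    def make(**kwargs):
        defaults = dict(
            s_true=800, sigma=1.5, n_studies=12, samples_per_study=5,
            depth_per_sample=5000, sample_noise_sigma=0.3, seed=0,
        )
        defaults.update(kwargs)
        return generate_census(CensusConfig(**defaults))

    return make


@pytest.fixture
def random_incidence():
    """Factory for random binary OTU-by-study matrices."""

    def make(n_otus: int, n_units: int, seed: int = 0, p: float = 0.3):
        rng = np.random.default_rng(seed)
        mat = (rng.random((n_otus, n_units)) < p).astype(np.int8)
        mat[mat.sum(axis=1) == 0, 0] = 1  # every OTU present somewhere
        from otucensus import IncidenceMatrix

        return IncidenceMatrix(
            pd.DataFrame(mat, index=[f"o{i}" for i in range(n_otus)],
                         columns=[f"u{j}" for j in range(n_units)])
        )

    return make
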