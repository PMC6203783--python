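"""Shared fixtures: small seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teflux.synthetic import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 genes, mild noise: the general-purpose end-to-end fixture."""
    spec = SyntheticSpec(n_genes=60, dispersion=0.05, depth=2e5, tss_noise_rate=0.002, seed=7)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Poisson counts at high depth, zero TSS noise: plant recovery."""
    spec = SyntheticSpec(
        n_genes=40, dispersion=0.0, depth=5e6, tss_noise_rate=0.0, seed=3
    )
    return make_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def split_counts(counts: pd.DataFrame):
    rna = counts[[c for c in counts.columns if c.startswith("rna_")]]
    ribo = counts[[c for c in counts.columns if c.startswith("ribo_")]]
    return rna, ribo
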