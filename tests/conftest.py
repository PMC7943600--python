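"""Shared fixtures: tiny matrix builders and the default synthetic dataset."""

import numpy as np
import pytest
import scipy.sparse as sp

from wgdhic import (ContactMatrix, SimulationConfig, bin_genome,
                    generate_dataset)
from wgdhic.pipeline import analyze_species


def make_matrix(dense, state="raw", resolution=10_000, chrom_sizes=None,
                mask=None):
    """ContactMatrix from a dense array on one or more chromosomes."""
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    if chrom_sizes is None:
        chrom_sizes = {"chr1": n * resolution}
    bins = bin_genome(chrom_sizes, resolution)
    return ContactMatrix(bins, sp.csr_matrix(dense), state=state, mask=mask)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down genome for fast generator round trips."""
    return SimulationConfig(
        seed=5, n_chroms=2, chrom_length=2_500_000,
        n_paralog_pairs=30, sv_counts={"inversion": 4, "translocation": 3,
                                       "species_specific_A": 2,
                                       "species_specific_B": 2},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition dataset shared across read-only tests."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Full per-species pipeline results on the default dataset."""
    return {
        s: analyze_species(d.matrix_hi, d.matrix_lo, d.genes)
        for s, d in default_dataset.species.items()
    }
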