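"""Shared fixtures: one small simulated dataset reused across test modules."""
import numpy as np
import pandas as pd
import pytest

from oryzapop.simdata import SimConfig, simulate_history, make_outgroup_map
from oryzapop.variantio import GenotypeMatrix, MISSING


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-species simulation shared by read-only tests."""
    cfg = SimConfig(seed=2, genome_length=200_000)
    matrix, samples, truth = simulate_history(cfg)
    return cfg, matrix, samples, truth


@pytest.fixture(scope="session")
def small_outgroup_map(small_sim):
    _, matrix, _, truth = small_sim
    return make_outgroup_map(matrix, truth, seed=11)


def make_matrix(genotypes, pos=None, chrom=None, ref=None, alt=None,
                samples=None, functional_class=None, annotations=None):
    """Build a GenotypeMatrix from a (samples x variants) array of codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    ns, nv = g.shape
    return GenotypeMatrix(
        samples=list(samples) if samples is not None else [f"s{i}" for i in range(ns)],
        chrom=np.asarray(chrom if chrom is not None else ["chr1"] * nv, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, nv + 1) * 100,
                       dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * nv, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * nv, dtype=object),
        genotypes=g,
        annotations=annotations or {},
        functional_class=(np.asarray(functional_class, dtype=object)
                          if functional_class is not None else None),
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
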