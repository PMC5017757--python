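"""Shared fixtures: one mid-sized genome pair with both ssPAL loci, its
hybrid reference, and one full contamination sweep reused by several tests."""

import numpy as np
import pytest

import pdxpurity as px


@pytest.fixture(scope="session")
def genome_pair():
    """20 kb human/mouse pair at 10% divergence carrying both loci."""
    cfg = px.default_genome_config(length=20_000, divergence=0.10, seed=7)
    return px.make_genome_pair(cfg)


@pytest.fixture(scope="session")
def hybrid_ref(genome_pair):
    human, mouse = genome_pair
    return px.build_reference(human, mouse, k=15)


@pytest.fixture(scope="session")
def sweep_result():
    """One full contamination sweep (20 kb genome, lambda 0..0.9)."""
    return px.contamination_sweep(
        px.ContaminationConfig(lambdas=(0.0, 0.3, 0.6, 0.9), seed=11),
        px.GenomePairConfig(length=20_000, divergence=0.10, seed=11),
        n_mutations=80, vafs=(0.05, 0.1, 0.2, 0.5))


def close_binomial(count, n, p, z=4.0):
    """|count - n*p| within z binomial standard deviations."""
    sd = np.sqrt(n * p * (1 - p))
    return abs(count - n * p) <= z * max(sd, 1e-12)
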