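"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings

import fdrscope as f

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def exact_hypergeom_tail(x: int, K: int, n: int, N: int) -> Fraction:
    """Exhaustive-enumeration oracle: P(X >= x) as an exact rational.

    X ~ Hypergeometric(N population, K marked, n drawn); the tail is the
    exact sum of binomial products over all achievable draw counts.
    """
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(max(x, max(0, K + n - N)), min(K, n) + 1)
    )
    return Fraction(num, math.comb(N, n))


@pytest.fixture(scope="session")
def planted_msa_small():
    """Two leaves, strength 1.0, 50 sequences per leaf: a perfect-signal fixture."""
    spec = f.PlantedHierarchySpec(
        children={0: [1, 2]},
        n_sequences={1: 50, 2: 50},
        pattern_columns={1: [5, 15, 25, 35, 45], 2: [10, 20, 30, 40, 50]},
        pattern_residues={1: "WWWWW", 2: "CCCCC"},
        pattern_strength=1.0,
        sequence_length=60,
        seed=7,
    )
    return f.gen_hierarchical_msa(spec)


@pytest.fixture(scope="session")
def planted_complex():
    """Default toy complex with an 8-residue cluster planted at the interface."""
    return f.gen_complex_structure(f.PlantedComplexSpec(seed=1))


@pytest.fixture(scope="session")
def fitted_small(planted_msa_small):
    msa, truth = planted_msa_small
    est = f.PatternHierarchyClusterer(
        fixed_shape=((), ()), n_sweeps=8, n_restarts=2, random_state=3
    )
    return est.fit(msa), msa, truth
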