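"""Shared fixtures: tiny networks built in memory, no data files."""

from __future__ import annotations

import io

import numpy as np
import pytest

from complexsampler import (
    ScoreParams,
    WeightedNetwork,
    read_weighted_network,
)


@pytest.fixture
def triangle_net() -> WeightedNetwork:
    """a-b (1.0), b-c (1.0); a-c absent."""
    return WeightedNetwork({("a", "b"): 1.0, ("b", "c"): 1.0})


@pytest.fixture
def k5_net() -> WeightedNetwork:
    """Complete graph on 5 proteins, all weights 1 (no forbidden partitions)."""
    prots = [f"p{i}" for i in range(5)]
    edges = {
        (u, v): 1.0 for i, u in enumerate(prots) for v in prots[i + 1 :]
    }
    return WeightedNetwork(edges)


@pytest.fixture
def random_net():
    """Factory: a random weighted network on n proteins, reproducible."""

    def make(n: int = 50, p: float = 0.2, seed: int = 0) -> WeightedNetwork:
        rng = np.random.default_rng(seed)
        prots = [f"q{i:03d}" for i in range(n)]
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges[(prots[i], prots[j])] = float(rng.uniform(0.1, 5.0))
        return WeightedNetwork(edges, extra_proteins=prots)

    return make


@pytest.fixture
def toy_params() -> ScoreParams:
    """Small-N parameter set convenient for hand checks."""
    return ScoreParams(N=5, lam=4.0, sigma3_sq=10.0)
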