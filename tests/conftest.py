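"""Shared fixtures: tiny deterministic synthetic inputs and toy networks."""

from __future__ import annotations

import numpy as np
import pytest

from chromage.chromatin_network import ChromatinNetwork
from chromage.genome_features import GenomicInterval
from chromage.synthetic_data import SyntheticConfig, make_genome


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_genes=200, n_edges=500, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)


def toy_network(
    edges: list[tuple[int, int]],
    n_nodes: int | None = None,
    genes: list[tuple[str, ...]] | None = None,
    positions: list[int] | None = None,
    chroms: list[str] | None = None,
) -> ChromatinNetwork:
    """Hand-built network: node i is a 1 kb fragment at a given position."""
    if n_nodes is None:
        n_nodes = max(max(e) for e in edges) + 1 if edges else 0
    if positions is None:
        positions = [10_000 * (i + 1) for i in range(n_nodes)]
    if chroms is None:
        chroms = ["chr1"] * n_nodes
    fragments = [
        GenomicInterval(chroms[i], positions[i], positions[i] + 1000) for i in range(n_nodes)
    ]
    if genes is None:
        genes = [(f"g{i}",) for i in range(n_nodes)]
    e = np.array(edges, dtype=np.int64).reshape(-1, 2)
    dists = np.array(
        [
            abs(fragments[a].midpoint - fragments[b].midpoint)
            if fragments[a].chrom == fragments[b].chrom
            else np.nan
            for a, b in e
        ]
    )
    return ChromatinNetwork(fragments, genes, e, dists)


@pytest.fixture
def make_toy_network():
    return toy_network


def random_feature_network(seed: int, n_nodes: int = 40, n_edges: int = 120):
    """Random graph + random binary feature for oracle checks."""
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for a in range(n_nodes) for b in range(a + 1, n_nodes)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = [pairs[i] for i in idx]
    net = toy_network(edges, n_nodes=n_nodes)
    values = {f"chr1:{10_000 * (i + 1)}-{10_000 * (i + 1) + 1000}": float(v)
              for i, v in enumerate(rng.random(n_nodes))}
    return net, values
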