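"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own data structures and
algorithms: triangles come from a triple loop over all index triples,
adjacency from a quadratic pairwise shared-edge check, and so on, so that
agreement with the package is a real cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from grnbalance.interaction_inference import SignedNetwork


# ---------------------------------------------------------------------------
# network construction helpers


def net_from_edges(n: int, edges: dict[tuple[int, int], float]) -> SignedNetwork:
    J = np.zeros((n, n))
    for (i, j), w in edges.items():
        J[i, j] = J[j, i] = w
    return SignedNetwork([f"g{i:02d}" for i in range(n)], J)


def random_signed_network(
    n: int, p: float, rng: np.random.Generator, frac_negative: float = 0.4
) -> SignedNetwork:
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = rng.uniform(0.2, 2.0)
                if rng.random() < frac_negative:
                    w = -w
                edges[(i, j)] = w
    return net_from_edges(n, edges)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_triangles(net: SignedNetwork) -> list[tuple[int, int, int]]:
    """All index triples with all three edges present, by exhaustive triple loop."""
    n = net.n_genes
    out = []
    for i, j, k in itertools.combinations(range(n), 3):
        if net.J[i, j] != 0 and net.J[j, k] != 0 and net.J[i, k] != 0:
            out.append((i, j, k))
    return out


def brute_total_energy(net: SignedNetwork) -> float:
    return sum(
        -(net.J[i, j] * net.J[j, k] * net.J[k, i]) for i, j, k in brute_triangles(net)
    )


def brute_triangle_adjacency(
    triples: list[tuple[int, int, int]],
) -> set[tuple[int, int]]:
    """Pairs of triangles sharing exactly two vertices (hence one edge)."""
    adj = set()
    for a in range(len(triples)):
        for b in range(a + 1, len(triples)):
            if len(set(triples[a]) & set(triples[b])) == 2:
                adj.add((a, b))
    return adj


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
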