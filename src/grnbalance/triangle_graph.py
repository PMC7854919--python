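"""Coarse-grained triangle graph: mixing, localisation and assortativity.

Each triangle of the underlying signed network becomes a node; two triangle
nodes are connected when their triangles share an edge (two genes and the
link between them).  On this graph we ask where the frustrated triangles
live: whether they sit inside the giant connected component or are isolated
from it, how triangle energies co-occur across adjacencies (the energy-energy
mixing matrix) and whether adjacent triangles have correlated energies
(assortativity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from .balance_analysis import TriangleRecord

__all__ = [
    "TriangleGraph",
    "MixingMatrix",
    "ComponentStats",
    "build_triangle_graph",
    "mixing_matrix",
    "giant_component_stats",
    "energy_assortativity",
    "write_triangle_graphml",
    "write_mixing_matrix",
]


@dataclass
class TriangleGraph:
    """Graph whose nodes are triangles, adjacent when they share a network edge."""

    triangles: list[TriangleRecord]
    adjacency: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return len(self.triangles)

    @property
    def n_adjacencies(self) -> int:
        return len(self.adjacency)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, t in enumerate(self.triangles):
            g.add_node(
                idx,
                genes=",".join(t.genes),
                energy=float(t.energy),
                balance_class=t.balance_class,
                color="green" if t.balance_class == "balanced" else "red",
            )
        g.add_edges_from(self.adjacency)
        return g


@dataclass
class MixingMatrix:
    """Binned energy-energy co-occurrence counts over adjacent triangle pairs.

    ``counts[k, l]`` is incremented for both orientations of every adjacent
    pair, so the matrix is symmetric and sums to twice the number of
    adjacencies when unnormalised.
    """

    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class ComponentStats:
    """Connected-component census of a triangle graph.

    Fractions are of the *imbalanced* triangles: the share of them inside
    the largest component vs outside.  With no triangles (or no imbalanced
    triangles) the fractions are NaN and the counts are zero.
    """

    labels: list[int]
    giant_size: int
    n_imbalanced: int
    n_imbalanced_in_giant: int

    @property
    def frac_imbalanced_in_giant(self) -> float:
        if self.n_imbalanced == 0:
            return float("nan")
        return self.n_imbalanced_in_giant / self.n_imbalanced

    @property
    def frac_imbalanced_outside(self) -> float:
        if self.n_imbalanced == 0:
            return float("nan")
        return 1.0 - self.frac_imbalanced_in_giant


def build_triangle_graph(triangles: list[TriangleRecord]) -> TriangleGraph:
    """Connect triangles that share an underlying network edge.

    Uses a shared-edge index (network edge -> triangles containing it); two
    distinct triangles can share at most one edge, so each bucket contributes
    each pair once.
    """
    edge_index: dict[tuple[str, str], list[int]] = {}
    for idx, t in enumerate(triangles):
        a, b, c = t.genes
        for pair in ((a, b), (b, c), (a, c)):
            edge_index.setdefault(tuple(sorted(pair)), []).append(idx)
    adjacency: set[tuple[int, int]] = set()
    for bucket in edge_index.values():
        for x in range(len(bucket)):
            for y in range(x + 1, len(bucket)):
                i, j = bucket[x], bucket[y]
                adjacency.add((min(i, j), max(i, j)))
    return TriangleGraph(list(triangles), adjacency)


def mixing_matrix(
    tg: TriangleGraph,
    n_bins: int = 20,
    bin_edges: np.ndarray | None = None,
    signed: bool = True,
    normalize_by: int | None = None,
) -> MixingMatrix:
    """Energy-energy mixing matrix C_kl over adjacent triangle pairs.

    Default binning: ``n_bins`` equal-width bins on signed energies, spanning
    the observed range symmetrically about zero (``signed=False`` bins
    |energy| instead).  Every adjacent pair (E1, E2) increments both
    ``counts[bin(E1), bin(E2)]`` and ``counts[bin(E2), bin(E1)]``.
    ``normalize_by`` divides the counts by the given node count.
    """
    energies = np.array(
        [t.energy if signed else abs(t.energy) for t in tg.triangles], dtype=float
    )
    if bin_edges is None:
        if energies.size == 0:
            bin_edges = np.linspace(-1, 1, n_bins + 1)
        elif signed:
            m = max(np.max(np.abs(energies)), np.finfo(float).tiny)
            bin_edges = np.linspace(-m, m, n_bins + 1)
        else:
            hi = max(np.max(energies), np.finfo(float).tiny)
            bin_edges = np.linspace(0, hi, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if energies.size and (
        energies.min() < bin_edges[0] or energies.max() > bin_edges[-1]
    ):
        raise ValueError("bins do not cover the observed energy range")
    nb = len(bin_edges) - 1
    # np.digitize with right-closed last bin
    bins = np.clip(np.digitize(energies, bin_edges) - 1, 0, nb - 1)
    counts = np.zeros((nb, nb), dtype=float)
    for i, j in tg.adjacency:
        counts[bins[i], bins[j]] += 1.0
        counts[bins[j], bins[i]] += 1.0
    if normalize_by:
        counts /= normalize_by
    return MixingMatrix(bin_edges, counts)


def giant_component_stats(tg: TriangleGraph) -> ComponentStats:
    """Component labels and giant-component membership of imbalanced triangles.

    Components come from breadth-first traversal over the triangle graph
    (isolated triangles are their own components).  The giant component is
    the largest by node count; ties go to the component containing the
    lexicographically smallest triangle.
    """
    if tg.n_nodes == 0:
        return ComponentStats([], 0, 0, 0)
    g = tg.to_networkx()
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), tg.triangles[c[0]].genes))
    labels = [0] * tg.n_nodes
    for label, comp in enumerate(components):
        for idx in comp:
            labels[idx] = label
    giant = set(components[0])
    imbalanced = [
        i for i, t in enumerate(tg.triangles) if t.balance_class == "imbalanced"
    ]
    in_giant = sum(1 for i in imbalanced if i in giant)
    return ComponentStats(labels, len(giant), len(imbalanced), in_giant)


def energy_assortativity(tg: TriangleGraph) -> float:
    """Pearson correlation of endpoint energies over adjacent triangle pairs.

    Each unordered adjacency contributes both orientations.  Returns NaN
    when there are no adjacencies or the endpoint energies have zero
    variance (the correlation is then undefined).
    """
    if tg.n_adjacencies == 0:
        return float("nan")
    e = [t.energy for t in tg.triangles]
    x = np.array([e[i] for i, j in tg.adjacency] + [e[j] for i, j in tg.adjacency])
    y = np.array([e[j] for i, j in tg.adjacency] + [e[i] for i, j in tg.adjacency])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def write_triangle_graphml(tg: TriangleGraph, path: str | Path) -> None:
    nx.write_graphml(tg.to_networkx(), str(path))


def write_mixing_matrix(mm: MixingMatrix, path: str | Path) -> None:
    """TSV matrix; header row carries the bin edges."""
    with open(path, "w") as fh:
        fh.write("# bin_edges\t" + "\t".join(f"{e:.17g}" for e in mm.bin_edges) + "\n")
        for row in mm.counts:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
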