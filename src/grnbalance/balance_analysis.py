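"""Triangle enumeration, balance classification and frustration energies.

In a signed network a triangle is *balanced* when the product of its three
edge signs is positive, and *imbalanced* (frustrated) otherwise.  A triangle
of type Delta_k carries exactly k negative links: Delta_0 and Delta_2 are
balanced, Delta_1 and Delta_3 are imbalanced.  The energy of a triangle is
``E_ijk = -J_ij * J_jk * J_ki``, so balanced triangles sit at negative energy
and frustrated ones at positive energy; the total network energy is the sum
over all (unordered) triangles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .interaction_inference import SignedNetwork

__all__ = [
    "TriangleRecord",
    "enumerate_triangles",
    "classify_triangle",
    "triangle_energy",
    "total_energy",
    "energy_distribution",
    "type_counts",
    "write_triangle_table",
    "write_histogram",
]

TYPE_LABELS = {0: "D0", 1: "D1", 2: "D2", 3: "D3"}


@dataclass(frozen=True)
class TriangleRecord:
    """One triangle (i, j, k) in canonical sorted gene order.

    ``weights`` holds (J_ij, J_jk, J_ki); ``energy = -J_ij J_jk J_ki``;
    ``balance_class`` is "balanced" iff the number of negative links is even,
    equivalently iff the energy is negative.
    """

    genes: tuple[str, str, str]
    weights: tuple[float, float, float]

    @property
    def energy(self) -> float:
        return triangle_energy(self.weights)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.weights if w < 0)

    @property
    def balance_class(self) -> str:
        return "balanced" if self.n_negative % 2 == 0 else "imbalanced"

    @property
    def type_label(self) -> str:
        return TYPE_LABELS[self.n_negative]


def triangle_energy(weights: Sequence[float]) -> float:
    """E = -(J_ij * J_jk * J_ki)."""
    w1, w2, w3 = weights
    return -(w1 * w2 * w3)


def classify_triangle(weights: Sequence[float]) -> tuple[int, str, str]:
    """(number of negative links, balance class, type label Delta_k).

    Balanced iff the product of the three (nonzero) weights is positive.
    """
    if any(w == 0 for w in weights):
        raise ValueError("zero weight is not a triangle edge")
    n_negative = sum(1 for w in weights if w < 0)
    balance = "balanced" if n_negative % 2 == 0 else "imbalanced"
    return n_negative, balance, TYPE_LABELS[n_negative]


def enumerate_triangles(net: SignedNetwork) -> list[TriangleRecord]:
    """All unordered gene triples whose three edges are present.

    Output is deterministic: canonical sorted gene order within a triangle,
    triangles sorted lexicographically by gene ids.
    """
    order = sorted(range(net.n_genes), key=lambda i: net.gene_ids[i])
    rank = {idx: r for r, idx in enumerate(order)}
    adj: list[set[int]] = [set() for _ in range(net.n_genes)]
    for i, j in net.edges:
        adj[i].add(j)
        adj[j].add(i)
    records: list[TriangleRecord] = []
    for a in order:
        higher_a = {x for x in adj[a] if rank[x] > rank[a]}
        for b in sorted(higher_a, key=lambda i: net.gene_ids[i]):
            common = higher_a & adj[b]
            for c in sorted((x for x in common if rank[x] > rank[b]),
                            key=lambda i: net.gene_ids[i]):
                records.append(
                    TriangleRecord(
                        genes=(net.gene_ids[a], net.gene_ids[b], net.gene_ids[c]),
                        weights=(
                            float(net.J[a, b]),
                            float(net.J[b, c]),
                            float(net.J[c, a]),
                        ),
                    )
                )
    return records


def total_energy(
    triangles: Iterable[TriangleRecord],
    normalization: str = "none",
    n_genes: int | None = None,
) -> float:
    """Sum of triangle energies over unordered triangles.

    ``normalization="per-node"`` divides the raw sum by the number of genes
    N (requires ``n_genes``); the raw sum is the primary convention.
    """
    e = float(sum(t.energy for t in triangles))
    if normalization == "none":
        return e
    if normalization == "per-node":
        if not n_genes:
            raise ValueError("per-node normalization requires n_genes")
        return e / n_genes
    raise ValueError(f"unknown normalization {normalization!r}")


def _select(triangles: Iterable[TriangleRecord], type_filter: str):
    if type_filter == "all":
        return list(triangles)
    if type_filter in ("balanced", "imbalanced"):
        return [t for t in triangles if t.balance_class == type_filter]
    by_label = {v: k for k, v in TYPE_LABELS.items()}
    if type_filter in by_label:
        return [t for t in triangles if t.n_negative == by_label[type_filter]]
    raise ValueError(f"unknown type filter {type_filter!r}")


def type_counts(triangles: Iterable[TriangleRecord]) -> dict[int, int]:
    """Triangle census: number of triangles per type Delta_0..Delta_3."""
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for t in triangles:
        counts[t.n_negative] += 1
    return counts


def energy_distribution(
    triangles: Sequence[TriangleRecord],
    type_filter: str = "all",
    n_bins: int = 30,
    bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of |energy| on logarithmic bins for one triangle type.

    Returns ``(bin_edges, counts)``.  Default bins: ``n_bins`` logarithmic
    bins between the observed smallest and largest nonzero |energy|.  The
    total count over bins equals the number of selected triangles (zero
    energies, possible only with a zero weight, cannot occur for triangles).
    """
    selected = _select(triangles, type_filter)
    abs_e = np.array([abs(t.energy) for t in selected], dtype=float)
    if bin_edges is None:
        if abs_e.size == 0:
            bin_edges = np.logspace(0, 1, n_bins + 1)
        else:
            lo, hi = abs_e.min(), abs_e.max()
            if lo <= 0:
                raise ValueError("zero |energy| cannot be log-binned")
            if lo == hi:
                lo, hi = lo * 0.5, hi * 2.0
            bin_edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
            # guard against log/exp round-off at the endpoints
            bin_edges[0] = min(bin_edges[0], lo)
            bin_edges[-1] = max(bin_edges[-1], hi)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if abs_e.size and (abs_e.min() < bin_edges[0] or abs_e.max() > bin_edges[-1]):
        raise ValueError("bins do not cover the observed |energy| range")
    counts, _ = np.histogram(abs_e, bins=bin_edges)
    return bin_edges, counts


def write_triangle_table(
    triangles: Iterable[TriangleRecord], path: str | Path
) -> None:
    """TSV: gene_i, gene_j, gene_k, J_ij, J_jk, J_ki, energy, n_negative, class."""
    with open(path, "w") as fh:
        fh.write(
            "gene_i\tgene_j\tgene_k\tJ_ij\tJ_jk\tJ_ki\tenergy\tn_negative\tclass\n"
        )
        for t in triangles:
            w = "\t".join(f"{x:.17g}" for x in t.weights)
            fh.write(
                f"{t.genes[0]}\t{t.genes[1]}\t{t.genes[2]}\t{w}\t"
                f"{t.energy:.17g}\t{t.n_negative}\t{t.balance_class}\n"
            )


def write_histogram(
    bin_edges: np.ndarray, counts: np.ndarray, path: str | Path
) -> None:
    """TSV histogram: bin_low, bin_high, count."""
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tcount\n")
        for lo, hi, c in zip(bin_edges[:-1], bin_edges[1:], counts):
            fh.write(f"{lo:.17g}\t{hi:.17g}\t{int(c)}\n")
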