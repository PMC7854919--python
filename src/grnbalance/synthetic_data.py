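"""Synthetic expression data with a known signed interaction ground truth.

Expression vectors are drawn from a zero-mean multivariate Gaussian whose
precision matrix (inverse covariance) Theta is constructed explicitly, so the
ground-truth interaction network J = -Theta (off-diagonal) is known exactly.
This gives every downstream stage — covariance estimation, sparse precision
recovery, triangle enumeration, balance classification — a planted answer to
recover.

Sign convention: an interaction between genes i and j has sign
``sign(J_ij) = sign(-Theta_ij)``, so an *inductive* (positive) interaction is
planted as a negative off-diagonal precision entry.  Triangle motifs are
specified by their number of negative interactions k (type Delta_k): Delta_0
and Delta_2 are balanced, Delta_1 and Delta_3 are frustrated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix

__all__ = [
    "PrecisionSpec",
    "ToyStudy",
    "make_planted_precision",
    "plant_triangle_motifs",
    "sample_expression",
    "make_toy_study",
    "add_housekeeping_genes",
]

#: Relative diagonal-dominance margin used to force positive definiteness.
DOMINANCE_MARGIN = 0.1


@dataclass
class PrecisionSpec:
    """A symmetric positive-definite precision matrix with known support.

    ``edge_list`` holds the unordered index pairs carrying nonzero
    off-diagonal precision; ``planted_triangles`` records triples planted by
    :func:`plant_triangle_motifs` together with their intended interaction
    type (number of negative J signs).
    """

    gene_ids: list[str]
    theta: np.ndarray
    edge_list: set[tuple[int, int]]
    seed: int
    planted_triangles: list[tuple[tuple[int, int, int], int]] = field(
        default_factory=list
    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        t = self.theta
        if not np.allclose(t, t.T):
            raise ValueError("theta must be symmetric")
        support = {
            (i, j)
            for i in range(self.n_genes)
            for j in range(i + 1, self.n_genes)
            if t[i, j] != 0.0
        }
        if support != self.edge_list:
            raise ValueError("edge_list does not match off-diagonal support")
        if np.min(np.linalg.eigvalsh(t)) <= 0:
            raise ValueError("theta is not positive definite")

    def interaction_signs(self) -> dict[tuple[int, int], int]:
        """Ground-truth interaction sign per edge: sign(J_ij) = sign(-theta_ij)."""
        return {(i, j): int(np.sign(-self.theta[i, j])) for i, j in self.edge_list}


def _default_gene_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _set_dominant_diagonal(theta: np.ndarray) -> None:
    """Make theta strictly diagonally dominant (hence positive definite).

    theta_ii = max(1, (1 + margin) * sum_j |theta_ij|); the unit floor keeps
    isolated genes at unit precision (unit variance).
    """
    np.fill_diagonal(theta, 0.0)
    rowsum = np.abs(theta).sum(axis=1)
    np.fill_diagonal(theta, np.maximum(1.0, (1.0 + DOMINANCE_MARGIN) * rowsum))


def make_planted_precision(
    n_genes: int,
    edge_density: float,
    frac_negative: float,
    weight_scale: float,
    seed: int,
) -> PrecisionSpec:
    """Random sparse signed precision matrix.

    Each of the ``n_genes * (n_genes - 1) / 2`` pairs independently carries an
    edge with probability ``edge_density``.  Off-diagonal magnitudes are drawn
    uniformly in ``[0.5, 1.5] * weight_scale``; the entry is negative with
    probability ``frac_negative``.  The diagonal is then set by strict
    diagonal dominance, which guarantees positive definiteness without
    touching the planted off-diagonal signs.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must be in (0, 1]")
    if not 0.0 <= frac_negative <= 1.0:
        raise ValueError("frac_negative must be in [0, 1]")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    rng = np.random.default_rng(seed)
    theta = np.zeros((n_genes, n_genes))
    edges: set[tuple[int, int]] = set()
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_density:
                mag = weight_scale * rng.uniform(0.5, 1.5)
                sign = -1.0 if rng.random() < frac_negative else 1.0
                theta[i, j] = theta[j, i] = sign * mag
                edges.add((i, j))
    _set_dominant_diagonal(theta)
    return PrecisionSpec(_default_gene_ids(n_genes), theta, edges, seed)


# J-sign patterns by triangle type: Delta_k has k negative interactions.
_TYPE_SIGNS = {
    0: (+1, +1, +1),
    1: (-1, +1, +1),
    2: (-1, -1, +1),
    3: (-1, -1, -1),
}


def plant_triangle_motifs(
    spec: PrecisionSpec,
    counts: dict[int, int],
    weight_scale: float = 0.3,
) -> PrecisionSpec:
    """Plant triangles of requested types Delta_0..Delta_3 on free gene triples.

    Each planted triangle occupies three genes that carry no other edge, so
    the ground-truth triangle census of the resulting network is exactly the
    requested counts.  J signs follow the requested type; precision entries
    are the negated J values.  The diagonal is re-inflated afterwards to keep
    the matrix positive definite.
    """
    for k in counts:
        if k not in _TYPE_SIGNS:
            raise ValueError(f"unknown triangle type Delta_{k}")
    n_needed = 3 * sum(max(0, c) for c in counts.values())
    used = {i for e in spec.edge_list for i in e}
    free = [i for i in range(spec.n_genes) if i not in used]
    if len(free) < n_needed:
        raise ValueError(
            f"need {n_needed} free genes for planted triangles, have {len(free)}"
        )
    theta = spec.theta.copy()
    edges = set(spec.edge_list)
    planted = list(spec.planted_triangles)
    rng = np.random.default_rng(spec.seed + 1)
    cursor = 0
    for k in sorted(counts):
        for _ in range(counts[k]):
            triple = tuple(free[cursor : cursor + 3])
            cursor += 3
            pairs = list(itertools.combinations(triple, 2))
            for (i, j), j_sign in zip(pairs, _TYPE_SIGNS[k]):
                mag = weight_scale * rng.uniform(0.5, 1.5)
                theta[i, j] = theta[j, i] = -j_sign * mag
                edges.add((i, j))
            planted.append((triple, k))
    _set_dominant_diagonal(theta)
    return PrecisionSpec(list(spec.gene_ids), theta, edges, spec.seed, planted)


def sample_expression(
    spec: PrecisionSpec, n_samples: int, seed: int, condition: str | None = None
) -> ExpressionMatrix:
    """Draw i.i.d. expression profiles from N(0, theta^{-1}).

    Sampling goes through the Cholesky factor of theta itself
    (x = L^{-T} z with theta = L L^T), which both verifies positive
    definiteness and avoids forming the covariance explicitly.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    try:
        chol = np.linalg.cholesky(spec.theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("theta is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((spec.n_genes, n_samples))
    values = np.linalg.solve(chol.T, z)
    labels = [condition] * n_samples if condition is not None else None
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    return ExpressionMatrix(list(spec.gene_ids), sample_ids, values, labels)


def add_housekeeping_genes(
    em: ExpressionMatrix, n: int, level: float = 10.0, noise_sd: float = 1e-3,
    seed: int = 0,
) -> ExpressionMatrix:
    """Append near-constant "housekeeping-like" genes.

    Such genes are transcribed at an almost constant rate across samples;
    their tiny variance should make the variance filter drop them.
    """
    rng = np.random.default_rng(seed)
    rows = level + noise_sd * rng.standard_normal((n, em.n_samples))
    ids = [f"HK{i:03d}" for i in range(n)]
    return ExpressionMatrix(
        em.gene_ids + ids,
        list(em.sample_ids),
        np.vstack([em.values, rows]),
        em.condition,
    )


@dataclass
class ToyStudy:
    """Two synthetic conditions with known, contrasting triangle structure.

    ``normal`` has its frustrated triangles on gene triples disjoint from the
    balanced core (isolated in the coarse-grained triangle graph); ``cancer``
    has its frustrated triangles sharing an edge with the core (embedded in
    the giant component).  ``*_spec`` carry the ground-truth precision
    matrices; ``*_truth`` the expected per-type triangle counts.
    """

    normal: ExpressionMatrix
    cancer: ExpressionMatrix
    normal_spec: PrecisionSpec
    cancer_spec: PrecisionSpec
    normal_truth: dict[int, int]
    cancer_truth: dict[int, int]
    normal_frustrated_in_giant: int
    cancer_frustrated_in_giant: int


def _build_condition_spec(
    n_genes: int,
    n_core_triangles: int,
    n_frustrated: int,
    embedded: bool,
    weight_scale: float,
    seed: int,
) -> PrecisionSpec:
    """A balanced triangle-strip core plus frustrated Delta_1 triangles.

    The core is a strip of all-positive triangles (t, t+1, t+2) whose
    coarse-grained triangle graph is a connected path — the giant component.
    Frustrated triangles are either placed on fresh disjoint triples
    (``embedded=False``) or attached to distinct core edges by one new gene
    with one negative link (``embedded=True``), which creates exactly one new
    Delta_1 triangle per attachment and leaves the core balanced.
    """
    rng = np.random.default_rng(seed)
    theta = np.zeros((n_genes, n_genes))
    edges: set[tuple[int, int]] = set()
    planted: list[tuple[tuple[int, int, int], int]] = []

    def put(i: int, j: int, j_sign: float) -> None:
        i, j = min(i, j), max(i, j)
        mag = weight_scale * rng.uniform(0.8, 1.2)
        theta[i, j] = theta[j, i] = -j_sign * mag
        edges.add((i, j))

    n_core_nodes = n_core_triangles + 2
    for a in range(n_core_nodes - 1):
        put(a, a + 1, +1)
    for a in range(n_core_nodes - 2):
        put(a, a + 2, +1)
        planted.append(((a, a + 1, a + 2), 0))

    cursor = n_core_nodes
    if embedded:
        if n_frustrated > n_core_nodes - 1:
            raise ValueError("not enough distinct core edges for attachments")
        for t in range(n_frustrated):
            i, j = t, t + 1  # distinct strip edge per attachment
            x = cursor
            cursor += 1
            put(i, x, -1)
            put(j, x, +1)
            planted.append((tuple(sorted((i, j, x))), 1))
    else:
        for _ in range(n_frustrated):
            a, b, c = cursor, cursor + 1, cursor + 2
            cursor += 3
            put(a, b, -1)
            put(b, c, +1)
            put(a, c, +1)
            planted.append(((a, b, c), 1))
    if cursor > n_genes:
        raise ValueError(f"n_genes={n_genes} too small, need {cursor}")
    _set_dominant_diagonal(theta)
    return PrecisionSpec(_default_gene_ids(n_genes), theta, edges, seed, planted)


def make_toy_study(
    n_core_triangles: int = 8,
    n_frustrated_normal: int = 5,
    n_frustrated_cancer: int = 2,
    n_samples: int = 10_000,
    weight_scale: float = 0.15,
    seed: int = 0,
) -> ToyStudy:
    """Two-condition synthetic study contrasting frustration localisation.

    The "normal-like" condition has ``n_frustrated_normal`` frustrated
    triangles isolated from the balanced core; the "cancer-like" condition
    has ``n_frustrated_cancer`` frustrated triangles embedded in the core's
    giant component.  Both share the same gene set.

    The default coupling scale is deliberately weak relative to the unit
    precision diagonal: the chained core violates the lasso's
    irrepresentability condition when couplings are strong, producing
    spurious weak distance-2 edges; at this scale a moderate penalty
    recovers the planted support exactly.
    """
    n_genes = (n_core_triangles + 2) + 3 * max(
        n_frustrated_normal, n_frustrated_cancer
    )
    normal_spec = _build_condition_spec(
        n_genes, n_core_triangles, n_frustrated_normal, False, weight_scale, seed
    )
    cancer_spec = _build_condition_spec(
        n_genes, n_core_triangles, n_frustrated_cancer, True, weight_scale, seed + 1
    )
    normal = sample_expression(normal_spec, n_samples, seed + 2, condition="normal")
    cancer = sample_expression(cancer_spec, n_samples, seed + 3, condition="cancer")
    return ToyStudy(
        normal=normal,
        cancer=cancer,
        normal_spec=normal_spec,
        cancer_spec=cancer_spec,
        normal_truth={0: n_core_triangles, 1: n_frustrated_normal, 2: 0, 3: 0},
        cancer_truth={0: n_core_triangles, 1: n_frustrated_cancer, 2: 0, 3: 0},
        normal_frustrated_in_giant=0,
        cancer_frustrated_in_giant=n_frustrated_cancer,
    )


def export_ground_truth(spec: PrecisionSpec, path) -> None:
    """Edge-list TSV of the ground truth: gene_i, gene_j, theta_ij."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\ttheta_ij\n")
        for i, j in sorted(spec.edge_list):
            fh.write(
                f"{spec.gene_ids[i]}\t{spec.gene_ids[j]}\t"
                f"{spec.theta[i, j]:.17g}\n"
            )
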