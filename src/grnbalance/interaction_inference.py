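"""Signed interaction network inference from expression covariance.

The maximum-entropy distribution over continuous expression levels with the
observed first and second moments is a multivariate Gaussian, so the pairwise
interaction matrix of the corresponding energy model is (minus) the precision
matrix: ``J = -C^{-1}`` off the diagonal.  With few samples the sample
covariance cannot be inverted reliably, so the precision matrix is estimated
with the graphical lasso, an L1-penalised maximum-likelihood estimator that
yields exact off-diagonal zeros — absent edges — rather than thresholding
weak links away.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import networkx as nx
from sklearn.covariance import graphical_lasso

from .expression_io import ExpressionMatrix

__all__ = [
    "CovarianceMatrix",
    "SignedNetwork",
    "sample_covariance",
    "glasso_precision",
    "interaction_network",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]

_SYM_TOL = 1e-12


@dataclass
class CovarianceMatrix:
    """Symmetric gene-gene covariance (expression units squared)."""

    gene_ids: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.gene_ids)
        if self.C.shape != (n, n):
            raise ValueError("covariance shape does not match gene_ids")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("covariance contains non-finite values")
        if np.max(np.abs(self.C - self.C.T)) > _SYM_TOL * max(
            1.0, np.max(np.abs(self.C))
        ):
            raise ValueError("covariance is not symmetric")
        if np.any(np.diag(self.C) < 0):
            raise ValueError("negative variance on the diagonal")

    def to_correlation(self) -> "CovarianceMatrix":
        """Standardise to the correlation matrix (unit diagonal)."""
        d = np.sqrt(np.diag(self.C))
        if np.any(d == 0):
            raise ValueError("zero-variance gene; cannot standardise")
        R = self.C / np.outer(d, d)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        return CovarianceMatrix(list(self.gene_ids), R)


@dataclass
class SignedNetwork:
    """Undirected signed weighted gene network.

    ``J`` is symmetric with an exactly-zero diagonal; an edge exists iff
    ``J_ij != 0`` (graphical-lasso zeros are structural, no extra threshold).
    Positive weights are inductive interactions, negative are inhibitory.
    """

    gene_ids: list[str]
    J: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        n = len(self.gene_ids)
        if self.J.shape != (n, n):
            raise ValueError("J shape does not match gene_ids")
        if np.max(np.abs(self.J - self.J.T), initial=0.0) > 0:
            raise ValueError("J must be exactly symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J diagonal must be exactly zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Unordered index pairs with nonzero weight, lexicographic order."""
        i, j = np.nonzero(np.triu(self.J, k=1))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_sign_counts(self) -> tuple[int, int]:
        """(number of positive edges, number of negative edges)."""
        upper = np.triu(self.J, k=1)
        return int(np.sum(upper > 0)), int(np.sum(upper < 0))

    def degree_sequence(self) -> list[int]:
        return np.count_nonzero(self.J, axis=1).astype(int).tolist()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        for i, j in self.edges:
            g.add_edge(self.gene_ids[i], self.gene_ids[j], weight=float(self.J[i, j]))
        return g


def sample_covariance(em: ExpressionMatrix) -> CovarianceMatrix:
    """Mean-centred sample covariance over samples (denominator n - 1)."""
    if em.n_samples < 2:
        raise ValueError("covariance needs at least 2 samples")
    C = np.cov(em.values, ddof=1)
    C = np.atleast_2d(C)
    C = (C + C.T) / 2.0
    return CovarianceMatrix(list(em.gene_ids), C)


def glasso_precision(
    cov: CovarianceMatrix,
    penalty: float,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Sparse precision matrix via the graphical lasso.

    Maximises ``log det(Theta) - tr(C Theta) - penalty * sum_{i!=j} |Theta_ij|``
    over symmetric positive-definite matrices.  ``penalty = 0`` reduces to the
    plain matrix inverse of ``C``.  ``tol`` is the duality-gap stopping
    criterion of the coordinate-descent solver.
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    C = cov.C
    if penalty == 0.0:
        try:
            theta = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("covariance is singular; penalty 0 needs an invertible input") from exc
        return (theta + theta.T) / 2.0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            _, theta, n_iter = graphical_lasso(
                C, alpha=penalty, tol=tol, max_iter=max_iter, return_n_iter=True
            )
        except FloatingPointError as exc:
            raise RuntimeError(f"graphical lasso did not converge: {exc}") from exc
    if n_iter >= max_iter:
        # the reported duality gap is mathematically >= 0; a small negative
        # value means the solver sits at its numerical floor and is converged
        gap = _parse_dual_gap(caught)
        if gap is None or gap > 10 * tol:
            raise RuntimeError(
                f"graphical lasso hit max_iter={max_iter} without reaching "
                f"duality gap {tol} (last gap: {gap})"
            )
    theta = np.asarray(theta)
    # symmetrise exactly; keep structural zeros exact
    theta = np.where(np.abs(theta) < np.abs(theta.T), theta, theta.T)
    theta = (theta + theta.T) / 2.0
    return theta


def _parse_dual_gap(caught: list[warnings.WarningMessage]) -> float | None:
    for w in caught:
        m = re.search(r"dual gap: (-?[\d.e+-]+)", str(w.message))
        if m:
            return float(m.group(1))
    return None


def glasso_objective(C: np.ndarray, theta: np.ndarray, penalty: float) -> float:
    """Penalised Gaussian log-likelihood objective (to maximise)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    l1 = np.sum(np.abs(theta)) - np.sum(np.abs(np.diag(theta)))
    return float(logdet - np.trace(C @ theta) - penalty * l1)


def interaction_network(
    theta: np.ndarray, gene_ids: Sequence[str]
) -> SignedNetwork:
    """Signed network J = -Theta off the diagonal; J_ii = 0.

    An edge is present exactly where the precision off-diagonal is nonzero;
    no magnitude threshold is applied, so weak links survive.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != theta.shape[1]:
        raise ValueError("theta must be square")
    if np.max(np.abs(theta - theta.T), initial=0.0) > _SYM_TOL * max(
        1.0, np.max(np.abs(theta))
    ):
        raise ValueError("theta must be symmetric")
    J = -((theta + theta.T) / 2.0)
    np.fill_diagonal(J, 0.0)
    J = J + 0.0  # normalise -0.0 to 0.0 so support tests are exact
    return SignedNetwork(list(gene_ids), J)


# ---------------------------------------------------------------------------
# serialisation


def write_edgelist(net: SignedNetwork, path: str | Path) -> None:
    """Edge-list TSV: gene_i, gene_j, J_ij (17 significant digits)."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tJ_ij\n")
        for i, j in net.edges:
            fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\t{net.J[i, j]:.17g}\n")


def read_edgelist(
    path: str | Path, gene_ids: Sequence[str] | None = None
) -> SignedNetwork:
    """Read an edge-list TSV written by :func:`write_edgelist`.

    If ``gene_ids`` is omitted, the node set is the sorted set of ids seen
    in the file.
    """
    triples: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_i"):
            raise ValueError(f"{path}: missing edge-list header")
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            triples.append((a, b, float(w)))
    if gene_ids is None:
        gene_ids = sorted({g for a, b, _ in triples for g in (a, b)})
    index = {g: i for i, g in enumerate(gene_ids)}
    J = np.zeros((len(gene_ids), len(gene_ids)))
    for a, b, w in triples:
        J[index[a], index[b]] = J[index[b], index[a]] = w
    return SignedNetwork(list(gene_ids), J)


def write_graphml(net: SignedNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


def read_graphml(path: str | Path) -> SignedNetwork:
    g = nx.read_graphml(str(path))
    gene_ids = sorted(g.nodes)
    index = {gid: i for i, gid in enumerate(gene_ids)}
    J = np.zeros((len(gene_ids), len(gene_ids)))
    for a, b, data in g.edges(data=True):
        J[index[a], index[b]] = J[index[b], index[a]] = float(data["weight"])
    return SignedNetwork(gene_ids, J)
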