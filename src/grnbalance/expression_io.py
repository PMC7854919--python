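"""Reading, normalising and filtering gene-expression tables.

The pipeline's data front door: a genes x samples real-valued matrix with
unique gene and sample identifiers.  Values are either RPKM-normalised
expression levels or raw read counts (to be converted with
:func:`compute_rpkm`).  Downstream inference treats each gene's expression
level as a continuous real-valued variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "write_expression_table",
    "compute_rpkm",
    "gene_variances",
    "select_top_variance",
    "log2_transform",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``values``.
    sample_ids
        Unique sample identifiers, one per column of ``values``.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; all
        entries must be finite.
    condition
        Optional per-sample condition label (e.g. ``"normal"``/``"cancer"``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {label} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.condition is not None and len(self.condition) != len(self.sample_ids):
            raise ValueError("condition must have one label per sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[rows], self.condition
        )


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_table(
    path: str | Path,
    orientation: str = "genes-in-rows",
    condition: str | None = None,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression table.

    The file must have one header row and one identifier column (the first).
    With ``orientation="genes-in-rows"`` the header holds sample ids and the
    first column gene ids; ``"genes-in-columns"`` is the transpose.

    ``condition``, if given, is applied as the label of every sample.
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.isnull().any() or df.isnull().any().any():
        raise ValueError(f"{path}: ragged or incomplete rows")
    if orientation == "genes-in-columns":
        df = df.T
    values = np.empty(df.shape, dtype=float)
    # cell-by-cell float() parse: correctly rounded (bit-exact round-trips,
    # unlike pandas' fast parser) and lets errors name the offending cell
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (ValueError, TypeError):
                raise ValueError(
                    f"non-numeric value {raw!r} at gene {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    labels = [condition] * df.shape[1] if condition is not None else None
    return ExpressionMatrix(list(df.index), list(df.columns), values, labels)


def write_expression_table(em: ExpressionMatrix, path: str | Path) -> None:
    """Write in the same dialect read_expression_table reads (round-trips)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        fh.write("gene_id" + sep + sep.join(em.sample_ids) + "\n")
        for g, row in zip(em.gene_ids, em.values):
            fh.write(g + sep + sep.join(format(v, ".17g") for v in row) + "\n")


def compute_rpkm(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Reads-Per-Kilobase-per-Million normalisation of raw read counts.

    ``RPKM_ij = counts_ij / ((length_i / 1e3) * (library_size_j / 1e6))``
    where the library size is the column sum of the raw counts.
    """
    if np.any(counts.values < 0):
        raise ValueError("counts must be non-negative")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise KeyError(f"no length for gene(s): {missing[:5]}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    if np.any(lengths <= 0):
        bad = counts.gene_ids[int(np.argmax(lengths <= 0))]
        raise ValueError(f"non-positive length for gene {bad!r}")
    lib = counts.values.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.sample_ids[int(np.argmax(lib == 0))]
        raise ValueError(f"zero library size in sample {bad!r}")
    rpkm = counts.values / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), rpkm, counts.condition
    )


def gene_variances(em: ExpressionMatrix, ddof: int = 1) -> dict[str, float]:
    """Per-gene variance of expression across samples.

    ``ddof=1`` (the default) gives the unbiased sample variance; the choice
    does not affect any variance *ranking*.
    """
    if em.n_samples < 2:
        raise ValueError("variance needs at least 2 samples")
    var = em.values.var(axis=1, ddof=ddof)
    return dict(zip(em.gene_ids, var.tolist()))


def select_top_variance(em: ExpressionMatrix, k: int, ddof: int = 1) -> ExpressionMatrix:
    """Keep the ``k`` genes of highest expression variance.

    Rows of the result are ordered by descending variance; ties are broken
    lexicographically by gene id so the selection is deterministic.
    """
    if not 1 <= k <= em.n_genes:
        raise ValueError(f"k={k} out of range for {em.n_genes} genes")
    var = gene_variances(em, ddof=ddof)
    ranked = sorted(em.gene_ids, key=lambda g: (-var[g], g))
    return em.subset_genes(ranked[:k])


def log2_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Optional log2(x + 1) transform of expression levels."""
    if np.any(em.values < 0):
        raise ValueError("log2 transform expects non-negative expression")
    return ExpressionMatrix(
        list(em.gene_ids), list(em.sample_ids), np.log2(em.values + 1.0), em.condition
    )
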