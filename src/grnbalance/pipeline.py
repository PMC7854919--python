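"""End-to-end orchestration: expression tables in, balance report out.

Each condition is processed fully independently: read -> (optional RPKM,
optional log2) -> variance filter -> sample covariance -> graphical lasso ->
J = -Theta -> triangle enumeration -> energies and histograms -> triangle
graph, mixing matrix, component stats -> artifacts on disk.  With two
conditions the total energies are compared and referenced against the
degree-preserving shuffle null.

Defaults follow the study settings: keep the 483 highest-variance genes and
sparsify with graphical-lasso penalty 0.09.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import balance_analysis as ba
from . import expression_io as eio
from . import interaction_inference as ii
from . import null_model as nm
from . import triangle_graph as tg

__all__ = ["PipelineConfig", "StudySummary", "run_pipeline", "write_summary", "read_summary"]

log = logging.getLogger("grnbalance.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    ``inputs`` maps condition name -> expression table path (one or two
    conditions).  ``top_k_genes`` (default 483) and ``glasso_penalty``
    (default 0.09) reproduce the study's stated settings.
    """

    inputs: dict[str, str]
    output_dir: str = "results/pipeline"
    orientation: str = "genes-in-rows"
    gene_lengths: str | None = None  # two-column TSV enables RPKM
    log2: bool = False
    top_k_genes: int = 483
    standardize: bool = False  # feed correlation instead of covariance
    glasso_penalty: float = 0.09
    glasso_tol: float = 1e-4
    glasso_max_iter: int = 500
    variance_ddof: int = 1
    histogram_bins: int = 30
    mixing_bins: int = 20
    mixing_signed: bool = True
    null_realizations: int = 20
    null_swaps_factor: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= len(self.inputs) <= 2:
            raise ValueError("inputs must name one or two conditions")
        if self.top_k_genes < 1:
            raise ValueError("top_k_genes must be positive")
        if self.glasso_penalty < 0:
            raise ValueError("glasso_penalty must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ConditionSummary:
    condition: str
    n_genes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    triangle_counts: dict[int, int]
    n_triangles: int
    n_imbalanced: int
    total_energy: float
    total_energy_per_node: float
    frac_imbalanced_in_giant: float
    giant_size: int
    assortativity: float


@dataclass
class StudySummary:
    config: dict[str, Any]
    conditions: dict[str, ConditionSummary]
    energy_difference: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    z_score: float | None = None


def _read_gene_lengths(path: str | Path) -> dict[str, float]:
    lengths: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            gid, val = line.split("\t")
            lengths[gid] = float(val)
    return lengths


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def _process_condition(
    name: str, path: str, config: PipelineConfig, outdir: Path
) -> ConditionSummary:
    with _stage(f"{name}:read"):
        em = eio.read_expression_table(path, config.orientation, condition=name)
        log.info("%s: %d genes x %d samples", name, em.n_genes, em.n_samples)
    if config.gene_lengths:
        with _stage(f"{name}:rpkm"):
            em = eio.compute_rpkm(em, _read_gene_lengths(config.gene_lengths))
    if config.log2:
        with _stage(f"{name}:log2"):
            em = eio.log2_transform(em)
    with _stage(f"{name}:variance-filter"):
        k = min(config.top_k_genes, em.n_genes)
        em = eio.select_top_variance(em, k, ddof=config.variance_ddof)
    with _stage(f"{name}:covariance"):
        cov = ii.sample_covariance(em)
        if config.standardize:
            cov = cov.to_correlation()
    with _stage(f"{name}:glasso"):
        theta = ii.glasso_precision(
            cov, config.glasso_penalty, tol=config.glasso_tol,
            max_iter=config.glasso_max_iter,
        )
    with _stage(f"{name}:network"):
        net = ii.interaction_network(theta, cov.gene_ids)
        ii.write_edgelist(net, outdir / f"{name}_edges.tsv")
        ii.write_graphml(net, outdir / f"{name}_network.graphml")
    with _stage(f"{name}:triangles"):
        triangles = ba.enumerate_triangles(net)
        ba.write_triangle_table(triangles, outdir / f"{name}_triangles.tsv")
        counts = ba.type_counts(triangles)
        e_raw = ba.total_energy(triangles)
        e_node = ba.total_energy(triangles, "per-node", n_genes=net.n_genes)
        for label in ("D0", "D1", "D2", "D3"):
            if triangles:
                edges_, counts_ = ba.energy_distribution(
                    triangles, label, n_bins=config.histogram_bins
                )
                ba.write_histogram(edges_, counts_, outdir / f"{name}_hist_{label}.tsv")
    with _stage(f"{name}:triangle-graph"):
        graph = tg.build_triangle_graph(triangles)
        tg.write_triangle_graphml(graph, outdir / f"{name}_triangle_graph.graphml")
        mix = tg.mixing_matrix(
            graph, n_bins=config.mixing_bins, signed=config.mixing_signed
        )
        tg.write_mixing_matrix(mix, outdir / f"{name}_mixing.tsv")
        comp = tg.giant_component_stats(graph)
        assort = tg.energy_assortativity(graph)
    pos, neg = net.edge_sign_counts()
    return ConditionSummary(
        condition=name,
        n_genes=net.n_genes,
        n_edges=net.n_edges,
        n_positive_edges=pos,
        n_negative_edges=neg,
        triangle_counts=counts,
        n_triangles=len(triangles),
        n_imbalanced=counts[1] + counts[3],
        total_energy=e_raw,
        total_energy_per_node=e_node,
        frac_imbalanced_in_giant=comp.frac_imbalanced_in_giant,
        giant_size=comp.giant_size,
        assortativity=assort,
    )


def run_pipeline(config: PipelineConfig) -> StudySummary:
    """Execute the full analysis; writes artifacts under ``config.output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", asdict(config))
    summaries: dict[str, ConditionSummary] = {}
    nets: dict[str, ii.SignedNetwork] = {}
    for name in sorted(config.inputs):
        summaries[name] = _process_condition(name, config.inputs[name], config, outdir)
        nets[name] = ii.read_edgelist(outdir / f"{name}_edges.tsv")
    summary = StudySummary(config=asdict(config), conditions=summaries)
    if len(summaries) == 2:
        (na, a), (nb, b) = sorted(summaries.items())
        summary.energy_difference = abs(a.total_energy - b.total_energy)
        with _stage("null-model"):
            null = nm.null_energy_difference(
                nets[na],
                nets[nb],
                n_realizations=config.null_realizations,
                n_swaps=None
                if config.null_swaps_factor == 10
                else config.null_swaps_factor * max(n.n_edges for n in nets.values()),
                seed=config.seed,
            )
        summary.null_mean = null.mean
        summary.null_sd = null.sd
        summary.z_score = (
            (summary.energy_difference - null.mean) / null.sd
            if null.sd > 0
            else float("nan")
        )
    write_summary(summary, outdir / "summary.json")
    return summary


def _sig15(x: float | None) -> float | None:
    if x is None:
        return None
    if math.isnan(x):
        return None  # explicit null marker in JSON
    return float(f"{x:.15g}")


def write_summary(summary: StudySummary, path: str | Path) -> None:
    """JSON with stable key order; counts as integers, energies as decimals."""
    payload: dict[str, Any] = {"config": summary.config, "conditions": {}}
    for name in sorted(summary.conditions):
        c = summary.conditions[name]
        payload["conditions"][name] = {
            "n_genes": int(c.n_genes),
            "n_edges": int(c.n_edges),
            "n_positive_edges": int(c.n_positive_edges),
            "n_negative_edges": int(c.n_negative_edges),
            "triangle_counts": {
                f"D{k}": int(c.triangle_counts[k]) for k in sorted(c.triangle_counts)
            },
            "n_triangles": int(c.n_triangles),
            "n_imbalanced": int(c.n_imbalanced),
            "total_energy": _sig15(c.total_energy),
            "total_energy_per_node": _sig15(c.total_energy_per_node),
            "frac_imbalanced_in_giant": _sig15(c.frac_imbalanced_in_giant),
            "giant_size": int(c.giant_size),
            "assortativity": _sig15(c.assortativity),
        }
    payload["cross_condition"] = {
        "energy_difference": _sig15(summary.energy_difference),
        "null_mean": _sig15(summary.null_mean),
        "null_sd": _sig15(summary.null_sd),
        "z_score": _sig15(summary.z_score),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
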