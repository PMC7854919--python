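"""Infer the signed interaction networks J = -Theta for both conditions.

Reads the simulated expression tables, estimates the sample covariance and
the sparse precision matrix (graphical lasso, penalty 0.08 — the recovery
regime for the weakly-coupled toy; the study-scale default of 0.09 lives in
the pipeline config), and reports how well the inferred edge set and signs
match the planted ground truth.
"""

from pathlib import Path

import numpy as np

from grnbalance.expression_io import read_expression_table
from grnbalance.interaction_inference import (
    glasso_precision,
    interaction_network,
    read_edgelist,
    sample_covariance,
    write_edgelist,
    write_graphml,
)

DATA = Path("results/data")
OUT = Path("results/networks")
PENALTY = 0.08


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("normal", "cancer"):
        em = read_expression_table(DATA / f"{name}_expression.tsv", condition=name)
        cov = sample_covariance(em)
        theta = glasso_precision(cov, PENALTY)
        net = interaction_network(theta, cov.gene_ids)
        write_edgelist(net, OUT / f"{name}_edges.tsv")
        write_graphml(net, OUT / f"{name}_network.graphml")

        truth = read_edgelist(DATA / f"{name}_truth_edges.tsv", net.gene_ids)
        true_edges = set(truth.edges)
        got_edges = set(net.edges)
        sign_ok = sum(
            1 for (i, j) in true_edges & got_edges
            if np.sign(net.J[i, j]) == np.sign(-truth.J[i, j])
        )
        pos, neg = net.edge_sign_counts()
        print(
            f"{name}: {net.n_edges} edges ({pos}+/{neg}-); "
            f"support: {len(got_edges & true_edges)}/{len(true_edges)} true, "
            f"{len(got_edges - true_edges)} spurious; "
            f"signs correct on {sign_ok}/{len(true_edges & got_edges)} recovered edges"
        )


if __name__ == "__main__":
    main()
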