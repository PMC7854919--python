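"""Generate the two-condition synthetic study.

Draws a "normal-like" and a "cancer-like" expression matrix from known
sparse signed precision matrices.  Both share a balanced triangle-strip core;
the normal-like condition carries 5 frustrated triangles on gene triples
disjoint from the core, the cancer-like condition 2 frustrated triangles
attached to the core.  Writes the expression tables and the ground-truth
edge lists under results/data/.
"""

import json
from pathlib import Path

from grnbalance.expression_io import write_expression_table
from grnbalance.synthetic_data import export_ground_truth, make_toy_study

OUT = Path("results/data")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = make_toy_study(seed=SEED)
    for name, em, spec in [
        ("normal", study.normal, study.normal_spec),
        ("cancer", study.cancer, study.cancer_spec),
    ]:
        write_expression_table(em, OUT / f"{name}_expression.tsv")
        export_ground_truth(spec, OUT / f"{name}_truth_edges.tsv")
        print(
            f"{name}: {em.n_genes} genes x {em.n_samples} samples, "
            f"{len(spec.edge_list)} true edges, "
            f"{len(spec.planted_triangles)} planted triangles"
        )
    truth = {
        "seed": SEED,
        "normal_counts": {f"D{k}": v for k, v in study.normal_truth.items()},
        "cancer_counts": {f"D{k}": v for k, v in study.cancer_truth.items()},
        "normal_frustrated_in_giant": study.normal_frustrated_in_giant,
        "cancer_frustrated_in_giant": study.cancer_frustrated_in_giant,
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"ground truth -> {OUT / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
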