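# grnbalance

Structural-balance analysis of signed gene regulatory networks inferred
from expression data.

## The problem

Genes up- and down-regulate one another, so a cell's transcriptome is
shaped by a signed, weighted gene regulatory network (GRN): positive edges
for inductive influence, negative for inhibitory. Balance theory classifies
each triangle of such a network by the product of its edge signs — a
triangle with an odd number of negative links is *imbalanced* (frustrated)
and carries positive energy, a tension the network would "like" to resolve.
Comparing how much frustration two conditions carry, and *where* the
frustrated triangles sit (isolated motifs vs embedded in the network's
giant component), distinguishes network-level organisation that single-gene
analyses cannot see — e.g. between expression data from normal and from
cancerous tissue.

`grnbalance` is for computational/systems biologists who have a genes x
samples expression table (RPKM values, or raw counts plus gene lengths) per
condition and want that comparison end to end.

## The model

With expression levels treated as continuous Gaussian fields `S_i`, the
maximum-entropy distribution matching the observed first and second moments
is a multivariate Gaussian, and the pairwise interaction matrix of the
corresponding energy model `H = −Σ_{i<j} J_ij S_i S_j` is minus the
precision matrix:

```
J = −C⁻¹   (off-diagonal)
```

Because samples are far fewer than gene pairs, the precision matrix is
estimated with the **graphical lasso**, maximising
`log det Θ − tr(CΘ) − ρ Σ_{i≠j}|Θ_ij|`. The L1 penalty ρ produces exact
zeros — absent edges — instead of thresholding away weak-but-structurally
important links.

On the resulting signed network:

* triangle energy `E_ijk = −J_ij J_jk J_ki` (balanced < 0, frustrated > 0);
* total energy `E_total = Σ E_ijk` over unordered triangles;
* the coarse-grained **triangle graph** (triangles sharing an edge are
  adjacent), its giant component, the binned energy–energy mixing matrix
  `C_kl`, and energy assortativity;
* a degree-preserving, weight-carrying double-edge-swap **null model** for
  the total-energy difference between conditions.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with planted
ground truth (a balanced triangle core plus frustrated triangles, isolated
in the "normal-like" condition and attached to the core in the
"cancer-like" one):

```
$ python analysis/01_simulate_study.py
normal: 25 genes x 10000 samples, 32 true edges, 13 planted triangles
cancer: 25 genes x 10000 samples, 21 true edges, 10 planted triangles

$ python analysis/02_infer_networks.py
normal: 32 edges (27+/5-); support: 32/32 true, 0 spurious; signs correct on 32/32 recovered edges
cancer: 21 edges (19+/2-); support: 21/21 true, 0 spurious; signs correct on 21/21 recovered edges

$ python analysis/03_triangle_energies.py
normal: 13 triangles (D0=8 D1=5 D2=0 D3=0, 5 frustrated); total energy -0.0083 (-0.0003 per node)
cancer: 10 triangles (D0=8 D1=2 D2=0 D3=0, 2 frustrated); total energy -0.0085 (-0.0007 per node)

$ python analysis/04_coarse_grain.py
normal: 13 triangle nodes, 7 adjacencies; giant component 8 nodes; frustrated in giant: 0/5 (fraction 0.000); energy assortativity 0.217
cancer: 10 triangle nodes, 10 adjacencies; giant component 10 nodes; frustrated in giant: 2/2 (fraction 1.000); energy assortativity 0.181

$ python analysis/05_null_comparison.py
total energy: normal -0.0083, cancer -0.0085; |difference| 0.0002
shuffle null (50 realizations): 0.0028 +/- 0.0018; z = -1.42
```

Reading the numbers: the inference recovers every planted edge with the
right sign and no spurious ones; the triangle census matches the planted
counts exactly (D1 = frustrated triangles with one negative link: 5 vs 2);
and the localisation contrast is recovered — none of the normal-like
network's frustrated triangles touch the giant component, while both of the
cancer-like network's do. The tiny total energies are expected: energies
are cubic in the shrunken interaction weights.

Real data go through the same machinery via the CLI:

```
grnbalance run-all --input normal=normal.tsv --input cancer=cancer.tsv \
    --top-k 483 --penalty 0.09 --out results/study
```

(defaults: keep the 483 highest-variance genes, graphical-lasso penalty
0.09). Subcommands `infer`, `balance`, `mix`, `null` expose the stages
individually.

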