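# Methods

## Interaction inference

Expression levels are modelled as continuous Gaussian variables. The
maximum-entropy distribution constrained to the observed means and
covariances is the multivariate Gaussian, whose pairwise coupling matrix is
minus the precision matrix; we therefore define the signed interaction
network as `J_ij = −Θ_ij` for `i ≠ j`, `J_ii = 0`. Some derivations place a
factor 2 between the covariance and the inverse coupling matrix; we use
`J = −C⁻¹` directly, since any uniform rescaling changes no edge sign,
triangle class, or mixing structure — only the overall energy scale.

The precision matrix is estimated with the graphical lasso
(`sklearn.covariance.graphical_lasso`): maximise
`log det Θ − tr(CΘ) − ρ Σ_{i≠j}|Θ_ij|`. Choices:

* **Input scale.** The sample covariance (denominator n−1) is passed to the
  solver by default; a `standardize` switch feeds the correlation matrix
  instead, which is the right choice whenever genes have wildly different
  expression scales, since a fixed penalty is only meaningful relative to
  the input scale.
* **Edges are structural zeros.** An edge exists iff `Θ_ij ≠ 0` exactly.
  No magnitude threshold is applied afterwards: L1 zeros are exact, and
  thresholding would preferentially delete weak links that can be
  structurally important (e.g. bridges).
* **Penalty.** The pipeline default is ρ = 0.09 with the top 483
  highest-variance genes, the study-scale settings. ρ = 0 is special-cased
  to the exact matrix inverse (the unpenalised maximum-likelihood limit).
* **Convergence.** Duality-gap tolerance 1e-4, max 500 sweeps, both
  configurable. The solver's reported gap is mathematically non-negative;
  a slightly negative reported value indicates the numerical floor and is
  treated as converged. Tolerances much below 1e-4 are not reachable on
  typical covariance inputs in double precision.

## Preprocessing

RPKM: `count / ((length/10³)·(library/10⁶))`, library size = raw-count
column sum. Gene selection keeps the k genes of largest sample variance
(ddof 1; the ranking is denominator-independent), ties broken
lexicographically by gene id for determinism. When two conditions are
present each condition's network is built from its own samples, selection
included; pooled selection is a config switch. No log transform by default;
`log2(x+1)` is available behind a flag.

## Balance and energies

A triangle on genes (i, j, k) requires all three edges nonzero. Its energy
is `E = −J_ij J_jk J_ki`; with k negative links it is of type Δ_k, balanced
for even k (E < 0), frustrated for odd k (E > 0). Total energy is the sum
over *unordered* triangles (summing ordered index triples would only
multiply every total by 6); the per-node variant divides by the gene count
and is reported alongside. |Energy| histograms use 30 logarithmic bins
between the observed nonzero extremes by default.

The coarse-grained triangle graph connects two triangles iff they share an
edge of the underlying network (sharing only a vertex does not connect
them). The energy–energy mixing matrix counts, for every adjacent triangle
pair, both orientations of their binned energies (20 equal-width signed
bins symmetric about zero by default; |energy| bins and a 1/N normalisation
are config options, since either convention is defensible). Giant-component
membership is computed by connected-components traversal, largest component
by node count with lexicographic tie-break; assortativity is the Pearson
correlation of endpoint energies over both orientations of each adjacency,
reported as NaN when undefined (no adjacency or zero variance).

## Null model

Degree-preserving double edge swaps: pick two distinct edges uniformly,
pick one of the two rewirings uniformly, reject self-loops and duplicate
edges; weights travel with their edge. Default 10 swap attempts per edge.
The null comparison shuffles both networks with a shared per-realization
seed (so identical inputs give exactly zero difference) and records the
absolute total-energy difference over realizations.

## Synthetic data

The generator draws expression from `N(0, Θ⁻¹)` with Θ built explicitly:

* random support at a given density, off-diagonal magnitudes uniform in
  `[0.5, 1.5]·weight_scale`, negative with a given probability;
* positive definiteness by strict diagonal dominance,
  `Θ_ii = max(1, 1.1·Σ_j|Θ_ij|)` — simple, and it never flips a planted
  off-diagonal sign;
* planted triangle motifs occupy otherwise edge-free gene triples, so the
  ground-truth census is exactly the requested counts;
* near-constant "housekeeping-like" genes can be appended to exercise the
  variance filter.

The two-condition toy study (`make_toy_study`) plants a strip of balanced
all-positive triangles as a connected core, plus Δ₁ frustrated triangles
either on disjoint triples ("normal-like": frustration isolated from the
giant component) or attached to distinct core edges by one new gene with
one negative link ("cancer-like": frustration embedded). Defaults: 8 core
triangles, 5 isolated vs 2 embedded frustrated triangles, 10⁴ samples per
condition, coupling scale 0.15.

The coupling scale is deliberately weak. The chained core violates the
lasso irrepresentability condition when couplings are strong, in which case
the graphical lasso plants small spurious distance-2 edges at *every*
penalty and exact support recovery is impossible; at scale 0.15 a penalty
of 0.08 recovers the planted support exactly across seeds. This is a
designed property of the demonstration: the toy study's purpose is to make
the full chain's correctness checkable against ground truth.

What the generator does **not** emulate: RNA-Seq count noise (negative
binomial dispersion, zeros), gene-length and library-size artefacts,
non-Gaussian marginals, or the ~20k-gene scale of real transcriptomes.
Passing tests therefore certify the inference and balance machinery under
the model's own assumptions, not robustness to real-data violations of
Gaussianity.

## Problem sizes

Tests and the acceptance script run the toy study at 25 genes x 10⁴
samples, the sign-recovery experiment at 20 genes x 5000 samples over 10
seeds, oracle comparisons on 50 random graphs of up to 15 nodes, and the
null with 20–50 shuffle realizations — sizes at which every claim can be
checked exactly or within tight Monte-Carlo error in seconds.

## Known limitations

* The network is undirected and static; time-lagged or directed regulation
  is out of scope.
* Energies are cubic in edge weights, so totals depend on the penalty
  through shrinkage; only comparisons under a fixed convention are
  meaningful, not absolute "units".
* The mixing-matrix binning convention (signed vs absolute energies, the
  normalising N) is not canonical; both are exposed as config.
* Exact support recovery by the graphical lasso requires weak coupling /
  incoherent designs; on strongly coupled networks the inferred edge set
  should be read as approximate.
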