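# Methods

## Model

A subject's network is an undirected weighted graph `G(V, E, W)` given as a
square nonnegative matrix `W` with zero diagonal; for brain data, `W[i, j]`
is the number of tracked fibers between regions `i` and `j`. A group of
subjects sharing one node set is summarized by the elementwise mean matrix.
All scoring operates on a single (typically group-average) network.

### Cleaning

Each subject matrix is thresholded at `min_weight` (default 1: any traced
fiber forms an edge; counts below the threshold are treated as
tractography noise), its diagonal is zeroed, and near-symmetric input —
asymmetry up to `symmetrize_tol × max(W)` — is symmetrized by averaging.
Larger asymmetry is an error rather than a silent fix, since FN matrices
are symmetric by construction and real asymmetry indicates a corrupted
export. Subjects are cleaned *before* averaging and the average is not
re-thresholded; thresholding the average would re-binarize genuine
group-level gradations.

### Local features

Four classical indices are computed on the positive-weight skeleton:

* **Degree centrality** `C_D(v) = d(v)/(n−1)`, `d` counting distinct
  neighbors. Weights do not contribute; a single heavy edge is still one
  neighbor.
* **Betweenness centrality** `c_B(v)`: the sum over unordered pairs
  `{s, t}`, `v ∉ {s, t}`, of `σ(s,t|v)/σ(s,t)` (geodesic counting;
  unreachable pairs contribute 0). Unordered summation halves the ordered
  value for every node and cannot change any ranking.
* **Closeness centrality** `C_c(v) = (n−1)/Σ_j d(j, v)` on connected
  graphs. On disconnected graphs the within-component closeness
  `(r−1)/Σ d` over the `r` reachable nodes is scaled by `(r−1)/(n−1)`
  (Wasserman–Faust), which recovers the plain definition exactly on
  connected graphs and gives isolated nodes 0; without this rule the
  definition involves infinite distances.
* **Maximal-clique count** `N_MC(v)`: the number of maximal cliques
  containing `v`, enumerated by Bron–Kerbosch with pivoting. An isolated
  node is its own singleton maximal clique (`N_MC = 1`), by set-theoretic
  maximality. A configurable cap (default 2×10⁶ cliques) guards the
  exponential worst case.

Shortest paths default to unit edge lengths on the binarized skeleton,
matching the unweighted degree definition; a weighted mode with edge
length `1/w` (stronger connections are shorter) is available for both
path-based features, since either convention is defensible for count
weights.

### 2hopRWR and 2hop-connectivity

The 1-step operator is the weighted row normalization `P = D⁻¹W` with
`d_i = Σ_j w_ij`; a node with no edges keeps its step mass on itself, so
`P` stays stochastic. The 2-step operator is the matrix square `P²`,
including its return-to-self mass. For each node,
`α₁ = |N₁|/(|N₁| + |N₂|)` where `N₁` are 1-hop neighbors and `N₂` the
nodes at graph distance exactly 2 (self and `N₁` excluded); nodes with no
neighbors at all get `α₁ = 1`. The mixed step operator is

    A = diag(α₁) P + diag(α₂) P²,

which is row-stochastic because each row is a convex combination of two
stochastic rows; a scalar-α mode (`A = α₁P + α₂P²`) is also provided, and
with `α₁ = 1` the model reduces exactly to the classical random walk with
restart. The walk iterates

    r_{t+1} = c Aᵀ r_t + (1 − c) r₀ ,

with `r₀` the unit vector at the start node. Since the spectral radius of
`cAᵀ` is at most `c < 1`, the iteration contracts geometrically
(`L1 residual ≤ 2cᵗ`) to the unique fixed point

    r_∞ = (1 − c)(I − cAᵀ)⁻¹ r₀ ,

which is also computed directly as a linear solve; the agreement of the
two routes is asserted in the tests and the acceptance script, turning the
convergence proof into an executable check. All n starts at once are one
matrix solve: `Π = (1 − c)(I − cA)⁻¹`, whose row `i` is the stationary
distribution of the walk started at `v_i`.

**Scoring from Π.** Summing row `i` of `Π` is degenerate: each row is a
probability vector, so the row total is identically 1 and cannot rank
nodes. The package therefore scores by **column sums**,
`S_2hop(v_i) = Σ_j Π[j, i]` — the total stationary mass node `i` receives
over all start nodes, the standard restart-walk relevance aggregate and
the reading consistent with "larger score = more important node". The
literal row-sum mode is retained (with a warning) to document the
degeneracy. Both modes total exactly `n` over all nodes.

**Parameters.** `c` defaults to 0.85 (restart probability 0.15, the common
random-walk-with-restart convention); `c = 1` is rejected because the
stationary solution is then non-unique. Convergence tolerance `tol`
defaults to 1e−10 in L1 with `max_iter = 1000`; by the geometric bound
this is reachable for any `c ≤ 0.98`. The solver is fully deterministic.

### Global Feature Score

Each of the five feature vectors is min-max normalized to [0, 1] per
network (the only rescaling that maps onto the stated [0, 1] range;
z-scores do not). A feature that is constant across nodes — to a relative
tolerance of 1e−12, so solver round-off on vertex-transitive graphs is
not amplified into a spurious spread — normalizes to all zeros and
contributes nothing. GFS is the convex combination of the five normalized
features with weights `w`, default `w = (1/5, …, 1/5)`. Optionally the
weights are fitted by nonnegative least squares of an external per-node
score on the normalized features, rescaled to sum 1; NNLS keeps GFS a
convex combination, and an all-zero fit falls back to equal weights with
a warning. At least 6 observations are required (five coefficients).

### Differential ranking and CCA

Two group-average networks with identical node sets are each scored;
nodes are ranked by `ΔGFS = GFS_A − GFS_B` descending, ties broken by
input label order (stable sort) for bitwise-reproducible output. The
association between two observation blocks (e.g., per-subject GFS values
and MMSE/MoCA scale scores) is summarized by the first canonical
correlation: both blocks are centered, whitened by symmetric inverse
square roots of their covariances (eigenvalues below `rcond = 1e−10`
times the largest are treated as null directions, so rank-deficient
blocks remain well defined), and the largest singular value of the
whitened cross-covariance is `ρ`. Loadings are reported normalized to
unit composite variance. Only the first canonical pair is reported, and
no significance test is attached. How per-node scores are matched to
per-subject observations is a study-design question left to the caller;
the function accepts any two conformable observation tables.

## Synthetic study design

The generator emulates a case–control connectome contrast:

* one base topology per study — Erdős–Rényi at `edge_density` (default
  0.15, a typical FN-matrix density after thresholding), resampled until
  connected — shared by both groups, so the planted effect is the only
  systematic difference;
* integer edge weights from a log-normal with mean `weight_scale`
  (default 50 fibers, log-σ = 1, giving the right-skewed spread of
  tractography counts), rounded up to at least 1;
* per-subject multiplicative log-normal noise per edge with mean 1 and
  coefficient of variation `subject_noise_cv` (default 0.2), weights
  re-rounded to nonnegative integers;
* in case subjects, every edge incident to the `affected_nodes` set
  (default 5 of 90 nodes) is scaled by `attenuation` (default 0.2)
  *before* the noise — a structural deficit, not a measurement artifact.
  `attenuation = 1` is the exact null: both groups are draws from the
  same distribution.

What the generator does **not** emulate: anatomical wiring (distance
dependence, hemispheric symmetry, hubs/modules), tractography artifacts
(gyral bias, crossing-fiber dropout), or subject-level topology
differences. Passing the recovery study therefore shows the pipeline
detects localized connectivity attenuation against multiplicative count
noise — not that it handles registration error or population
heterogeneity in real cohorts.

Under the default study conditions (90 nodes, 15% density, 10 subjects
per group, CV 0.2, 5 nodes attenuated to 20%), the pipeline's top-5 ΔGFS
set recovers on average over 90% of the planted nodes across 20 seeds,
while the attenuation-free null recovers them at the 5/90 chance rate;
both numbers are recomputed by `scripts/acceptance.py` and the test
suite. The solver cross-validation uses 100 random graphs of 5–100 nodes
and the brute-force feature oracles run on ~1000 graphs of up to 8 nodes
— sizes at which exhaustive enumeration is exact and fast.

## Numerical choices and limitations

* Steady-state entries are clipped to [0, 1] to remove solver round-off
  at the 1e−16 level; row sums are validated to 1e−8.
* The closed-form solve is O(n³) per network, fine for atlas-scale
  networks (n ≤ a few thousand); no sparse path is provided.
* Maximal-clique counts are exponential in the worst case; the cap turns
  pathological inputs into a clear error instead of a hang.
* Min-max normalization is per network: GFS values are comparable across
  nodes within one network, and between two networks only through the
  shared [0, 1] scale, which is exactly how the differential ranking
  uses them.
* The NNLS weight fit treats the external score as node-aligned; it does
  not model subject-level variation.
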