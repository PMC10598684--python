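# Methods

## The model

`graphtexture` transfers the gray-level co-occurrence matrix (GLCM) and its
Haralick-style summary statistics from images to node-weighted graphs. The
analogy is: node weight ↔ pixel intensity, graph edge ↔ pixel adjacency.
Given a simple graph G = (V, E) with unweighted edges and one scalar weight
w_i per node, the pipeline is

1. **Discretize** continuous weights into Ng ordered levels 1..Ng;
2. **Count** the co-occurrence matrix C, where C_ij is the number of times a
   node of level i shares an edge with a node of level j;
3. **Normalise** to the joint probability matrix p(i, j) = C_ij / ΣC, with
   marginals px, py and moments μx, μy, σx, σy over the integer level
   values;
4. **Summarise** p with twelve texture features (energy, contrast,
   correlation, variance/"sum of squares", inverse difference moment,
   entropy, max probability, autocorrelation, homogeneity, dissimilarity,
   cluster shade, cluster prominence).

First-order graph summaries (degree statistics, diameter, density) are blind
to any permutation of node weights; the texture features are exactly the
second-order information those summaries miss.

### Counting conventions

* **Undirected** graphs: every edge contributes both ordered pairs
  (level_u, level_v) and (level_v, level_u), the symmetric-GLCM convention,
  so C is symmetric and sums to 2|E|. On 4-neighbourhood grid graphs this
  makes C identical to the symmetric image GLCM summed over unit offsets
  (0, 1) and (1, 0), which is verified against scikit-image in the test
  suite. The factor of two cancels under normalisation.
* **Directed** graphs: each edge contributes one source→target pair; the
  total is |E|. Requesting directed counting on an undirected graph is an
  error (the orientation would be arbitrary); the reverse direction
  symmetrises.
* An optional per-edge categorical label (e.g. activation vs repression)
  restricts counting to matching edges, so one regulatory network yields
  separate matrices per interaction type.
* Levels absent from the graph still occupy their row/column of the fixed
  Ng×Ng matrix — contrast-type features depend on level spacing.
* Self-loops are rejected at validation (a diagonal self-pair would be
  ambiguous between one and two counts), duplicate edges are removed with a
  warning, and isolated nodes are retained but contribute nothing. A graph
  with no usable edges is an error, not a zero matrix.

### Discretization

Three monotone schemes map real weights to levels 1..Ng (default Ng = 4,
the value used throughout the validation studies):

* **equal** — Ng equal-width intervals spanning [min, max]; bins are
  left-closed/right-open with the top bin closed, so a value on an interior
  boundary joins the upper level.
* **quantile** — cut points at type-7 (linear-interpolation) sample
  quantiles, giving equal bin counts up to ±1 on distinct data; a value
  equal to a cut joins the *lower* level, so all copies of a tied value
  share one level.
* **kmeans** — exact 1D k-means solved by dynamic programming over the
  sorted unique values (optimal 1D clusters are contiguous), so the fit is
  deterministic and globally optimal in within-cluster sum of squares; the
  test suite checks this against brute-force partition enumeration. Values
  are assigned to the nearest cluster centre, midpoint ties breaking toward
  the lower level.

The two closure conventions differ deliberately: equal-width slicing is
conventionally right-open, while the lower-closure for quantiles is what
keeps tied values in one group. Feature values can depend on this choice;
bit-exact agreement with other implementations' binning is not a goal.
Values outside the fitted range clamp to the boundary level with a warning.
Constant inputs collapse to a single level with a warning.

### Feature definitions and degenerate cases

All sums run over the integer level values i, j = 1..Ng (1-based; a zero
level never occurs, so the cluster shade/prominence sums cover exactly the
occupied index range). Entropy uses the natural logarithm by default
(configurable), with 0·log 0 = 0. Variance ("sum of squares") is taken
about μx, the standard Haralick choice.

Correlation, (Σ ij·p − μxμy)/(σxσy), is undefined when a marginal is
degenerate; it is returned as NaN — a flagged value, not an exception — and
a tolerance of 1e-10 on σ catches marginals degenerate up to floating-point
rounding. Group scaling excludes NaNs from its statistics and preserves
them.

For comparing feature sets across groups of graphs, per-feature min-max
scaling to [0, 1] is the default (z-scoring is available); features with
zero range across the group map to 0 and are flagged.

## Synthetic generators

The generators are first-class, tested code: they define the controlled
conditions under which the metrics are validated.

### Fitness landscapes

Landscapes live on the L-locus biallelic genotype hypercube (2^L genotypes,
L·2^(L−1) Hamming-distance-1 edges; "4 allele" landscapes have 16 genotypes
and 32 edges, 5 loci give 32 and 80).

* **additive**: fitness(g) = base + Σ effects_k·g_k. Default effects are
  i.i.d. magnitudes uniform(0.05, 0.3) with random sign — small multi-locus
  effects of either direction, a realistic smooth landscape.
* **eggbox**: base + height·parity(#1-alleles); exactly two fitness values,
  every mutation alternates between them, so the co-occurrence diagonal is
  empty under any discretization with Ng ≥ 2 and texture correlation is −1.
  Under 4-level equal binning only levels 1 and 4 are occupied — the
  landscape "collapses" to the anti-corner cells.
* **House of Cards (HOC)**: i.i.d. uniform(0,1) fitness per genotype, the
  null model.
* **NK**: each of N loci contributes a uniform(0,1) table value indexed by
  its own allele and those of its K neighbours (adjacent with wraparound,
  the classic convention; a random-neighbourhood mode is available behind a
  flag); fitness is the arithmetic mean of contributions. K = 0 is exactly
  additive; K = N−1 decorrelates neighbours like HOC.

**Roughness:slope** is implemented as the RMS residual of the best
least-squares additive fit divided by the mean absolute fitted locus
effect — the standard ruggedness baseline in the fitness-landscape
literature. It is exactly 0 for additive landscapes and NaN (undefined)
when the fitted slope is zero; notably the eggbox's parity symmetry forces
every fitted effect to zero, so its ratio is undefined rather than large.

### Modular gene networks

A planted-partition (stochastic block model) generator. The default is four
modules of sixteen genes with within-module edge probability 0.6; the
between-module probability is either given or solved numerically (Brent's
method on the closed-form expected planted modularity) to hit a target Q.
The high-modularity benchmark used throughout the sensitivity studies
targets Q = 0.7 and assigns module index + 1 as each gene's expression
level, i.e. four clusters with four associated levels. Sampling retries
until the graph is connected (bounded retries), and the achieved Q of the
planted partition is always reported alongside the graph. Newman
modularity Q = Σ_c [e_c/m − (d_c/2m)²] is implemented directly and
cross-checked against networkx's community modularity.

### Noise and label baselines

* **Uniform noise** adds u_i ~ Uniform(−aR, +aR) per node, with R the
  original weight range; the amplitude is parameterised as the fraction a
  of the range so that a = 1 is noise as large as the signal span.
* **Permutation** shuffles the weights across nodes (multiset preserved);
  **bootstrap** resamples each weight with replacement. Neither touches the
  topology.

In the noise-sensitivity study (50 benchmark graphs, amplitudes a ∈
{0, 0.5, 2}), feature means converge toward the permuted-label baseline as
a grows. Two features — variance and cluster shade — are driven almost
entirely by the level *marginal*, which permutation preserves exactly; their
noise-free means already sit within one baseline standard deviation of the
permuted mean, so there is no displacement to converge from and the tests
require monotone convergence only of the features displaced by more than one
baseline SD (the other ten), while the marginal-driven pair must stay within
a few SDs. The sensitivity ranking is measured as the deviation of the
noisy mean from the noise-free mean, normalised by the original-to-baseline
gap: contrast and correlation are the most robust features by this measure,
cluster prominence among the most sensitive.

### Correlated expression

Expression replicates on a fixed wiring diagram are drawn from a zero-mean
multivariate normal whose correlation between genes i and j is ρ^d(i,j),
with d the shortest-path distance — adjacent genes correlate at ρ and the
correlation decays with network distance. The matrix is repaired to the
nearest positive semi-definite correlation (eigenvalue clipping, diagonal
rescaled to 1) when needed. This is a deliberately simple covariance rule;
only the qualitative behaviour is asserted: mean texture correlation after
4-level quantile discretization increases monotonically in ρ over
{0.2, 0.4, 0.6, 0.8} (100 replicates per ρ on the 64-gene benchmark
wiring).

## Problem sizes and numerical choices

The validation studies use: 200 random graphs (≤20 nodes, ≤6 levels) for
the brute-force counting oracle; 50 random 8×8 grids against the
scikit-image GLCM oracle (agreement to 1e-9); 10 landscapes per type (L=4,
Ng=4 equal) for the type-ordering study; 50 seeds for the noise study; 100
expression replicates per ρ; and 100 NK landscapes per K ∈ {1, 2, 3} at
N = 5. These sizes give stable orderings across seeds while keeping the
whole suite fast.

Probability matrices sum to 1 within 1e-12. All stochastic operations take
explicit seeds (numpy `default_rng`); derived seeds stay below 2^31. The
exact 1D k-means makes the `seed` argument of that fit inert — it is
accepted for interface symmetry.

## What the synthetic data does and does not show

The generators reproduce the *structural* situations the metrics are meant
to distinguish — alternating vs smooth vs random fitness surfaces, modular
label structure vs randomized labels, distance-decaying expression
correlation. They do not emulate real measurement error models, long-tailed
expression distributions, hub-dominated protein-interaction degree
distributions, or curated pathway topologies; passing these studies shows
the metrics behave as designed on controlled structure, not that any
particular biological classification will succeed. Applying the features to
real networks still requires choosing subnetworks and discretization levels
with care — the features are, by design and like their image ancestors,
sensitive to both.

## Known limitations

* Only distance-1 neighbourhoods (the image offset-1 analogue); no
  edge-weighted graphs, multigraphs or hypergraphs.
* The remaining classical Haralick features (sum average, sum/difference
  entropy, information measures of correlation) are not implemented.
* Texture correlation is undefined on graphs whose discretized labels are
  constant; downstream group scaling skips such entries.
* The expression simulator's ρ^distance covariance is a stand-in for more
  mechanistic co-expression simulators; its monotone ρ→texture-correlation
  trend is the only calibrated claim.
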