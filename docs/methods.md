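# Methods

This note records the models implemented in `phylobeta`, the conventions
and defaults chosen where the underlying definitions leave room, and what
the synthetic-data experiments do and do not demonstrate.

## Trees and transformations

A `PhyloTree` is a rooted tree whose every non-root node carries a finite
branch length ≥ 0; branches are attached to child nodes and the root
carries no branch. Tip labels are unique non-empty strings; at least two
tips are required. A tree counts as ultrametric when all root-to-tip path
lengths agree within a relative tolerance of 1e-9.

Patristic distances are computed in a single postorder pass: two tips
whose subtrees first meet at node u are d_ij = depth_i + depth_j −
2·depth_u apart. The same pass yields the shared-depth (MRCA-depth) matrix
V used as the Brownian trait covariance structure. The test suite checks
both against independent root-path enumeration.

**Pagel's λ transform.** For an ultrametric tree of depth T, every
internal node at height h above the root moves to λ·h while tips stay at
T. λ = 1 is the identity; λ → 0 approaches a star phylogeny. The
transform refuses non-ultrametric input rather than approximating — on a
non-ultrametric tree "keep the tips in place" is ill-defined — and
rejects λ outside [0, 1].

**Random polytomy resolution.** A polytomy over k child subtrees is
replaced by a uniformly random rooted binary expansion, built by
sequential attachment: subtrees are inserted one at a time onto an edge
chosen uniformly among the 2m−1 edges of the partial resolution
(including its root edge), which makes each of the (2k−3)!! rooted shapes
equally likely; the suite verifies uniformity over the 15 shapes of a
four-way polytomy with a ±3 s.e. band at 15,000 seeds. Inserted nodes get
branch length 0, so patristic distances and total tree length are exactly
conserved; consequently, across random resolutions only the
branch-sharing metrics (PhyloSor, UniFrac) can vary, and the distance-
based metrics' resolution confidence intervals have zero width by
construction. This is a deliberate choice: it isolates the sensitivity of
the branch-sharing metrics to resolution rather than confounding it with
arbitrary assignments of length to invented branches.

## Beta-diversity metrics

Definitions are given in the README. Conventions that matter:

- A branch "belongs" to a community iff at least one of the community's
  tips descends through it (equivalently, it lies on some tip's root
  path).
- UniFrac is the unique-branch-length fraction. (A descendant-count
  weighted variant exists in the literature; the branch-fraction form is
  the one whose worked-example values this package reproduces.)
- Species shared between the two plots participate in Dnn/Dpw/Rao sums
  with distance 0 to themselves; they are not excluded. This matches the
  source implementations of these metrics, but it means the distance
  metrics respond to species overlap as well as to phylogenetic
  structure (see the caveats under the gradient simulator below).
- Presence mode sets f_i = 1/n, so every presence-weighted metric is the
  equal-abundance special case of its weighted form; Rao's D ≡ Dpw′/2
  algebraically on every input.
- Dnn presence mode pools nearest-neighbour distances over both plots
  with denominator n₁ + n₂; the abundance form averages the two
  f-weighted sums (divides by 2). The two agree when abundances are equal
  and n₁ = n₂; how to pool when n₁ ≠ n₂ is not uniquely fixed by the
  definitions, and the pooled/2 convention is this package's documented
  choice.
- On an exact star tree PhyloSor reduces to the classical Sørensen
  similarity, and Dnn = Dpw = 2T for disjoint plots; the suite asserts
  both, along with equivalence of all eight metrics to a naive
  root-path implementation on 200 random small instances at 1e-10.

## Trait evolution and phylogenetic signal

**Ornstein–Uhlenbeck simulation** uses the exact transition along each
branch of length t: child = parent·e^(−αt) + θ(1 − e^(−αt)) + ε with
ε ~ N(0, σ²(1 − e^(−2αt))/(2α)); the root starts at θ. There is no Euler
discretisation, so results are exact for any branch length. Defaults
follow the sweep's design grid: α ∈ [0.2, 0.99], θ = 0, σ = 0.1. A
separate Brownian sampler (child = parent + N(0, σ²t)) is provided;
α = 0 is rejected rather than treated as a limit.

**Blomberg's K** is computed in closed form with V the shared-depth
matrix: K = (MSE0/MSE) / [(tr V − n/ΣV⁻¹)/(n−1)], where the mean is the
GLS (phylogenetic) estimate, MSE0 the ordinary and MSE the
V-weighted mean square of the residuals, solved via Cholesky
factorisation. K = 1 exactly on a star tree; the suite checks agreement
with an independent dense-matrix evaluation and a mean of ≈ 1 (band
0.85–1.15) over 500 Brownian replicates on a 64-tip tree. K > 1 indicates
relatives resemble each other more than Brownian motion predicts; K < 1
less.

**Trait dendrograms** cluster species by absolute trait difference
(Euclidean distance in one dimension; the package's experiments use a
single trait) with UPGMA linkage by default (complete and single are
available). Tip depth is merge height / 2, so the cophenetic (patristic)
distance between two tips equals the height of the merge that joins them,
and the dendrogram is usable by every beta-diversity metric.

**Signal sweep.** `signal_sweep` simulates 10× the requested number of
trait datasets with α cycling over the grid, computes K for each, keeps
`n_datasets` (default 60) at evenly spaced ranks of K so the retained set
spans the realised range, and for each retained dataset computes
functional beta diversity on the trait dendrogram for every plot pair and
records the R² of the regression of functional on phylogenetic beta per
metric. Everything is reproducible from one seed.

## The worked-example fixture

`scenario_fixture()` builds the 16-tip balanced ultrametric tree with all
branch lengths 1 (depth 4), cherries (t1,t2)…(t15,t16), and four
presence-absence community pairs: A = one four-species clade per root
half (deep basal turnover; any right-half clade is equivalent, one is
fixed for determinism), B = sister four-clades, C = cherry mates split
across the whole tree, D = cherry mates within one half. Every pair has
complete species turnover. The acceptance suite recomputes all six
presence-absence metrics for every scenario at λ ∈ {1, 0.75, 0.5, 0.25,
0.001} and checks them cell-by-cell against the worked-example table (to
printed precision for λ ≥ 0.25, where the values are exact rationals;
within 1e-3 at λ = 0.001, where a star phylogeny is approached).

## The gradient community simulator

`simulate_gradient` emulates a network of forest plots along a rainfall
gradient. Defaults: 96 plots, 446 species, 61,965 individuals in total,
latitude 13.2–15.2° at constant longitude 75°E, altitude 55–1060 m,
annual precipitation 776–8340 mm.

- **Phylogeny**: a birth–death tree (birth 1.0, death 0.25 per unit time)
  conditioned on the species count, run one extra exponential waiting
  time past the final speciation so no terminal branch is zero, then
  rescaled to depth 10 time units and snapped exactly ultrametric. Depth
  10 makes the OU grid α ∈ [0.2, 0.99] span weak to strong mean reversion
  (αT from 2 to ~10).
- **Niches**: each species gets a precipitation optimum evolved by
  Brownian motion on the tree and rescaled linearly to the precipitation
  range (`mode="conserved"`); `mode="labile"` shuffles the optima across
  tips, destroying phylogenetic niche structure while leaving the
  species-level gradient intact.
- **Environment**: plots are evenly spaced in latitude; precipitation
  rises monotonically along the line with an exponential (orographic-
  style) profile of shape parameter 5, so environmental distance is
  correlated with, but not collinear to, geographic distance. Altitude is
  drawn uniformly and does not enter assembly — its Mantel correlation is
  a negative control.
- **Assembly**: a plot's individuals (total ÷ n_plots each, remainders to
  the first plots, so the total is met exactly) are drawn multinomially
  with species weights exp(−Δ²/2b²), Δ the plot-precipitation minus
  species-optimum gap and b the niche breadth, default 1250 mm (≈ 1/6 of
  the gradient span).

With conserved niches, the Mantel correlation of Dpw with precipitation
difference exceeds the one with geographic distance in ≥ 90% of simulated
worlds (checked over 50 seeds at 24 plots × 60 species). Shuffling the
optima (labile mode) removes most — more than half — of that systematic
preference but not all of it: because shared species contribute distance
zero, Dpw carries a species-overlap component that tracks the
precipitation kernel no matter where the optima sit on the tree. The
residual preference is a property of the metric's convention, not of
niche evolution, and is asserted as such in the tests.

**Sweep experiment configuration.** The K-versus-R² experiment uses a
dedicated turnover-dominated configuration: 24 plots × 60 species,
645 individuals per plot, a linear precipitation profile and niche
breadth 100 mm. The reason is diagnostic: when neighbouring plots share
most of their species, any trait's functional beta correlates strongly
(R² ≈ 0.8) with phylogenetic beta through that shared-species channel —
comparing Brownian traits with tip-shuffled copies shows no R² gap — so
the effect of phylogenetic signal is unmeasurable. With near-complete
turnover between plots, both beta diversities are driven by
between-species distances and the link appears: Spearman ρ(K, R²) is
positive for PhyloSor, UniFrac, Dnn and Dnn′, with the retained 60
datasets spanning at least a five-fold range of K. Problem sizes here
(and the 24 × 60 Mantel worlds above) are the package's chosen
desk-scale defaults for its own experiments; all machinery runs at the
full 96 × 446 default scale as well.

## What the synthetic data does not show

The gradient simulator reproduces the *form* of the field analyses
(Mantel tables with resolution confidence intervals, metric correlation
matrices, PCA loadings), not the numerical results of any particular
field dataset: real floras have non-random tree shape, spatially
autocorrelated environments, dispersal limitation and detection error,
none of which are modelled. Passing tests demonstrate internal
correctness of the metrics and the qualitative behaviour of the
experiments under the stated generative model, not effect sizes to be
expected in empirical systems. The trait experiments use a single
continuous trait; multi-trait functional beta diversity with conflicting
trait structures is out of scope.

## Numerical conventions

- Mantel tests: Pearson r over upper-triangle vectors; the null permutes
  rows and columns of the second matrix simultaneously; p-values carry
  the +1 correction, so the minimum attainable p is 1/(1 + n_perm);
  permutations tied with the observed statistic count as at least as
  extreme (tolerance 1e-12). Exhaustive mode enumerates all non-identity
  label permutations for small matrices. Default n_perm = 999, one-sided
  "greater"; two-sided and "less" available.
- PCA of metric outputs: bounded similarities (PhyloSor) are converted to
  dissimilarities as 1 − s; each metric vector is z-scored; axes come
  from the eigendecomposition of the correlation matrix (metric scales
  are incommensurate, so covariance would be dominated by the unbounded
  metrics). Loading signs are arbitrary; the largest-magnitude loading of
  each component is made negative, a fixed convention for comparability.
- Geographic distances are haversine great-circle distances on a 6371 km
  sphere; at the default 2° extent, projection choices are negligible.
- Abundance zeros mean absence; there are no pseudo-counts. A species
  present in a community table but absent from the paired tree is a hard
  error, not a silent drop.
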