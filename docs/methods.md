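# Methods

`pitmud` re-implements the statistical core of a pit-mud microbial
biogeography analysis as a tested library: given an OTU count table, a
rooted phylogeny over the OTUs, a taxonomy, and per-sample metadata
(cellar-age group Aa–Ad, longitude group La–Ld), it computes diversity
gradients, a phylogenetic null-model partition of community assembly,
co-occurrence network topology and stability, and age biomarkers.  A
synthetic-data generator with exposed ground truth stands in for the
original multi-study meta-dataset, so every stage is testable offline.

## Data model and preprocessing

The universal currency is a taxa × samples `CommunityTable` (counts or
relative abundances).  Rarefaction subsamples each sample to a common
depth **without replacement** (multivariate hypergeometric), so column
sums are exact and the scheme is seed-reproducible; samples below the
depth are dropped with a warning, mirroring the usual minimum-count
filter.  Taxonomic aggregation pools taxa unassigned at a rank into an
explicit `unassigned` row so per-sample totals are conserved (testable
to 1e-9).  Taxa absent from the phylogeny are excluded from tree-based
stages only.  A freshly closed relative table has columns summing to 1;
after prevalence filtering the columns are sub-closed, so the class
invariant is "column sums ≤ 1" and exact closure is the postcondition of
`to_relative`.

## Diversity

Alpha diversity per rarefied sample: bias-corrected Chao1
(S_obs + F1(F1−1)/(2(F2+1)), well-defined when F2 = 0), Shannon in nats,
Pielou H/ln(S_obs).  Trends against cellar age use OLS with a two-sided
t-test on the slope; when numeric ages are missing, age groups map to
representative ages {Aa: 5, Ab: 30, Ac: 100, Ad: 350} years
(configurable) — the groups span <10, 10–50, ~100 and ~300–400 years,
and these midpoints put them on a sensible temporal axis.

Beta diversity: Bray–Curtis on relative abundances and **normalized**
weighted UniFrac, Σ_b l_b|A_b−B_b| / Σ_b l_b(A_b+B_b) over branches b,
which is bounded in [0,1] and reduces exactly to Bray–Curtis on a star
tree with unit branches (a test).  NMDS uses non-metric stress
minimization with 20 seeded restarts of 500 iterations, reporting
Kruskal stress; coordinates are centred.  PERMANOVA is multi-term
**sequential (Type-I)** on the Gower-centred distance matrix, term order
(age, longitude) by default, p-values by free permutation of sample
labels; term r² fractions plus the residual sum to 1 by construction.
The one-way pseudo-F is cross-checked against scikit-bio's PERMANOVA in
the tests, and p-value uniformity under a label-permutation null is
verified by a KS test.

Within-group dissimilarity summaries (the "communities converge with
age" analysis) use all within-group pairwise distances per group, with
Kruskal–Wallis across groups, pairwise Mann–Whitney tests, and an OLS
trend of group medians against representative age.  Group taxon overlap
("endemic taxa" Venn analysis) defines presence as nonzero aggregated
abundance in ≥ 1 sample of the group and returns the full
inclusion–exclusion partition.

## Community assembly (βMNTD / βNTI)

Between-community mean nearest taxon distance, abundance weighted:

    βMNTD(k,m) = 0.5 [ Σ_i f_ik · min_{j∈m} Δ_ij  +  Σ_i f_im · min_{j∈k} Δ_ij ]

with f renormalized over the taxa present in each sample and Δ the
patristic (cophenetic) distance; a shared taxon is its own nearest
relative at distance 0.  The null model shuffles taxon identities across
the phylogeny's tips — implemented as a joint row/column permutation of
the cophenetic matrix — preserving every sample's abundance vector and
richness.  βNTI is the z-score of the observed βMNTD against `n_null`
(default 999) such shuffles.  Classification: βNTI > 2 heterogeneous
selection, βNTI < −2 homogeneous selection, otherwise (boundary
included) stochastic; pairs with a degenerate null (sd = 0, e.g. all
present sets identical) are flagged and excluded from fractions.
Per-group process fractions use within-group pairs only.  The
within-sample analogue (standardized MNTD) is exposed as `ses_mntd`.

Correctness is anchored three ways: a brute-force cophenetic enumeration
oracle, exhaustive tip-permutation enumeration on a 5-taxon toy, and R's
`picante::comdistnt` (abundance weighted), which matches to machine
precision.  The implementation shares one sequence of null shuffles
across pairs, so results are independent of pair evaluation order and
chunked (parallel) evaluation merges deterministically.

## Co-occurrence networks

Edges are Spearman correlations over samples (average-rank ties,
asymptotic t p-values) retained iff |rho| > 0.7 **and** p < 0.01, both
strict, with no multiple-testing correction — the raw cutoff convention
of this literature (a Benjamini–Hochberg toggle exists but defaults off).
Before screening, taxa are prevalence-filtered (present in ≥ 20% of the
group's samples, mean relative abundance ≥ 0.01%) to curb rank-tie
artifacts at rarefied depth.  Networks are built per age group at the
OTU level and annotated by class for the focal-class (intra/inter ×
positive/negative) decomposition.

Topology: node/edge counts, average (weighted) degree, density,
unweighted clustering coefficient, path length and diameter on the
largest component, connected components, the negative:positive edge
ratio as a percentage, and modularity from the best of 10 seeded Louvain
runs on |rho| weights (> 0.4 is read as "modular structure").

Robustness removes a fraction q of nodes uniformly at random (grid step
0.05, 100 replicates), then iteratively deletes nodes left with no
neighbours (secondary extinction); the score is the trapezoidal area
under the mean remaining-fraction curve.  On a complete graph the curve
is deterministic and the score ≈ 0.5; hub-dominated graphs fall below
it.  Natural connectivity is exposed as an alternative stability index.
Vulnerability is max_i (E − E_i)/E over single-node removals, with E the
global efficiency.

## Biomarkers

`rf_select` regresses OTU relative abundances on the ordinal age group
(1–4; numeric years optional) with a random-forest (100 trees,
max_features = p/3, the regression-forest convention).  Taxa are ranked
by permutation importance from a forest on all samples; nested top-n
subsets on a Fibonacci-like ladder (1, 2, 3, 5, 8, … , p) are re-fit
under 10-fold × 5-repeat cross-validation, and the subset with least
mean CV MSE is selected (ties toward fewer taxa).  Internally taxa are
processed in sorted-id order so results do not depend on input ordering.

`lefse` scales relative abundances by 1e6 (abundance per million — this
fixed factor is what places strong planted enrichments above the
conventional threshold), screens features by Kruskal–Wallis (p < 0.05),
then runs 30 bootstrap rounds on two-thirds of each group's samples: a
one-dimensional Fisher LDA (within-class scatter shrunk by λ = 1e-6·I
against singularity; unit-norm direction) is fit over the surviving
features, and a feature's effect is the absolute difference between the
two most extreme group means of its projected values (coefficient ×
feature), averaged over bootstraps; the reported score is
log10(1 + effect) and biomarkers exceed 4.  There is no subclass stage
(the design has none).  The procedure is validated by planted-enrichment
recovery and by label-permutation false-positive control rather than
bit-compatibility with any particular reference implementation, whose
effect-size composition varies.

The "error" minimized in the forest's CV curve is MSE under the ordinal
regression (a reasonable reading where a misclassification count would
require a classification forest instead).

## Synthetic data

`simulate_tree` draws a birth–death phylogeny (birth 1.0, death 0.5)
conditioned on the tip count; a Brownian trait (σ² = 1) evolved along it
provides the phylogenetically conserved niche axis.  Communities arise
per sample from a log-normal metacommunity profile bent by
(i) a Gaussian fitness kernel exp(−s(trait − E)²) around an
environmental optimum E — one shared extreme-quantile optimum per group
under homogeneous selection, per-sample optima spread over the trait
range under heterogeneous selection, none under neutral drift;
(ii) logistic succession multipliers that hand dominance from an early
clade to a late clade across log10(age), crossing near 50 years (in
succession scenarios the homogeneous optimum sits at the late clade's
mean trait, so selection and succession point the same way);
(iii) planted biomarker fold-changes.  Per-sample lognormal drift noise
and a fitness-biased occupancy draw (a subset of the pool is present in
any one sample) create the presence turnover that real communities show;
counts are Dirichlet-multinomial at depth 10,000 with concentration
equal to the depth, i.e. roughly twice multinomial variance.

The extreme-quantile optimum matters: Brownian traits near the *median*
occur all over the tree, so a median optimum selects a phylogenetically
scattered set and produces no clustering signal; extreme trait values
concentrate in the few clades that drifted far.

Two scenario families are preset and fixed:

* `regime_scenario(regime)` — single-regime recovery conditions:
  occupancy 0.10, drift σ 0.7, metacommunity σ 0.3, strength 1.0
  (homogeneous) / 2.0 (heterogeneous).  The sparse, mildly-drifting
  community maximizes the number of unshared but phylogenetically
  clustered taxa per pair, which is what the βNTI z-score can see: with
  ~30 taxa per sample the attainable |z| is bounded by the count of
  unshared contributions, and denser or noisier settings dilute the
  signal below the ±2 band.
* `succession_scenario()` — the full 4 × 4 design with succession
  multipliers (amplitude 6, rate 2.5) and regimes shifting from neutral
  (Aa) through weak to strong homogeneous selection (Ad), reproducing
  both temporal signatures at once: within-group Bray–Curtis falls with
  age (selection concentrates communities) and the dominant clades swap.

`simulate_correlated_table` plants block correlation through a latent
Gaussian copula (cross-block correlation 0): latent normals map
monotonically to log-normal abundances, so Spearman structure survives;
block taxa sit at a uniform, comfortably-abundant baseline because taxa
near the counting floor lose rank fidelity to zero-count ties.

What the generator does **not** emulate: compositional coupling beyond
closure, chimeras/primer artifacts, spatial autocorrelation between
regions, archaea, or real taxon names.  Passing tests show the methods
recover known structure under these idealized conditions; they do not
certify performance on real meta-analysis data, where cross-study batch
effects dominate.

## Numerical choices and degenerate inputs

* Strict inequalities everywhere the conventions state them: |βNTI| = 2
  is stochastic; rho = 0.7 is rejected; modularity 0.4 is "not modular".
* Null sd = 0 pairs are flagged, not classified; constant taxa are
  skipped by the correlation screen; empty graphs yield zero reports
  with warnings; an all-filtered LEfSe returns an empty result, not an
  error.
* UniFrac goes through scikit-bio, whose driver truncates float counts:
  samples are closed and rescaled to integer reads at 1e-12 resolution
  (the normalized metric is per-sample scale invariant), bounding the
  induced error near 1e-11.
* Rarefaction, null shuffles, Louvain, NMDS restarts, forests and
  bootstraps all consume explicit seeds; identical seeds give identical
  outputs, including across chunked βNTI evaluation.
* Problem sizes in tests and the acceptance script are desk scale (300
  taxa, 3–6 samples per design cell, 10,000 reads), the package's
  standing choice for examples and validation runs.

## Known limitations

* βNTI magnitudes scale with per-sample richness; at desk scale the
  homogeneous-selection signal needs the calibrated sparse presets
  above, whereas survey-scale data (thousands of OTUs) separate readily.
* Sequential PERMANOVA r² depends on term order, as in any Type-I
  decomposition; the default order (age before longitude) is a
  configuration knob.
* The robustness metric is fraction-remaining with secondary
  extinctions; other robustness definitions (e.g. natural-connectivity
  decay) are exposed but not the default, and curves from different
  definitions are not comparable.
* Spearman co-occurrence ignores compositionality; the screen is the
  field's convention, not an endorsement against SparCC-style
  estimators, which are out of scope.
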