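# Methods

## Scope and data model

`chronocell` analyzes droplet scRNA-seq UMI count matrices of
unicellular algal cultures under contrasting nutrient regimes. The
in-memory unit is a sparse cells × genes integer matrix with per-cell
barcodes and sample labels and per-gene IDs and organelle class
(`nuclear` / `mito` / `chloro`); on disk the 10x triplet layout is
used (MatrixMarket + barcode/feature tables, gzip transparent, genes
as rows by convention, 1-based coordinates). Gene programs are plain
(set, gene) TSVs; diurnal peak phases are a (gene, hours) TSV on the
half-hour grid 0.0–24.5 h with dawn at 0. Organelle membership is an
explicit per-gene annotation rather than an ID-prefix heuristic, so
chromosome naming conventions never matter.

## Preprocessing

Fixed stage order: filter → normalize → select variable genes → scale
→ PCA.

- **QC filter.** Cells with fewer than 100 detected genes or fewer
  than 300 UMIs are removed ("fewer than" read strictly: a cell with
  exactly 100 genes and 300 UMIs is retained). The filter is
  idempotent and never touches the gene axis.
- **Normalization.** value = ln(1 + 10,000 · count / cell total).
  Zero counts stay exactly zero; for every cell
  Σ expm1(value) = 10,000 up to float tolerance — this conservation
  identity is asserted in the tests.
- **Variable genes.** Genes are ranked by the residual of log10
  variance around the median of their mean-expression bin (up to 20
  equal-frequency bins). This binned-dispersion statistic is seed-free,
  deterministic (ties broken by gene ID), invariant to cell order, and
  robust to single high-leverage genes, which defeated a polynomial
  mean–variance trend fit during development. Default n_top = 2,000.
- **Scaling and PCA.** Per-gene centering to mean 0 and population
  variance 1, clipping at ±10 (clipping is stated explicitly because
  it changes the PCA), zero-variance genes dropped. PCA uses the exact
  full-SVD solver, 20 components by default; fixtures verify agreement
  with a dense SVD oracle up to component sign.

## Clustering

Cells are linked to their k = 20 Euclidean neighbors in PC space; edge
weights are the Jaccard overlap of (self-inclusive) neighbor sets,
pruned below 1/15. Communities are found by Leiden optimization of RB
modularity with a resolution parameter (default 0.5) and a fixed seed;
labels are relabelled by decreasing cluster size. Cluster counts on
real data are seed- and data-dependent and are treated qualitatively.

## Module scores

All genes are placed into 24 equal-frequency bins by mean normalized
expression (mean computed as sum/n so dense recomputations agree
bitwise; ties broken by gene ID). Each set member draws 100 control
genes without replacement from its own bin, excluding the set itself —
the exclusion makes the score exactly equivariant: adding δ to the
members' values in one cell moves that cell's score by exactly δ. If a
bin is smaller than 100 the whole bin is taken; controls are pooled
across members with multiplicity (the pooled-mean and per-member
paired-mean variants correlate at r > 0.99 on realistic simulations;
pooled is the default). The score is the members' mean minus the
pooled controls' mean, per cell, deterministic given the seed.

Derived statistics:

- **positive fraction** per group, with strict positivity (score 0 is
  not positive) — the "actively dividing" readout when applied to the
  division program;
- **bimodality**: a two-component Gaussian mixture initialized at the
  25th/75th percentiles (fixed seed, single init) summarized by
  Ashman's D = |μ₁ − μ₂|·√(2/(σ₁² + σ₂²)); D > 2 declares two
  separated modes. Degenerate fits fall back to a tied-variance
  mixture and are flagged; exactly constant inputs skip the fit. On
  unimodal Gaussian data this estimator stays below 2 (D ≈ 1.2–1.9
  across seeds), on an equal mix of well-separated components it
  approaches the closed-form D of the true parameters.

## The molecular timetable

**Phase bins.** The half-hour phase grid is collapsed into 13
non-overlapping gene sets centered every other hour: bin 0 holds
phases {0.0, 0.5}; bin t (t = 2…24) holds {t−0.5, t, t+0.5}. Genes
peaking exactly on odd hours belong to no bin; bins 0 and 24 hold
different genes (0/0.5 vs 23.5/24/24.5) whose rhythms nearly coincide,
so their score columns should — and do — correlate strongly, a useful
internal control. All 13 bins are scored with a shared control seed so
columns are mutually comparable.

**Per-cell phase.** Three estimators are provided:

- `argmax`: center of the best-scoring bin, ties to the earliest;
- `circular_mean`: score-weighted circular mean with negative scores
  floored at 0 and the dawn bins merged;
- `timetable` (default): the signed score profile is projected onto
  the bin-center directions (0 h and 24 h averaged into one dawn
  direction, leaving 12 uniform directions, so the projection is an
  exact first-harmonic Fourier coefficient and constant offsets drop
  out), and the per-cell resultant vectors are recentered by a Taubin
  least-squares circle fit across cells before taking angles.

The recentering is the load-bearing choice. Because control genes are
matched on mean expression, the population-average rhythm is baked
into the matching: for a population with mean phase μ₀ and resultant
length R, every cell's expected resultant vector is
k(e^{iθ_c} − R e^{iμ₀}) — a common translation of the whole cloud.
Reading angles from the origin then inflates deviations from the crowd
phase by 1/(1 − R); at the concentration the package simulates
(κ = 4, R ≈ 0.86) this is a ~7× distortion that biases both floored
estimators by ~3 h of circular MAE. The translated cloud is still a
circle, so fitting the circle and measuring angles about its center
removes the bias (MAE ≈ 0.3–0.6 h under the same conditions). The
Taubin algebraic fit is used because the centroid-based Kåsa fit
under-corrects in noise, leaving a residual ±0.25 h repulsion.
`timetable` needs ≥ 8 rows for the fit; per-row use falls back to the
other estimators. Confidence is the radial distance over the mean
fitted radius (capped at 1) for `timetable`, the weighted resultant
length for `circular_mean`.

**Cluster-level heatmaps** are per-cluster means of the 13 columns,
with both dawn columns retained for display.

**Phase shift.** The shift between two groups of per-cell calls is the
circular mean difference wrapped to (−12, +12] h; significance comes
from permuting group labels on the absolute circular mean difference
(default 1,000 permutations, seeded, +1 correction). Undefined calls
are excluded; a group more than half undefined is an error, as are
groups under 30 defined calls.

## Circular pseudo-time

Ordered expression change around the diurnal cycle traces a closed
circle with no branches, so a circular parameterization is the minimal
sufficient trajectory model — deliberately replacing graph-learning
trajectory inference. Cells are projected onto the top-2 principal
plane of the 13-bin score matrix (default; a gene-space mode over
genes with mean normalized expression > 0.5 detected in > 10 cells is
also provided). The ring is recentered by the same Taubin circle fit —
under phase crowding the ring's center is offset from the data
centroid — and pseudo-time is the angle around the fitted center,
rescaled to [0, 24) h. Two gauge freedoms are fixed deterministically:
direction, by comparing rotation vs reflection resultants against the
timetable phase calls, and the zero point, by rotating the
division-signature weight (bins 12 and 14, floored at 0) onto 13 h —
the division program peaks at 12–14 h after dawn. Degenerate
(collinear) inputs are an error pointing to the score-space mode.

## Differential expression

Per-gene two-sided Wilcoxon rank-sum on normalized values between two
disjoint cell groups, restricted to genes detected in at least one
cell of either group (the gene universe matters because it sets the BH
denominator; no further detection filter is applied by default). With
both groups ≥ 20 cells the tie-corrected normal approximation is used,
below that exact enumeration; constant genes get p = 1 and a flag.
Benjamini–Hochberg adjustment across all tested genes; significance
only via adjusted P < 0.05. The reported log fold-change is the
natural log of the expm1-mean ratio with a 1e-9 pseudocount and does
not enter significance.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with full latent truth for recovery testing:

- **Cell phases** θ_c are von Mises on the 24-h circle, default mean
  6 h after dawn (cells crowd a few hours after subjective dawn) and
  concentration κ; κ = 0 gives a fully desynchronized culture. One
  sample may carry a constant phase delay (a slowed clock under
  deficiency).
- **Rhythmic genes** (default 20% of genes) get peak phases uniform on
  the half-hour grid and log-mean
  μ_g + A·cos(2π(θ_c − φ_g)/24), default amplitude A = 1.
- **Regulons**: each named gene set gains its log fold-change in all
  cells of its target sample. Regulon baselines are set to the drawn
  level minus the fold-change — deficiency-response genes are
  near-silent when replete and induced to typical levels, which also
  keeps per-cell depth nearly independent of condition (a regulon with
  typical baselines would inflate the starved sample's library size by
  ~10% and, through depth normalization, shift every other gene — a
  compositional artifact that swamped the DE false-discovery control
  until baselines were made realistic).
- **Division**: cells whose phase falls in [12, 14) h divide, plus a
  configurable fraction (scalar or per-sample) of out-of-window cells;
  dividing cells elevate a 50-gene division program by +3 log units
  (a strong burst, as replication machinery is in bursty use).
- **Mixture samples** draw each cell's regulon behavior 50/50 from two
  component samples, emulating an equal-density mixed library.
- **Counts** are negative binomial with shared dispersion α
  (var = μ + αμ², default α = 0.5; α → 0 is the Poisson limit),
  scaled by a log-normal per-cell size factor (sd 0.3). Gene baseline
  log-means are log-normal (sd 1) centered so the expected baseline
  depth matches `mean_umis_per_cell`; dropout emerges from low means
  with no explicit zero-inflation. The closed form
  E[e^{A cos(θ−φ)}] = I₀(√(κ² + A² + 2κA cos(μ₀−φ)))/I₀(κ) gives an
  analytic expected depth that the simulation matches within
  Monte-Carlo tolerance.
- **Determinism**: one seed; three sub-streams (gene structure, cell
  structure, counts) spawned from it; identical configs give
  bit-identical matrices.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the shared phase/regulon
factors, organelle transcripts (all genes are labelled nuclear), and
cell-cycle DNA-content structure beyond the division program. Passing
recovery tests on these simulations therefore demonstrates
correctness of the estimators under the stated generative model, not
robustness to every artifact of real droplet data.

## Study conditions used by the tests and the acceptance script

Scaled-down but structurally faithful sizes keep everything inside a
desk-scale compute budget: 1,500–3,000 genes (600 rhythmic in the
phase-recovery setting), 300–2,000 cells per sample, ~3,300 mean UMIs
per cell (matching typical droplet depth for this organism), NB
dispersion 0.5, amplitude 1.0, κ = 4 for phase-concentrated cultures
and κ = 0 for desynchronized ones, a +2 log-FC 100-gene iron regulon,
a 2-h injected clock delay, and division fractions of 0.30 (arrested)
vs 0.07 (control). Under these conditions the pipeline recovers
per-cell phases with ~0.3 h circular MAE, the injected delay within
[1.5, 2.5] h at permutation p < 0.01, division fractions within
±0.05, mixed-sample Ashman's D ≈ 10 vs < 2 for pure samples, Wilcoxon
type-I ≈ 0.05 with regulon recall ≈ 0.98 at empirical FDR < 0.1, and
circular pseudo-time rank association ≈ 0.99.

## Numerical and degenerate-input conventions

Phase arithmetic is mod 24 with differences in (−12, +12]; a modulo
that rounds onto the period maps back to 0. Circular association uses
rotation-minus-reflection resultants (r₊² − r₋²), which remain defined
for uniform marginals where moment correlations degenerate. All-zero
cells are flagged in QC with organelle percentages of 0 and rejected
by normalization; empty phase bins yield flagged NaN columns; all-bins
non-positive rows are flagged undefined by the floored estimator while
`argmax` still answers earliest-max; empty groups give NaN positive
fractions; an all-cells-fail QC filter, an empty post-intersection
gene set, and a degenerate trajectory plane are hard errors naming the
offending stage or input.

## Known limitations

Phase inference assumes the rhythmic program dominates the score
profile; division and deficiency programs share genes with the cycle
in real data (the diurnal and cell cycles are intertwined in this
organism), so real-data phase calls inherit that confounding. The
phase-shift test compares circular means only — it will not detect a
pure concentration change. Cluster counts are not portable across
seeds or data. The CLI's stage subcommands recompute the deterministic
upstream stages from the counts directory rather than reloading an
intermediate container; with fixed seeds the results are identical.
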