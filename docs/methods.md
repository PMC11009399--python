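# Methods

## The neutral community model

The package models plasmid (or plasmid-segment) dispersal with Sloan's
near-neutral community model for large microbial populations. The
regional pool assigns each entity a relative abundance `p`; local
communities assemble by immigration, so the local relative abundance of
an entity is approximately Beta(Nm·p, Nm·(1−p)) distributed, with `Nm`
(metacommunity size × immigration rate) the single free parameter.
Detection is thresholded at a relative abundance `d`, giving the expected
occurrence frequency

    f(p) = 1 − I_d(Nm·p, Nm·(1−p)),

computed with the regularized incomplete beta function
(`scipy.special.betainc`).

**Fitting.** `Nm` minimizes the sum of squared residuals between the
observed and predicted occurrence frequencies, on untransformed
frequencies (the convention of the occupancy-modelling literature).
The optimizer works in log10(Nm) on [−2, 12]: a coarse grid (0.1 dex)
brackets the basin and bounded Brent refinement runs inside ± one grid
step, which guarantees agreement with a dense grid search. `R²` is
`1 − SSres/SStot` about the mean observed frequency; it can be negative
for strongly non-neutral data and is reported as NaN when all observed
frequencies coincide. Per-entity 95% bands are Wilson score intervals for
the predicted frequency at the fitted number of samples. The Wilson
choice (over, e.g., Clopper–Pearson) is a design decision: it is
well-behaved at frequencies near 0 and 1, where most selected candidates
live.

**Detection limit.** `d` defaults to the minimum nonzero per-sample
relative abundance in the filtered matrix — the standard convention when
the true limit is unknown — and is overridable everywhere.

**Selection rule.** Two rules are implemented because both appear in
practice: the default "quantile" rule selects entities in the top 5% of
occurrence frequency *and* the top 5% of positive deviation from the fit
(deviation measured on the frequency axis); the "ci" rule selects
entities above 95% prevalence whose frequency exceeds the Wilson upper
band. On exchangeable data the quantile rule selects at most ~0.25% of
entities in expectation (the intersection of two 5% tails).

**Stratified fits and group comparison.** Fits run per disease state
(subsetting samples), per mobilization lifestyle (subsetting entities)
and per combination; `R²` ratios are reported against the healthy
stratum. Uneven group sizes are handled by subsampling the larger group
to the smaller one's size 1000 times and reporting the empirical
probability `(1 + #{R²_sub ≥ R²_small})/(1 + n_iter)`.

## Synthetic cohorts

The generator is the model's generative counterpart and supplies every
input with ground truth:

- **Regional pool:** log-normal(μ=0, σ=2) weights renormalized to the
  simplex — heavy-tailed, like observed plasmidomes.
- **Local communities:** Beta draws per the model, renormalized per
  sample; integer read counts multinomial at a per-sample depth drawn
  uniformly from 2×10⁴–8.6×10⁵ (the survey's 2–86 million-read depth
  heterogeneity, scaled down 100× so a cohort simulates in seconds).
  Coverage fractions follow a Poisson per-base model of the implied read
  depth.
- **Cohort composition:** disease labels at the survey proportions
  (1548 healthy / 339 IBD / 1035 GRD / 545 obese of 3467); continents at
  plausible four-continent proportions (0.45/0.25/0.25/0.05 — the exact
  continental split is not a published quantity).
- **Sequences:** random circular DNA with lengths from a two-component
  log-normal mixture (modes 3 kb and 30 kb, weights 0.8/0.2, σ = 0.15
  dex), matching the observed bimodal length distribution qualitatively.
  Shared blocks are copied into two or more plasmids with i.i.d.
  substitutions split evenly across copies, so a target identity `t`
  uses a per-copy rate (1−t)/2 (expected pairwise identity slightly above
  `t` due to coincident hits; within the ±2-point tolerance used
  throughout). Substitution-only mutation is the default so "identity"
  has a single unambiguous definition. A configurable fraction of copies
  straddles the linearization origin. Mobilizable lifestyle is
  Bernoulli(1027/11086); AMR carriage odds between lifestyles default to
  6.14.
- **Planted selection:** carriage probability of chosen segments is
  multiplied by a boost factor (capped at 1) within one disease group, by
  converting non-carriers at the top-up rate. This is one of several
  plausible non-neutral mechanisms (alternatives: fitness advantages,
  frequency floors); it was chosen because it directly realizes
  "more frequent within a group than neutrality predicts" without
  touching abundances. Recovery scenarios plant boosts in the GRD group
  (~30% of samples) on mid-frequency entities, where a saturating boost
  moves an entity into the joint frequency/deviation tail of its stratum.

What the generator does **not** emulate: read-level noise and mapping
error, chimeric assemblies, compositional coupling between plasmids and
their bacterial hosts, phylogenetic correlation among samples, and
annotation error. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to upstream
artifacts of real metagenome processing.

## Filtering

Deduplication keeps the larger of two plasmids when identity is strictly
above 95% and the alignment covers ≥ 95% of the larger one; qualifying
pairs are processed in decreasing order of the larger member's length
(ties by lexicographic id), which makes chains deterministic and
order-invariant. Presence requires coverage ≥ 70% (inclusive boundary;
the identity boundary is exclusive — both follow the wording "at least"
vs "above"). The depth cutoff is 1% of the lowest *present, nonzero*
abundance in the sample with the smallest read depth; cells below it are
masked as absent while abundances are retained for NCM means (masking
presence, not abundance, is a documented interpretation choice). The
length-distribution trough is the minimum of a Gaussian KDE on
log10(length) between the two largest modes, with small shoulder bumps
(< 5% of peak density, or troughs shallower than 20% of the lower peak)
not counted as genuine bimodality.

## Segment extraction

Circular sequences are doubled before alignment so origin-spanning
blocks stay contiguous; coordinates are reduced modulo the plasmid
length afterwards and offset duplicates collapsed. The production engine
is seed-and-extend: exact 16-mer seeds, diagonal chaining (band 32,
max seed gap 400 bp), ungapped X-drop extension (X = 20), and rescoring
of the extended region by global edit alignment (identity = matches /
alignment columns, gaps counting as columns). A full dynamic-programming
local aligner (linear gap penalty, match +1 / mismatch −3 / gap −4,
row-vectorized) provides an independent reference on small instances;
the steep mismatch penalty prevents the two doubled copies of a block
from being bridged through unrelated sequence, and the DP reference
doubles only one sequence per run for the same reason. Both engines trim
hit ends back to a run of four consecutive matches, so reported
boundaries reflect the homologous block rather than chance flanking
matches, and the ≥ 1000 bp length threshold is meaningful at the
boundary. Hits overlapping > 50% reciprocally on the same pair are
merged keeping the higher identity. Hits are kept only when the two
carrying plasmids occur in ≥ 2 samples (applied from the presence
matrix, not sequence counts). Clustering is greedy longest-first: a
segment joins the first cluster whose representative is within the
length-ratio bound (mutual coverage ≥ 90% of both lengths) and aligns at
≥ 80% identity. Supplementary parameterizations (min length 500 bp;
identity 90/95%) are plain arguments.

Known limitation: if two plasmids of nearly equal length (within the
32-column band) share a block whose flanking gap is under the 400 bp
chaining distance, the seed chains of the two doubled copies can merge
and the hit is discarded at the identity threshold rather than split.

## Network null model

The sample × segment incidence is randomized by 2×2 checkerboard swaps:
each attempt draws two occupied cells and flips the checkerboard if the
opposite corners are empty. Sampling occupied cells directly (rather
than random row/column pairs) keeps the acceptance rate near 50% in
sparse matrices, which is what lets a chain of 10 × (number of 1-cells)
attempts — the default, with every ensemble member a fresh chain from
the original matrix, seeded independently — mix well enough that
group-test p-values are uniform under label exchange (verified by the
calibration suite). Row and column sums are conserved exactly by
construction and asserted in tests. The swap kernel is numba-compiled
with an inline xorshift64* generator.

Statistics: group connectivity is the total edge weight among qualifying
pairs (same disease; same or specified continent pair), computed from
per-group carrier counts (Σ C(k,2) within a block, Σ k₁k₂ across); edge
significance compares each same-disease edge weight to its null
distribution; segment significance uses within-disease carrier pair
counts C(k,2). All empirical p-values are (1+b)/(1+n) — never exactly
zero — with BH-FDR per family. Obesity samples are excluded from
geography-stratified groups by default (configurable), reflecting their
single-continent origin in the survey design. Strength ratios
(within-disease vs between-disease edge weight sums) default to
per-capita normalization — each sum divided by the number of potential
partners of that kind — because raw sums conflate group size with
affinity; the raw mode is available. Infinite ratios (zero
between-strength) are reported but excluded from rank tests.

A note on permutation resolution: with n permutations the smallest
attainable p is 1/(n+1), so BH discovery of k true signals among N tests
at FDR α requires roughly n ≥ N/(kα). The planted-recovery scenario
(10 signals among 1010 segments, α = 0.1) therefore uses 2000
permutations; the survey-scale analogue (10,000) is the pipeline's
"paper mode" (`n_perm` setting), with 1000 the desk-scale default.

## Enrichment and comparative statistics

Hypergeometric enrichment uses the upper-tail probability P(X ≥ k) per
term, BH correction across terms, and filters results to gene ratio
(k/n) strictly above 0.1 and q below the analysis-specific level
(0.01 default). The background is all annotated entities of the same
kind in the same stratum; entities with no annotations remain in the
background size N (they can only make enrichment more conservative).
Odds ratios use the Haldane–Anscombe +0.5 correction when a cell is
zero, with two-sided Fisher exact p-values; an empty margin yields an
undefined (NaN) ratio. Length comparisons subtract the merged union of
mobility-gene intervals from mobilizable plasmid lengths before the
rank-sum test, so the comparison is not driven by the mobility backbone
itself.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen so the whole suite
exercises every claim in minutes: 200–300 samples, 300–1010 entities,
ensembles of 500–2000 permutations, 100 calibration replicates, and
constructed alignment cases of 1–3 kb. Quantities that depend on the
full 3,467-metagenome survey (overall R² = 0.5, odds ratios 6.14/284,
56.1% significant IBD cross-continental edges, 20–25% selected segment
fractions) are treated as context: the pipeline computes their synthetic
analogues, and the generator's parameters (not the statistics) carry the
published values. Degenerate inputs are handled explicitly: all-equal
frequencies (R² undefined), matrices with no checkerboard (returned
flagged), empty margins (NaN with warning), strata below 10 informative
entities (skipped with note). Seeds thread through every stochastic
stage; identical configuration and seed reproduce byte-identical
outputs.
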