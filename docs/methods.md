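# Methods

This note documents the statistical procedures `semap` implements, the
defaults and conventions it fixes, what its synthetic data emulate, and
the design choices made where the procedure left room.

## Coordinates and containers

All coordinates are 0-based half-open (BED native); 1-based input
dialects are converted at the reader boundary behind an explicit flag.
Two intervals overlap iff `max(starts) < min(ends)` — one shared
predicate used by every stage, so "≥ 1 bp overlap" means the same thing
everywhere. Strand is ignored throughout; a gene's TSS is taken from the
annotation, never inferred. Missing matrix entries are NaN-masked, never
a sentinel value. Every stochastic operation takes an explicit integer
seed and owns its own `numpy` generator; there is no global random state.
Filters log input and surviving counts to standard error.

## Super-enhancer calling

Active enhancers are BRD4 peaks co-occupied (≥ 1 bp) by H3K27ac, with
output on the BRD4 coordinates; peaks overlapping annotated genes or
promoters are then removed. The genic/promoter filter runs *before*
stitching — exclusion at the peak stage, not via a TSS flag during
stitching. Peaks whose gap (`next.start − prev.end`) is ≤ 12.5 kb are
transitively merged; a region's signal is the sum of its constituents.

The rank cutoff operationalizes the classic signal-vs-rank inflection:
sort signals ascending, rescale both axes to [0, 1], estimate the curve's
derivative by central finite differences (one-sided at the ends), and set
the cutoff at the signal of the lowest-rank point whose derivative
strictly exceeds 1. Regions with signal *strictly above* the cutoff are
super-enhancers (boundary ties are not), ranked descending by signal.
Degenerate curves — identical signals, or a perfectly linear scaled curve
whose derivative never exceeds 1 — yield an empty SE set with a warning.
On a smooth unimodal signal distribution this construction, like the
tangent construction it mirrors, marks the convex upper tail; calling it
discriminates planted-cluster-scale signal only when such signal exists,
which is what the recovery tests assert.

## Copy-number windows and amplification tests

The autosomal genome is tiled into adjacent fixed-width windows
(default 15 kb; "sliding" in the source material is tiling — the
~192,000 count is only consistent with 2.88 Gb / 15 kb). The final
window of each chromosome is truncated. The 22 hg19 autosome lengths are
embedded constants summing to 2,881,033,286 bp and produce 192,080
windows.

Per patient, a window's value is the overlap-length-weighted mean of all
copy-number segments overlapping it by ≥ 1 bp (mass-conserving when
segments tile a window exactly); windows without any overlap are missing.
The per-window summary across patients is the mean with missing excluded;
a pooled patient×window variant is exposed behind a flag.

The random-draw test draws `|SE windows|` ids uniformly *without*
replacement from the whole-window pool — inclusive of the SE windows —
and compares per-window means with a one-sided Welch *t* (SE greater,
Welch–Satterthwaite df) and a one-sided Mann–Whitney *U* (normal
approximation with tie correction), collecting both p-value streams over
the configured iterations (default 10,000). The direct comparison tests
SE-window means against all-window means once, reporting vanishing
p-values at the 2.2e-16 floor. Constant matrices are flagged degenerate
with p = 1.

A calibration caveat documented because it is easy to trip over: with the
SE set held fixed, the per-iteration p-values are *conditional* on that
one draw and are not uniform — their rejection rate can sit anywhere.
The 5 % nominal rate is a marginal statement, recovered by repeating the
experiment over fresh exchangeable SE draws, which is how the calibration
tests (and the acceptance script) measure it.

## CNVeQTL

Genes with more than 100 missing-or-zero entries are removed (strictly
more: exactly 100 is kept). The association model is intentionally the
two-variable linear model implemented directly rather than through an
eQTL package: OLS of expression on copy number, *t* = β̂₁/SE(β̂₁),
two-sided *p* from Student's *t* with *n* − 2 df, pairwise deletion of
missing entries per pair, threshold *p* < 10⁻³. Exact fits report *p* at
a numeric floor; zero-variance copy number flags the pair as skipped.
The implementation is vectorized over all (window, gene) pairs and is
checked against an independent closed-form fit to 1e-10 relative
tolerance.

The null permutes the patient-column assignment of the expression matrix
(copy number untouched), rescans, and records the significant count; the
empirical FDR is median(null counts)/observed, capped at 1, and defined
as 1 when nothing is observed. The default is 1,000 permutations with
larger counts reachable by configuration — the median is a stable
estimator well below the 100k used at full scale. Covariates are not
included, matching the two-variable description of the scan.

## Screen rank-change analysis

Counts are normalized by a documented stand-in for the reference
pipeline: drop genes with zero counts in every well, divide by
median-of-ratios size factors (reference = per-gene geometric mean over
genes with all-positive counts), and take log₂(x + 1) as the variance
stabilization. An optional truncated-SVD step removes leading components
of the centered matrix, standing in for surrogate-variable removal. The
rank statistic depends only weakly on any monotone variance
stabilization, which is why the substitution is acceptable; it is a
deliberate deviation from the external fits it replaces.

Within each well genes are ranked descending (rank 1 = highest, ties
averaged); the global rank is the rank of the per-gene *median* across
wells (mean exposed as an alternative; the aggregation is a flagged
configuration choice, not inferred intent — the median resists single-well
perturbation effects). RC = within-well rank − global rank, so RC > 0
means downranked. With no ties, RC sums to zero within a well.

The eFDR at a threshold is median(control exceedances)/well exceedances
(1 when the well has none; capped at 1). Target selection walks an
ascending threshold grid (default: integer multiples of 1 % of the gene
count, 1–30 %) and keeps the smallest threshold with eFDR ≤ 0.1, per well
and per direction; downranked genes are the headline direction. Note the
median-based eFDR admits an occasional one-gene call on a pure-null
screen when the control median hits zero — the calibration test bounds
this rather than pretending it away.

Control-relative LFC is the well's normalized value minus the control
median (already log₂ scale). The RC-vs-LFC correlation matrix correlates
−RC in well *i* with LFC in well *j* over the pooled significant genes
(negated so self-agreement is positive); constant vectors yield flagged
NaN entries. Gene clusters come from k-means (seeded, 10 restarts) on RC
profiles with a within-cluster-sum-of-squares elbow table (default
k = 3); the SE dendrogram is average-linkage on Euclidean distances of
RC profiles.

## Hi-C targets

Contact matrices are balanced so every unmasked row of
diag(x)·M·diag(x) sums to 1, all-zero bins masked first. The primary
solver is the Knight–Ruiz inner–outer Newton iteration; a damped
symmetric Sinkhorn fixed point (x ← √(x/(Mx))) polishes to tolerance and
serves as the logged fallback when the Newton step stalls. Convergence
failure raises with the last residual; every balanced matrix asserts max
row-sum deviation < tol (default 1e-6) and balancing preserves zeros.

Expected contact at bin distance *d* is the mean of balanced entries over
unmasked pairs at that distance, so the global mean of O/E over all pairs
is 1 by construction. An SE is anchored at its midpoint bin, a gene at
its TSS bin (both conventions logged); the pair's O/E is the balanced
entry over expected at their distance. Same-bin pairs use the d = 0
stratum and are flagged.

Direct-target calling restricts to cis (same-chromosome) genes: targets
are significant genes (adjusted p < 0.0005, optionally LFC < −0.5), the
pool is the remaining cis expressed genes. For each of 100 permutations,
each target at distance *d* is matched to a control drawn uniformly from
the *k* = 10 pool genes nearest in distance (without replacement within a
permutation); nearest-k matching is used because exact distance matches
rarely exist and k gives the permutations their randomness. All control
O/E values are pooled (a per-gene variant is exposed), and a target is
*direct* iff its O/E strictly exceeds the 75th percentile
(linear-interpolation convention) of that distribution. By construction,
targets exchangeable with the pool go direct at (100 − 75) % = 25 %; the
tests assert this null rate, which also means a target set mixing looped
and unlooped genes will always carry ~25 % false "direct" labels among
the unlooped ones — the classification is a per-gene enrichment call, not
an error-controlled set. The contact resolution for target calling
defaults to the 50-kb ABC resolution and is configurable, as are the
percentile and matching parameters.

The modified ABC score uses each SE's aggregate BRD4 signal as activity
and the balanced 50-kb contact between SE bin and TSS bin as contact;
both are log₂(x + 1)-transformed and z-standardized over all scored pairs
("scaled" interpreted as z-standardization; min–max behind a flag), then
multiplied, and ranked descending per SE. Putative targets are expressed
genes (baseMean > 100). Two caveats follow from the construction: scores
of an SE with below-mean activity are sign-flipped relative to contact
(standardized activity is negative), and raw contact decays with
distance, so the score favors proximal genes; the recovery tests
therefore compare genes at comparable distances.

## Synthetic data

The generators emulate the statistical structure of the real inputs at
desk scale, and their defaults are the study conditions for every test:

- **Peaks**: background BRD4 peaks (default 500) scatter with log-normal
  signal (µ = 1, σ = 0.3) and a minimum 13-kb spacing so each forms its
  own stitched region; planted clusters (default 5 × 8 peaks within
  30 kb) carry 20× the background median signal with log-normal scatter
  (the inflation must be ≥ 5×). Real enhancer landscapes have clumped
  background and a heavier signal tail; at 500 background points that
  clumping makes the rank curve's upper tail jagged enough to draw
  spurious inflections, so the generator separates the scales cleanly —
  recovery tests on it certify the geometry of the cutoff, not
  performance on marginal signal. H3K27ac covers each BRD4 peak with
  probability `co_occupancy_prob`; genes and promoters are placed clear
  of the clusters.
- **Cohort**: per patient and chromosome, piecewise-constant seg-mean
  values Normal(0, 0.1) with geometric segment lengths (mean 8 windows,
  so windows straddle segment boundaries and exercise the weighted-mean
  rule). Amplified windows are shifted by `amp_effect` in carrier
  patients (carriage probability 0.5 per patient). Carriage must vary
  across patients: a uniform shift would leave no cross-patient variance
  and no eQTL signal to recover — varying carriage is also how real focal
  amplifications behave. Copy-number values are continuous seg-mean
  reals, not integer copies. Linked genes follow
  µ_g + slope·CN + Normal(0, noise_sd); entries go missing at the
  configured rate. Defaults: 300 patients (the matched RNA cohort scale),
  2 % missingness.
- **Screen**: 86 SE wells + 10 controls, negative-binomial counts with
  variance mean + d·mean² (d = 0.01; wells are draws from one clonal
  population), baselines log-normal(7, 1), Poisson(4) planted targets per
  well (the observed median number of genes downregulated per SE) at
  2^−2-fold knockdown. Targets are drawn from genes above the 30th
  expression percentile: enhancer targets are actively transcribed, and a
  rank statistic is structurally blind to knockdown of genes already at
  the rank floor.
- **Contacts**: Poisson counts around scale·|i−j|^−α with α = 1,
  scale = 300 (a deeply sequenced library at 50-kb bins), a fixed
  self-contact scale on the diagonal, and multiplicative planted loop
  enrichments (≥ 1) mirrored symmetrically.
- **DE table**: planted targets get their log2FC plus noise and adjusted
  p < 0.0005; non-targets get LFC ≈ 0 and p uniform on (0.1, 1); base
  means are log-normal with a configurable fraction under the
  100-count expression floor.

Everything is byte-deterministic under a fixed seed, emitted files re-read
cleanly through the real readers, and recovery tests consume only the
returned `PlantedTruth`. What passing tests show is that each procedure
recovers structure it is designed to see under clean planted conditions
and stays calibrated under matched nulls; they do not certify behavior on
real data's batch structure, GC/mappability bias, karyotype complexity,
or tail behavior the generators do not model.

## Problem sizes and known limitations

The shipped tests and acceptance script run the cohort at 300 patients ×
~1,200 windows, the screen at 2,000 genes × 96 wells, contact matrices at
300 × 50-kb bins, 400 × 25 draw comparisons for the marginal calibration,
and 20-seed recovery loops — sizes chosen so the full suite completes in
about a minute while keeping every estimator in its asymptotic regime.
The permutation default of 1,000 (vs 100k at full scale) changes only the
precision of the null median, not the estimator. Limitations worth
naming: the direct/indirect classification inherits the 25 % marginal
false-direct rate discussed above; the ABC score is distance-confounded
by design; eFDR-by-median is discrete at small counts; and the KR
implementation targets dense per-chromosome matrices at desk scale, not
genome-wide sparse resolution.
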