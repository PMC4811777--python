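# Methods

This note documents the models behind each pipeline stage, the tunable
parameters and their defaults, what the synthetic-data generators do and do
not emulate, and the numerical and design choices made where the design was
genuinely open.

## Expression preprocessing

**Generalized-log transform.** Raw bead-array intensities are transformed
with `glog(x; c) = log2((x + sqrt(x² + c²)) / 2)`. At `c = 0` this is plain
`log2`; positive `c` (same units as the intensities) damps the variance of
low-intensity values, the standard variance-stabilizing behaviour. The
original bead-array variance-stabilizing transform estimates its parameters
from bead-level variances that are not available downstream of a summarized
matrix; the glog form keeps the variance-stabilizing intent in closed form
with one interpretable constant. Default `c = 0`.

**Quantile normalization.** Each sample's sorted value vector is replaced by
the across-sample mean of sorted vectors; ties within a sample receive the
mean of the reference values their ranks span (mid-rank rule). This matches
the reference R implementation (`limma::normalizeQuantiles`, ties=TRUE),
which the tests verify on a frozen example. The transform is idempotent to
1e-12. One known property matters downstream: a gene that occupies the same
extreme rank in every sample is pinned to the same reference value, so its
fold change collapses to zero regardless of its true shift. Fold-change
*selection* accuracy is therefore benchmarked on the composition
`glog → duplicate averaging → fold change → threshold`; quantile
normalization is validated by its own oracle tests.

**Technical duplicates** are averaged per replicate group after
normalization; each duplicate pair's Pearson correlation is reported, and
pairs below `min_corr = 0.996` are flagged (warning by default, error in
strict mode — the check is QC, not a filter).

**Fold changes, deregulation, rescue.** Per gene,
`logFC = mean(log2 condition) − mean(log2 reference)`. A gene is
*deregulated* iff `|logFC| > log2(fold_threshold)` with `fold_threshold =
1.5` — strict, since the selection means "more than 1.5-fold". A deregulated
gene is *rescued* in a second comparison iff `|logFC₂| ≤ log2(fold_threshold)`
— non-strict, the complement of the deregulation region, chosen as the
natural explicit criterion for "returned to reference levels" (the rescue
band is configurable through the same threshold).

## Subtype classification

**Distances.** `d = 1 − ρ` for Spearman (default) or Pearson correlation
(range [0, 2]), or the Euclidean norm of the difference. Spearman is the
default because rank correlation survives monotone cross-platform and
cross-species scale distortions; the invariance is property-tested.

**Bootstrap null.** Each of `B = 1000` replicates resamples the mapped
profile's fold-change values *with replacement* and places them on the
signature positions in arbitrary order while the centroids stay fixed. The
pairing between genes and centroid values is deliberately broken: a paired
resample would concentrate the null on the observed distance and no lower
tail could exist. A without-replacement (permutation) variant is available
(`scheme="permutation"`). Replicates that are constant under a correlation
metric are redrawn and counted. When `n**n` is at most `enumeration_cap`
(default 100 000, i.e. signatures of ≤ 5 genes), sampling is replaced by
exhaustive enumeration of all equally likely assignments.

**Simulation test.** Per subtype, `p = (1 + #{d_null ≤ d_obs}) / (B + 1)`
(one-sided: small distance = similar; add-one keeps p ≥ 1/(B+1)), and a
subtype is flagged significant when the observed distance falls below the
null's lower `tail_level = 0.05` quantile. Monte-Carlo measurement at
B=1000 over 2000 independent no-association profiles puts the realized
type-I error at 0.050 for a fixed subtype, so the with-replacement scheme is
calibrated in practice despite the tie structure resampling introduces.
P-values can be computed against per-subtype nulls (default) or against the
pooled null across all subtype–centroid pairs (`pooled_null=True`); the
per-subtype form asks "is this profile closer to this centroid than chance",
which is the question the classifier answers.

**Assignment** minimizes the relative distance `d_obs / E[d_null]` (raw
distance selectable), with ties broken by raw distance and then label order.
Relative distance corrects for the fact that different centroids have
different typical distances to random profiles.

**Gene mapping.** Source symbols map to signature symbols through an
explicit table; duplicate sources resolve by policy (`first`/`drop`/
`error`), several sources landing on one signature gene are averaged, and a
mapped fraction below `min_mapped_fraction = 0.5` warns.

## Copy-number calling

**GC-waviness correction.** With `g~ = GC − median(GC)`,
`Var(LRR − c·g~)` is quadratic in `c` with the unique minimizer
`c* = Cov(LRR, g~)/Var(g~)`; the correction subtracts `c*·g~`. The fit is
genome-wide per sample over autosomal, allelic-balance-probing markers
(per-chromosome fitting available); constant GC degenerates to `c* = 0`
with a warning. GC fractions come from 1 Mb windows centred on each marker
(`window_bp = 1_000_000`), computed from a FASTA sequence (G/C among
A/C/G/T, windows truncated and renormalized at chromosome ends) or from a
binned GC track by overlap-weighted averaging.

**Segmentation** is recursive binary splitting: within a segment the split
maximizing the two-sample t-statistic is accepted while its permutation
p-value (add-one over `n_perm = 100` shuffles) is below `alpha = 0.01` and
both sides keep `min_markers = 5` markers. Afterwards the *SD-undo* pass
merges adjacent segments, weakest boundary first, while the segment-mean
difference is below `undo_sd = 3` standard errors of that difference,
`SE = σ·sqrt(1/n_L + 1/n_R)`, with the marker noise σ estimated robustly as
`median(|successive differences|)/(√2·0.6745)`. Scaling the undo bar by the
standard error (rather than by the marker SD itself) holds segment means —
averages over many markers — to the precision they actually have: a 0.5-LRR
shift supported by 80 markers at noise 0.2 is kept (SE ≈ 0.032), while a
0.05 wobble between 100-marker segments is undone (3·SE ≈ 0.085). A final
refinement pass re-locates each surviving boundary by maximizing the
two-sample t over the span of its two adjacent segments without the
side-size constraint, since the constrained search can park a boundary a few
markers off when the true change sits near a segment edge. The procedure is
a documented approximation of circular binary segmentation with SD-undo,
not a reimplementation of it.

**State calling** maps segment mean LRRs to the five-state coding through
fixed cut points `(−1.0, −0.3, +0.3, +0.9)`:
state 0 ≤ −1.0 < state 1 ≤ −0.3 < state 2 < +0.3 ≤ state 3 < +0.9 ≤ state 4.
These defaults respect log2 single-copy expectations at moderate tumor
purity (one-copy loss ≈ −0.5, one-copy gain ≈ +0.4 at 80–100% purity) and
are deliberately exposed as configuration: threshold calling replaces a
mixture-model caller, trading posterior probabilities for transparency and
tunability. **Reporting** keeps non-normal segments strictly longer than
`min_length_bp = 1_000_000` (length = end − start + 1, 1-based inclusive;
BED export converts to 0-based half-open). Multi-sample calls are compressed
onto the union of all samples' segment boundaries for side-by-side
comparison.

## Cohort statistics

z-scores use the unbiased reference SD. The rank-sum test delegates to the
Mann–Whitney implementation: exact enumeration when the combined n is at
most `exact_cutoff = 12` and tie-free, otherwise the normal approximation
with mid-rank tie correction and continuity correction. The
continuity-corrected approximation sits within 0.02 of the exact p
everywhere at n = 6 + 6 (worst gap ≈ 0.015, from the exact test's
discreteness). Platform concordance is Spearman rank correlation over the
shared samples (≥ 3 required), mid-ranks for ties.

## Synthetic-data generators

All generators are pure functions of their parameters and one seed, drawing
exclusively from numpy's PCG64 (`default_rng`), so identical calls are
bit-identical across platforms. Emitted truth objects carry planted gene
effects, segment coordinates/states and group labels, sufficient to score
every downstream stage.

* **Expression**: gene baselines are N(7, 2) on the log2 scale (the 2.0 SD
  reflects typical bead-array log-intensity spread and puts technical
  duplicate correlations near 0.997 at the default technical noise);
  condition effects add planted log2 fold changes; technical duplicates are
  the same latent sample plus independent N(0, `noise_sd = 0.1`) noise;
  intensities are emitted as `2^log2`, hence strictly positive.
* **Marker tracks**: markers every `spacing` bp; GC is a smoothed random
  walk clipped to [0.3, 0.7]; `LRR = segment shift + wave_coefficient·(GC −
  median GC) + N(0, noise_sd = 0.15)`; BAF scatters around the genotype
  cluster centres of the covering state (e.g. {0, ½, 1} for two copies),
  clipped to [0, 1].
* **Cohorts**: wild-type z-scores standard normal, the mutant group
  (an exact `round(n·fraction)` count) shifted by `effect`; subtype labels
  drawn from a stated categorical distribution (Proneural 0.30,
  Classical 0.25, Mesenchymal 0.25, Neural 0.15, G-CIMP 0.05 — a
  Proneural-rich, G-CIMP-rare mix resembling published cohort frequencies).

What the generators do *not* emulate: bead-level array structure, probe
sequences and cross-hybridization, background and batch effects,
biological replicate variance beyond technical noise, allele-specific
intensity biases, subclonal copy-number mixtures, and platform-specific
z-score pipelines. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under their stated noise
models, not robustness to every artifact of real array data.

## Benchmark problem sizes

The seeded benchmarks (`gbmkit.benchmarks`, driven by the test suite and
`scripts/acceptance.py`) use: 50 tracks × 2000 markers for the waviness
grid oracle (grid step 1e-4 on [−5, 5], evaluated through exact sufficient
statistics and spot-checked against direct variance computation); 100 runs
of a 240-marker chromosome with an 80-marker, −0.5-shift CNV at noise 0.2
for segmentation recovery; 20 seeds × 2000 markers for GC-wave invariance
at wave coefficient 1.0; 100 runs × 60-gene signatures at B = 1000 for
subtype recovery (profile noise = half the centroid SD); 500 runs for the
type-I calibration of the simulation test; and 20 seeded 2000-gene matrices
with 50 planted ±1.0-logFC genes for fold-change selection recovery.

## Known limitations

* Segmentation is binary splitting with refinement, not exact CBS; very
  short (< `min_markers`) aberrations are invisible by construction.
* State calling with fixed LRR thresholds ignores tumor purity and ploidy;
  the thresholds must be retuned for impure or aneuploid samples.
* The bootstrap null assumes exchangeable fold-change values across
  signature positions; strong gene–gene correlation structure in real
  signatures would make the null anti-conservative.
* BAF is generated and carried through but not used for calling; the caller
  is LRR-only by design.
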