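# Methods

## Chromatogram model and correction

A chromatogram is a strictly increasing retention-time grid (minutes;
relative front for HPTLC lanes, same code path) with an intensity trace
in arbitrary units. Correction proceeds in three stages:

* **Smoothing** — centered moving average (default window 5 points),
  shrinking symmetrically at the trace ends.
* **Baseline removal** — a rolling-minimum envelope over a window of
  10% of the trace length, itself smoothed with a moving average of the
  same width, is subtracted. On a pure ramp the envelope lags by about
  half a window; residuals are bounded by twice that grid-induced
  error. The envelope of a noisy trace sits low by roughly the expected
  window minimum of the noise (~2.7 σ for a 200-point window); the
  smoothing-before-baseline order keeps that bias small.
* **Peak detection** — strict local maxima at height ≥ snr_min × noise
  (default snr_min 3), maxima closer than 0.1 min merged keeping the
  taller, apex position refined by 3-point parabolic interpolation.
  Noise is 1.4826 · median(|first differences|)/√2, the MAD-based
  estimator that is robust to sparse peaks. This estimator assumes
  uncorrelated noise: on a smoothed trace first differences shrink by
  1/w while the noise itself shrinks only by 1/√w, so the pipeline
  estimates noise on the *unsmoothed* trace and passes it to the
  detector explicitly. Detecting on the smoothed trace with the
  raw-trace noise estimate is what makes the planted peak count exactly
  recoverable: smoothing pulls the extreme noise maxima (~3.5 σ on a
  2000-point grid) below the 3 σ threshold.

Alignment pools all detected apexes, visits them tallest-first, and
greedily attaches each to the nearest consensus column within rt_tol
(default 0.2 min) that does not yet contain that sample, founding a new
column otherwise; the consensus retention time is the running median.
Undetected peaks are stored as 0. The result is invariant to sample
order up to column permutation.

## Ratio features and chemometric grouping

For n consensus peaks, each sample yields n(n−1)/2 pairwise ratios
(earlier-eluting peak as numerator), with heights floored at half the
smallest nonzero height in the matrix so absent peaks contribute a
large but finite presence/absence signal; log2 ratios are the default
for symmetry. Multiplying a sample's whole trace by any c > 0 leaves
its ratio features unchanged, which is the point: grouping becomes a
statement about composition, not concentration.

PCA is computed by SVD of the samples × features matrix after centering
and unit-variance scaling (sample sd, ddof 1); zero-variance features
are dropped first and recorded. Scores are U·S, explained fractions
σ_k²/Σσ². Component signs are fixed so the largest-magnitude loading of
each component is positive. Grouping uses k-means (k = 3, first two
PCs, 100 k-means++ restarts, fixed seed); the original description of
"k-NN with three specified clusters" is internally inconsistent — k-NN
is supervised — and the unsupervised reading with a specified cluster
count is k-means. Group agreement is quantified with the adjusted Rand
index; loadings are ranked for a group by projecting them onto the unit
vector toward that group's cluster centroid.

## Synthetic chromatograms

Each sample is baseline (degree-3 polynomial scaled to a configurable
amplitude, default 5 a.u.) + Gaussian peaks + i.i.d. Gaussian noise
(default sd 1 a.u.). A 20-peak backbone is shared by all groups; each
group additionally owns exclusive marker peaks (default 1 per group,
the "constituent present in only one origin" pattern). Apexes are
evenly spaced with an edge margin and fail explicitly if the retention
range cannot hold them at ≥ 3 σ separation; per-sample jitter is
N(0, 0.05 min). Heights are uniform in 30–120 a.u. and modulated three
ways:

* `amplitude_group_scale` — one factor per group (default 1.0/0.65/1.4),
  the overall extract-concentration difference. Raw peak heights see
  it; ratios do not, by construction.
* `group_composition_sd` (default 0.4 log2 units) — a per-group,
  per-backbone-peak lognormal signature. Chemotypes share constituents
  at different relative levels; this is the structure that ratio
  features detect. Without it the only ratio-visible group signal would
  be the single marker peak, which a 2-PC projection of hundreds of
  features cannot reliably isolate — compositional signatures, not a
  scalar concentration factor, are what real chemotype profiles show.
* `within_group_cv` (default 0.05) — within-group lognormal height
  variability, exposed as a parameter because within-group chemical
  variance is not otherwise constrained.

Randomness descends from one seed through per-sample spawn keys, so
extending the design leaves existing samples bit-identical. The default
design (13 samples, 7/5/1) gives ARI = 1 group recovery in 20/20 seeds
for ratio features, and the 4× dilution of a single sample breaks
raw-height clustering in 20/20 seeds while leaving ratio clustering
intact — the dilution-robustness phenomenon the ratio transform exists
to provide.

## Synthetic probe arrays

Probe intensity is (2^(probeset baseline + probe affinity + condition
effect + N(0, noise_sd)) + optical background) × array factor, with ~11
probes per probeset, lognormal array factors (log-sd 0.1), log2-scale
noise sd 0.25, and background N(40, 8) a.u. floored above zero. Half of
the probesets are unexpressed (log2 signal ≈ 2): on the emulated
two-species chip nearly half the probesets target a species that is
never hybridized, and this mass of background-level probes is what
makes the density mode a valid background estimate. The default
condition layout is control(4) / China+Europe(6) / USA(4) / India(2);
planted effects are a 25-gene shared repression module (−1.0 log2 in
every treated condition, the phospholipid-pathway analogue) and a
15-gene USA-only module (+1.0 log2). Effect index sets must be
disjoint; planted genes are kept expressed.

Two deliberate generator features matter for calibration. The additive
background is required for the background-correction stage to be
meaningful — without it the normexp posterior mean distorts a
background-free lognormal signal (~10% fold-change inflation measured).
Conversely, the background itself compresses observed log fold changes
(−0.78 instead of −1.0 at these settings); correction restores them to
−0.99 ± 0.01 at 20 replicates/condition when planted genes are a
realistic minority (~1%) of probesets. Quantile normalization
redistributes planted signal when the changed fraction is large (~13%
attenuation measured at 6% of probes shifted one log2 down); this is a
known property of the method, and calibration checks plant effects
sparsely.

## RMA stages

* **Background correction.** Observed = exponential signal (rate α) +
  normal background (µ, σ). Per array, µ is the density mode located by
  Gaussian KDE on the log scale (with the change-of-variables
  correction), where the background cluster is narrow relative to the
  bandwidth — on the raw scale a Scott-bandwidth KDE smears the mode
  into the signal bulk. σ comes from sub-mode observations as the lower
  half of the background normal; α is the reciprocal mean excess above
  the mode. The corrected value is the posterior mean
  E[s|x] = a + σ·φ(a/σ)/Φ(a/σ) with a = x − µ − σ²α, evaluated in log
  space for numerical stability; it is strictly positive and approaches
  x − µ − σ²α for large x. The moment scheme is an approximation
  (everything below the mode is attributed to background); the
  posterior-mean formula itself is anchored by a quadrature oracle in
  the tests.
* **Quantile normalization.** Each array's sorted values are replaced
  by the across-array mean of sorted values; ties receive the mean of
  the reference values their ranks span, which keeps the operation
  idempotent.
* **Median-polish summarization.** Per probeset the log2 probe × array
  block is decomposed by alternating row/column median sweeps (max 10
  iterations or total absolute residual change < 0.01); expression of
  array j is the overall plus column effect. Exactly additive blocks of
  odd dimensions are recovered exactly.

Row standardization uses the population sd (ddof 0, configurable);
zero-variance rows are zeroed and flagged. Hierarchical clustering uses
1 − correlation distance (Pearson for genes, Spearman for arrays, both
exposed) with average linkage by default (none is prescribed by the
figure conventions this mirrors).

## Eigengenes and entropy

The uncentered, unscaled SVD of the log2 expression matrix orders
components by singular value and fixes signs so each eigengene's
largest-magnitude entry is positive. For an all-positive matrix the
first eigengene is nearly constant across arrays (the shared baseline);
a helper flags components whose eigengene has coefficient of variation
below 0.25 and uniform sign as baseline candidates, but exclusion is
always by explicit index. Eigen-fractions over the retained components
give the normalized Shannon entropy d = −(1/ln m)·Σ p_k ln p_k, with
0·ln 0 = 0 and d = 0 by convention for a single retained component.
Excluding a component from the fractions is numerically identical to
subtracting its rank-1 term and refitting, so both readings of
"entropy after filtering out eigengene 1" coincide. On default
synthetic data eigengene 1 is constant to CV < 0.05 and eigengene 2
separates control from treated arrays by more than three pooled
standard deviations.

## Moderated contrasts

Per-gene OLS against a treatment-coded design (intercept = control
baseline; the exact parameterization is not otherwise prescribed, and
treatment coding is assumed and documented). Contrasts are weight
vectors over coefficients: control vs all treated uses the unweighted
mean of the treated-level coefficients; per-group contrasts weight one
level. Arrays can be excluded by id through configuration (e.g. a
treated sample whose arrays cluster with the controls).

Variance moderation follows the standard empirical-Bayes scheme: with
s² ~ s0²·F(df, d0), the log-variance moments give
d0 = 2·trigamma⁻¹(var(e) − trigamma(df/2)) and s0² from the mean, with
e = log s² − digamma(df/2) + log(df/2); trigamma inversion is by Newton
iteration. When the moment variance is nonpositive the d0 = ∞ branch
pools all genes at the geometric mean of the observed variances —
deliberately without the chi-square log-bias correction, so that when
every gene shows the same s² the moderated t equals the ordinary t at
that variance. Posterior variances are
s̃² = (d0·s0² + df·s²)/(d0 + df); the moderated t has d0 + df degrees of
freedom (normal when d0 = ∞). Genes with zero posterior variance and
zero estimate get p = 1. Bonferroni adjustment multiplies by the number
of genes actually tested (not chip size) and selects at strict
adjusted p < α. The implementation is cross-checked against the
Bioconductor reference implementation on simulated data in the test
suite; the finite-d0 path agrees to ~1e−5.

## Assay calculators

DPPH scavenging is blank-relative inhibition with sample-blank
correction, % = 100·(A_blank − (A_sample − A_sample_blank))/A_blank,
clipped to [0, 100] with an out-of-range flag; the cited assay
literature permits variants and this one is documented as the choice.
The % scavenging is used as the response variable of the gallic-acid
standard curve (the mapping is not otherwise specified). Standard
curves are ordinary least-squares lines (≥ 3 points, r² reported);
inverse prediction flags extrapolation beyond the standards. ORAC nets
the trapezoid area under each fluorescence decay curve on its own time
grid; a strictly paired comparison can demand matching grids. Dose
arithmetic is exact dimensional analysis — mg/g × mg/mL = µg/mL,
µg/mL / (g/mol) × 1000 = µM — done in decimal arithmetic, with
two-decimal *truncation* as the default reporting convention (inferred
from the reproduced composition table, where every printed row
truncates; half-up rounding is available). Molar masses are
caller-supplied; myo-inositol 180.16 and choline 104.17 g/mol ship as
documented constants.

## Pipeline, configuration, determinism

A single validated configuration document (pydantic, unknown keys
rejected) carries every stage parameter and one explicit seed from
which all stage seeds derive. Runs are deterministic given the config;
manifests echo all parameters. Concordance aligns the chemical
clustering (per extract) with the transcriptomic condition-mean
clustering (propagated to extracts through the group → condition map),
reports pairwise ARIs, and flags extracts whose assignments disagree
after optimal (Hungarian) label matching.

Problem sizes used by the shipped checks: 13 chromatogram samples on a
2000-point grid with ~23 consensus peaks; 500 probesets × 11 probes ×
16 arrays for the transcriptomic run; 200 genes × 8 arrays × 500
replicates for null calibration. These sizes make the whole suite and
the acceptance script run in seconds while leaving all effects several
standard errors from their thresholds.

## Limitations

The synthetic chromatograms use symmetric Gaussian peaks with no
co-elution shoulders, tailing, or m/z dimension; passing tests show the
correction/alignment logic is sound, not that it handles heavily
overlapped real LC traces. The expression generator has no probe
saturation, no mismatch probes, no spatial artifacts; the background
estimator is a documented approximation to the canonical RMA estimator
rather than a reimplementation of it. Fold-change attenuation by
quantile normalization at high changed-gene fractions is inherent to
the method and not corrected. The full phytomics similarity index is
out of scope; only its ratio-feature rationale is implemented.
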