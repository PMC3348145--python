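# Methods

This note records the models, parameter choices and numerical conventions
behind `ovmorph`, and what the synthetic validation does and does not
establish about real data.

## Segmentation model

Images are assumed to show nuclei darker than their background (grayscale,
or RGB collapsed by Rec. 601 luminance; a single channel can be selected
instead). The band-pass filter is implemented as a difference of Gaussian
low-passes applied in the Fourier domain: structures smaller than
`band_low` px are smoothed with σ = band_low/2 and structures larger than
`band_high` px are removed by subtracting a σ = band_high/2 low-pass.
Defaults are 3 and 40 px, the conventional small/large structure settings
for this kind of particle segmentation; both are configurable. The filter's
amplitude response is exactly `exp(−σ_s²ω²/2) − exp(−σ_l²ω²/2)`, which the
test suite checks against pure sinusoids.

Thresholding defaults to Otsu's method on the band-passed image (a manual
threshold overrides it); pixels below threshold are foreground, holes are
filled, and components are labelled with 8-connectivity — the common default
for roundish blobs. A uniform input has no meaningful threshold and raises a
degenerate-input error rather than returning an arbitrary mask.

Per-nucleus measurements use the standard particle-analysis definitions:
area = pixel count, perimeter from boundary tracing, axes from the ellipse
with matching second-order central moments, convex area from the hull.
Circularity 4πA/P² is capped at 1.0 because discretized boundaries can
exceed the continuum bound; components smaller than 5 px are unmeasurable
(degenerate moments) and are skipped by the chain — they are far below the
50 px² gate and cannot affect results. The retention gate is inclusive in
area (50 ≤ A ≤ 500 px²) and strict in circularity (> 0.3), matching the
stated selection rule literally.

## Profile construction

Bins are half-open `[50+45(b−1), 50+45b)` with the last bin closed at 500,
so bin assignment is total on the gated range. Statistics use the
population-SD convention (divisor n), which is defined for single-nucleus
bins — common in the extreme bins — and keeps SD features well-defined
instead of missing; the divisor is configurable. Empty bins yield missing
means/SDs (a zero would fabricate a shape value) and zero counts;
percentages are 100·count/total. Profiles are built per sample, pooling all
of a sample's images; per-image profiles can be produced by passing
single-image sets.

Compactness, defined here as the Clark–Evans aggregation index
(mean nearest-neighbour distance over 0.5/√density, density = nuclei per
total imaged area), is the most standard single-number spatial-aggregation
statistic: < 1 indicates clustering, ≈ 1 complete spatial randomness, > 1
regular spacing. No edge correction is applied; at the nucleus densities the
pipeline produces the edge bias is on the order of 2%.

Normalization is natural-log transform followed by per-feature
median-centering of the logs (equivalently log(value/feature median)), which
produces per-feature median 0. Centering before the log would be undefined
for the non-positive values centering creates, so the log-then-center order
is used. Non-positive raw values (e.g. zero counts) cannot be log-scaled;
they become missing, are excluded from that feature's median, and propagate
to downstream statistics under pairwise deletion.

## Signature discovery and the weighted vote

SNR uses sample SDs (divisor n−1, configurable); its sign is positive when
the sensitive class mean is higher. Significance testing is the two-sided
unequal-variance (Welch) t-test; morphometric features are corrected by
Benjamini–Hochberg over all testable features and gated at FDR ≤ 2%, genes
are gated jointly at p < 0.05 and |log2 FC| ≥ log2(cutoff), where the fold
change is the geometric-mean ratio resistant/sensitive (expression values
are log2, so this is 2^(mean difference)). The fold-change cutoff is tuned
by maximizing resubstitution accuracy on the training set over a candidate
grid (ties to the smallest cutoff; an empty selection scores the
majority-class rate and is flagged); leave-one-out accuracy, with selection
and fitting redone per fold, is available and used in validation.

The classifier is the Golub-style weighted vote with the 1/N-normalized
score S = (1/N) Σ w_f (x_f − b_f); a flag switches to the unnormalized sum,
which is ranking-equivalent. Scores above the cutoff predict sensitive. The
default cutoff is 0 (the natural midpoint rule); in the pipeline the cutoff
is re-calibrated as the Youden-optimal point of the training ROC, and a
user-supplied cutoff is honoured for external application. Missing model
genes in a query sample are dropped with renormalization and a warning; no
overlap is an error. AUC is the trapezoid rule (equivalently the concordant
pair fraction, which the tests verify by double loop).

Quantile splits label the round(f·n) highest scores as "high-score" with
ties broken by stable sample order; rounding (rather than ceiling) matches a
70.1% split of 244 samples giving 171/73. Feature normality, which
motivates the parametric t-test and Pearson correlation, is checked with
the Jarque–Bera test.

## Survival analysis

Median splits send values equal to the median to the "high" group. The
product-limit estimator, log-rank test (hypergeometric variance under ties)
and Cox model (Efron tie handling) delegate to lifelines; each is pinned
against hand-tabulated oracles on toy data in the test suite. The reported
median survival is the earliest time the curve reaches ≤ 0.5 (missing if
never). Cox fits adjust for age (continuous) and stage/grade
(dummy-encoded); constant covariates are dropped with a warning, and
non-convergence or separation is reported, not swallowed — the pipeline
driver records such failures in the run manifest and fits the unadjusted
model only when groups are too small (< 20 samples) to support covariates.

## Integration

The supervised analysis is a per-gene Welch t-test between the feature
split's groups at p < 0.01; the correlation screen is Pearson at p < 0.005
with pairwise deletion and no multiple-testing correction — both thresholds
are deliberate screening rules, not FDR-controlled discoveries, and are
documented as such. Spearman is available behind a flag.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure each stage assumes, at
the motivating study's printed conditions:

* **Images** — non-overlapping anti-aliased dark ellipses (uniform area and
  elongation, uniform orientation) on a Gaussian-noise background at the
  study's 1072×648 px field size; non-overlap by rejection sampling (cap
  10,000 attempts) because the measurement oracle assumes one component per
  nucleus. Defaults: background 200, nuclei 60, noise SD 4 on the 8-bit
  scale — strong nuclear contrast typical of well-stained fields.
* **Expression** — 232 samples split 165 sensitive / 67 resistant, gene
  baselines N(7, 1.5²) log2 units, planted informative genes shifted by 1
  log2 unit in the resistant class (32.5% up / 67.5% down, the direction
  split of the motivating 227-gene signature) over N(0, 0.5²) noise.
* **Features** — a 130-sample (90/40) two-class matrix with 5 features
  shifted up and 10 down by 1.5 SD. Null features are drawn in correlated
  blocks (14 features sharing a latent factor at ρ = 0.9) because real
  binned profiles are strongly dependent within bins (count/percentage
  near-duplicates, per-bin parameter families); an iid null model would
  misrepresent the false-positive behaviour of the FDR screen on profile
  data.
* **Survival** — exponential event times (closed-form medians, exact
  proportional hazards), resistant hazard multiplied by the planted ratio;
  OS defaults 53.9-month sensitive median, HR 1.6, 37% censoring; PFS 25.8
  months, HR 2.8, 11% censoring. Censoring is independent Uniform(0, U)
  with U solved so the expected censored fraction matches the target.

Passing tests on these cohorts establishes that the implementation computes
its statistics correctly and recovers planted signal under the assumed
structure. They do not establish performance on real histology — touching
or overlapping nuclei, stain variation, texture, out-of-focus fields and
non-elliptical shapes are all outside the generator — nor robustness of the
gene signature to cross-platform effects.

## Numerical conventions and problem sizes

Tolerances: oracle-equivalence checks are exact to 1e−10; calibration
checks use binomial-width bands (e.g. null log-rank rejection in [0.01,
0.10] over 200 replicates). Degenerate inputs fail loudly: constant images,
zero-spread features, all-censored log-rank, constant median-split features
all raise. Validation problem sizes were chosen as the smallest that make
the statistical checks sharp: 20 images of 10–60 nuclei for segmentation
recovery, 20 seeds for planted-recovery rates, 200 replicates for null
calibration, 500/group for hazard-ratio recovery; the full validation suite
and the acceptance script each run in well under a minute.

## Known limitations

* Compactness substitutes a standard spatial statistic for an undefined
  original; absolute values are not comparable to other definitions of
  "compactness".
* The weighted-voting score normalization (1/N) is one of two conventions
  in use; the flag preserves the other.
* Otsu thresholding replaces a human-verified threshold; on low-contrast
  real images a manual threshold may be required.
* The per-sample "Total" statistics pool nuclei over a sample's images;
  per-image averaging is a different convention and would give different SD
  features.
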