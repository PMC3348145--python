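# ovmorph

Integrated analysis of chemotherapy response in serous ovarian carcinoma from
two data modalities: a **binned nuclear-morphometry profile** extracted from
histology-style images, and an **SNR-weighted gene-expression classifier**
with an ROC-calibrated decision cutoff, followed by Kaplan–Meier / log-rank /
Cox survival stratification of the resulting patient groups and a
feature–gene integration step. The package is aimed at computational
pathology and cancer-genomics researchers who want each stage of this
workflow as a tested, reusable library function, exercisable end to end on
synthetic cohorts with planted ground truth.

## The method

**Nuclear image profile.** Each image is FFT band-pass filtered (suppressing
structure below 3 px and above 40 px), thresholded (Otsu by default), and
labelled into 8-connected components. Each nucleus is measured (area,
perimeter, moment-matched ellipse axes, convex hull) and gated to an area of
50–500 px² and circularity > 0.3. Retained nuclei are split into 10 evenly
spaced area bins of 45 px². For each parameter *P* ∈ {area, perimeter,
circularity, aspect ratio, solidity, roundness} the per-bin and overall mean
and SD are features (2 × 6 × 11 = 132), plus 10 bin counts, 10 bin
percentages, and one spatial compactness statistic (Clark–Evans
nearest-neighbour index) — 153 features per sample, log-transformed and
median-centered across the cohort.

**Signature discovery and classification.** Candidate features/genes are
ranked by the signal-to-noise ratio between response classes,

```
SNR_f = (μ_f,sens − μ_f,res) / (σ_f,sens + σ_f,res),
```

with significance from a two-sided Welch t-test: morphometric features pass
at Benjamini–Hochberg FDR ≤ 2%; genes pass a joint rule of p < 0.05 and a
geometric-mean fold-change cutoff tuned on training accuracy. The classifier
is a weighted vote: each signature gene casts `w_f (x_f − b_f)` with
`w_f = SNR_f` and `b_f = (μ_f,sens + μ_f,res)/2`, the sample score is the
vote average `S = (1/N) Σ_f w_f (x_f − b_f)`, and `S` above a cutoff
(Youden-optimal on the training ROC by default) predicts chemosensitive.

**Survival and integration.** Patient groups — classifier score quantiles or
a median split on a single morphometric feature — are compared by the
product-limit estimator, the log-rank test and Efron-tie Cox regression
adjusted for age, stage and grade; feature–gene links come from a supervised
per-gene t-test across the feature split (p < 0.01) and a signed Pearson
correlation screen over all feature–gene pairs (p < 0.005).

Because the workflow is validated on synthetic data, `ovmorph.synthetic` is
a first-class module: it renders non-overlapping elliptical nuclei with
analytic ground truth, plants informative gene subsets at a stated fold
change, and draws exponential survival times with a planted hazard ratio and
calibrated uniform censoring.

## Worked example

```
python analysis/01_simulate_cohort.py      --seed 0
python analysis/02_segment_and_profile.py  --seed 0
python analysis/03_gene_signature.py       --seed 0
python analysis/04_survival_stratification.py --seed 0
python analysis/05_integrate_features_genes.py --seed 0
```

prints (abridged):

```
segmented 32 images -> 1440 retained nuclei
profiles: 16 samples x 153 features (expected 153)
tuned fold-change cutoff: 1.2 -> 33 signature genes
training AUC 1.000; score cutoff -0.0422
15 response-associated features at FDR<=2%
median split on top-ranked feature F140: 127 high / 126 low
PFS: median high 28.7 vs low 14.1 months; log-rank p=0.00021; age/stage/grade-adjusted HR(high) 0.58
600 correlated feature-gene pairs at p<0.005 (265 positive, 335 negative)
```

Reading: every planted nucleus was recovered and profiled (153 features per
sample); the tuned classifier separates the two response classes perfectly
on this noise level (AUC 1.0); exactly the 15 planted morphometric features
survive the FDR ≤ 2% screen; the median split on the top-ranked feature
stratifies progression-free survival (the "high" group's hazard is 0.58 of
the "low" group's after covariate adjustment, log-rank p ≈ 2×10⁻⁴); and the
feature–gene correlation map links the morphometric signature exclusively to
planted signature genes. The same stages are available as a CLI
(`ovmorph all --seed 0 --run-dir results/run`) or as library calls.

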