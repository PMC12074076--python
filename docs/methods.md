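# Methods

## Background and scope

Argyrophilic nucleolar organizer regions (AgNORs) are silver-stainable
protein complexes at ribosomal gene loci. In an AgNOR-stained exfoliative
cytology smear they appear as well-defined dark dots inside the nucleus,
and the number of dots per nucleus tracks the cell-proliferation rate.
In oral-cancer screening the mean AgNORs/nucleus rises from healthy
mucosa (control group, CG), through carcinogen-exposed mucosa (EG) and
potentially malignant disorders (OPMDG), to squamous cell carcinoma
(OSCCG), which makes a per-patient mean count a candidate screening
marker with a diagnostic cut-off.

This package implements the full analysis chain around that marker on
synthetic data with exact ground truth: cohort simulation, smear
rendering, automated dot counting, group summaries, ROC-based cut-off
estimation, and human-vs-automated agreement. Raw clinical smears are
not consumed; the image stage accepts any grayscale/RGB image plus
LabelMe-style rectangle annotations, so real data can be substituted
where available.

## Cohort model

Each of the four groups is parameterized by a between-patient mean ± SD
of mean AgNORs/nucleus and by the probabilities of a cell carrying 1, 2,
3, 4 or 5+ dots (`synthetic_data.default_group_params`; percentages are
renormalized to sum to one since the printed CG row sums to 100.2%).
Defaults:

| group | mean ± SD | % 1 / 2 / 3 / 4 / 5+ |
|-------|-----------|----------------------|
| CG    | 2.89 ± 0.62 | 13.3 / 29.6 / 26.1 / 20.1 / 11.1 |
| EG    | 3.67 ± 1.03 | 8.1 / 17.0 / 24.1 / 21.1 / 29.7 |
| OPMDG | 3.25 ± 0.63 | 8.4 / 20.0 / 31.5 / 23.6 / 16.5 |
| OSCCG | 4.08 ± 0.46 | 3.6 / 12.6 / 23.4 / 29.0 / 31.4 |

Counts live on 1..13 (the counting convention's range; a counted nucleus
has at least one dot). The 5+ class is expanded over {5..13} with
geometric decay (ratio 0.5), giving the class a conditional mean of
about 5.98.

Per-patient heterogeneity is coupled to the published summaries by
exponential tilting. A patient draws a latent mean m_p ~ Normal(μ_g,
σ_g) truncated to [1, 13]; the group's base distribution p over 1..13 is
tilted to p_k(θ) ∝ p_k·exp(θk) with θ solved (Brent's method, tolerance
1e-12) so that the tilted mean equals m_p; cells are i.i.d. draws from
the tilted distribution. Tilting is the minimal-assumption way to couple
the two printed summaries (group means/SDs and class percentages): the
source reports no within-patient dispersion, so any coupling is a
modeling choice, and this one reproduces both summaries in expectation
while keeping the per-cell law in the exponential family of the base
distribution. Patient means at the boundary are clamped into the open
interval (1, 13) by 1e-9 so θ stays finite.

Defaults of 15 patients/group and 50 cells/patient mirror the screening
protocol the cohort emulates ("first 50 analyzable cells"; 15
participants per group from the power computation below).

## Smear renderer

A scene is a list of elliptical nuclei with circular dots; rendering
paints background / nucleus / dot gray levels (defaults 230 / 150 / 30,
mimicking a light smear background, mid-gray silver-stained nucleoplasm
and near-black dots) plus additive Gaussian noise (default SD 8 gray
levels on an 8-bit scale). Same seed, same scene → byte-identical image.

Ground truth per nucleus is the fused-aware count: dots whose disks
touch or intersect are one structure, so the count is the number of
connected components of the dot-intersection graph. Scene construction
keeps distinct structures more than one fuse-distance plus a 4 px
raster-safety gap apart, so pixel connectivity in the rendered image
always agrees with the geometric ground truth; "fused" structures are
realised as touching twin disks. Nuclei destined to carry many dots are
drawn proportionally larger so the groups fit.

Overlap cases are rendered as near-touching pairs (centre distance
2.12–2.3 radii): their pixel masks stay distinct but their minimal
bounding boxes collide, which is the situation the manual protocol calls
overlapping and refuses to box. Accordingly the emitted LabelMe
annotation contains rectangles only for non-overlapping, non-artifact
nuclei; the ground-truth JSON records every nucleus with its flags.

What the generator does **not** emulate: uneven illumination, stain
intensity variation, debris and microbial background beyond simple dark
blobs, partially focused dots, cytoplasm, and color. Passing tests
therefore demonstrate correctness of the counting logic and statistics
under the stated imaging model, not robustness to real-smear artifacts.

## Automated counting

`quantify` replaces a learned detector with deterministic classical
operators, because every downstream statistic depends only on the
per-nucleus counts and determinism makes the whole pipeline exactly
reproducible:

1. **Segmentation** (`segment_nucleus`): per-crop Otsu thresholding on
   exact integer gray levels; the largest dark connected component is
   the nucleus. If Otsu's dark class covers less than 10% of the crop it
   has locked onto the dot level rather than the nucleus/background
   boundary, and the split is re-estimated on the bright remainder.
   Quality flags: `no_nucleus_found` (largest component < 50 px, or no
   contrast), `overlapping_nuclei` (second component > 50% of the
   largest), `touches_box_edge` (mask on ≥ 25% of the crop border).
2. **Dot detection** (`count_nors`): a second Otsu restricted to the
   nucleus mask; components < 3 px are noise; 8-connectivity makes
   touching/fused dots a single structure; counts cap at 13.
3. **Exclusion rules** (`quantify_slide`): any quality flag excludes the
   nucleus with its reason; zero detected dots excludes it as
   `zero_nors` (an unlabeled nucleus is not analyzable); otherwise the
   count is recorded. counted + excluded = boxes, always.

A threshold is accepted only when the dark/bright class means differ by
at least `min_contrast` (default 40 gray levels ≈ 5 noise SDs): Otsu
always returns *some* split, and without this gate a unimodal noisy
region (background-only crop, dot-free nucleus) is halved into phantom
structures. All constants live in `QuantifyConfig`.

On the renderer's imaging model this pipeline reproduces ground truth
exactly on noise-free scenes and ≥ 95% of nuclei at the default noise
(the test suite measures both).

## Summaries

The unit of analysis is the patient. `patient_summary` gives the mean
count and the class percentages (1..4 exact, 5+ pooled); `group_table`
reports mean and SD of patient means (SD across patients, n−1
denominator — not pooled cell-level SD), the mean of each class
percentage, and marks the most frequent class (ties to the lower class;
none arise in practice). Report files render means to 2 decimals and
percentages to 1, matching the reporting style of the field.

## Diagnostics

Higher counts mean more suspicious, so a test is positive when the
patient mean is at or above the threshold. `roc_curve` evaluates
sensitivity/specificity at midpoints between consecutive distinct values
plus ±∞ sentinels; `auc` is the Mann-Whitney statistic computed by the
rank-sum identity (ties get half credit), which equals both the pair
enumeration and the trapezoidal area under the ROC; `optimal_cutpoint`
minimizes (1−sens)² + (1−spec)² — the ROC point closest to the perfect
corner — breaking ties toward higher sensitivity, then the lower
threshold. Logistic regression on a single monotone predictor induces
the same ranking and hence the same ROC and AUC, so no separate logistic
fit is performed. `sample_size_two_means` is the two-sided z-formula
n = ⌈(z₁₋α/₂ + z_power)²(σ₁² + σ₂²)/Δ²⌉ with drop-out inflation
⌈n/(1−d)⌉; with Δ = 0.59, SDs 0.56/0.58, α = 0.05, power = 0.80 and 10%
drop-out it gives 15 required and 17 recruited per group.

Degenerate inputs: one-class label vectors are errors; ratios with zero
denominators are reported as missing (NaN), never as 0; an all-tied ROC
has only the two trivial corner points and its "cut-off" falls back to
the tied value.

## Agreement

`icc_agreement` computes the intraclass correlation between two raters
from the two-way ANOVA mean squares. The default form is ICC(A,1) —
two-way, single measures, absolute agreement — because the comparison is
between two specific raters whose absolute counts must match; the
consistency form ICC(C,1), which forgives a constant offset, is an
option and the form used is echoed in the output. Confidence intervals
use the F-distribution (Satterthwaite degrees of freedom for the
absolute-agreement form). Reliability labels: ≥ 0.75 "good" (boundary
inclusive), 0.5–0.75 "moderate", else "poor". Constant data in both
raters leaves the ICC undefined and raises.

In the pipeline, agreement pairs the renderer's ground-truth counts
(standing in for the human examiner) with the automated counts over the
bounding-boxed nuclei. Because the synthetic imaging model is benign,
this ICC is essentially 1; it validates the plumbing, not the field
performance of any detector.

## Pipeline problem sizes

The default end-to-end run simulates 15 patients/group × 50
cells/patient, renders one 512×512 slide per group with 12 boxed nuclei
plus one overlap pair and one background artifact, quantifies every
annotated box, summarizes, evaluates all six pairwise group contrasts
(reference listed first: CG–EG, CG–OPMDG, CG–OSCCG, EG–OPMDG, EG–OSCCG,
OPMDG–OSCCG), and computes the truth-vs-system ICC. The verification
script enlarges only the pieces that need precision: 40 000 simulated
patient means per arm for AUC recovery and 1 000 replicates at the
study's arm sizes (15 controls vs 14 cases) for the cut-point
distribution. A full run takes a few seconds on one CPU.

## Known limitations

- The imaging model is deliberately simple; the counting accuracy
  reported here does not transfer to real smears.
- The exponential-tilt coupling between patient means and cell-class
  probabilities is one of many distributions consistent with the printed
  summaries.
- Confidence intervals are provided for the ICC only; AUCs and cut-offs
  are point estimates.
- The per-patient 1–13 histogram is kept internally but only the 1–4/5+
  binning is reported.
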