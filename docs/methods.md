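# Methods

## Model and assumptions

The package implements a weakly supervised slide classifier. Its core
assumption is that a slide is a bag of patches of which only a minority carry
category-discriminative morphology, and that discriminative patches share
imaging phenotypes — so they concentrate in a few feature-space clusters. The
pipeline therefore (i) clusters patch features, (ii) measures each cluster's
class-discriminative power against an all-patch benchmark, (iii) trains the
final patch classifier only on clusters that beat the benchmark, and
(iv) aggregates patch votes to the patient with a majority rule. The
patient-level label propagated to every patch is noisy by construction; the
benchmark comparison is what turns that noise into a selection signal:
clusters of uninformative patches cannot beat a classifier trained on
everything, while clusters enriched in informative patches can.

## Tissue segmentation

Segmentation runs at a 4× downsample of level 0 (the 5× objective level of a
20× scan at 0.5 µm/px). The RGB image is converted to CIE L\*a\*b\* (D65,
sRGB transfer) and the chroma magnitude √(a\*² + b\*²) is thresholded by
Otsu's criterion on a 256-bin histogram. Chroma rather than a single channel
is thresholded because H&E tissue is chromatic whereas glass background is
near-achromatic white; this makes the split robust to overall illumination.
For integer-count histograms the between-class-variance argmax is computed in
exact integer arithmetic, so near-ties resolve deterministically to the
smallest threshold. A histogram with all mass in one bin (e.g. a pure-white
slide) yields an empty mask with a warning rather than an error. Patches lie
on a non-overlapping grid anchored at the origin, 0-based half-open
coordinates, and are retained when at least `min_tissue_fraction` (default
0.5) of their footprint is mask-positive. Defaults: patch size 1024 px at
level 0 for clinical-scale imagery, 128–256 px in the synthetic tiers.

## Features

Extractors are pluggable: any pure function from a 256×256 patch to a
fixed-length vector satisfies the contract (a trained CNN embedding is one
admissible implementation). The shipped `BaselineTextureExtractor` (D = 38)
uses per-channel means/variances, 8-bin per-channel histograms, and
gradient-magnitude statistics on a 2×2 grid; it is deterministic, needs no
training, and separates the synthetic texture archetypes. Features are not
standardised before clustering (configurable); the patch *classifier*
standardises internally, since its descriptor blocks live on very different
scales.

## Clustering and the choice of K

K-means (Lloyd's algorithm, k-means++ seeding, best of 10 restarts by
inertia, fixed seed) is scanned over K = 2..12. The mean silhouette
coefficient picks K; the Calinski-Harabasz index is logged as a cross-check
and a warning notes any disagreement of the argmax. Conventions: singleton
clusters contribute silhouette 0; degenerate all-singleton partitions score
0; CH is +∞ when K = n (zero within-cluster dispersion). Silhouette is exact
up to 20,000 points and computed on a seeded subsample beyond that. The
pipeline fits the clustering on a seeded subsample of training patches
(default 2,000) and then assigns all patches to the fitted centroids —
fitting on a manageable subsample and deploying to the full cohort is the
intended usage pattern at clinical scale. Assignment ties go to the lowest
cluster id.

## Selection, voting, and fallbacks

Per-cluster classifiers and the all-patch benchmark are the same learner (by
default a seeded multinomial logistic regression behind a scaler — convex,
deterministic, fast; an iterative deep learner can be plugged in behind the
same contract, in which case the epoch rule below applies). Selection keeps
clusters whose validation accuracy is *strictly* greater than the benchmark's;
equality excludes. Fallbacks, all logged: a cluster with no validation
patches is excluded from candidacy; if no cluster beats the benchmark the
single best cluster is selected; a patient with no patch in a selected
cluster falls back to an all-patch vote. Vote ties break by the higher mean
predicted probability among the tied classes, then by class order
(A2, A3, A4, O2, O3, GBM). Selection is global — one selected set per trained
model — rather than per patient.

## Evaluation

One-vs-rest metrics per class: AUC by the rank statistic with ties counted
½, threshold metrics (accuracy, sensitivity, specificity, F1) from argmax
class assignments (matching how the majority vote assigns patients), PR
curves, and a confusion matrix. The macro AUC is the unweighted mean over
classes present in the truth; absent classes are reported as undefined with
a warning. The DeLong test compares correlated AUCs through midrank
structural components; zero-variance degenerate cases return p = 1 (equal
AUCs) or p = 0 with a warning. Cross-validation uses stratified folds at a
4:1 train:validation ratio (per-fold class counts within one patient of
proportionality); the best fold is the macro-AUC argmax, ties to the lowest
index.

For iterative learners the epoch rule tracks the 10-epoch moving average of
validation loss after a minimum of 50 epochs, up to a hard cap of 150; the
retained model is the *last* epoch of the best window (the rule is anchored
at consecutive epochs, ties to the earliest window), and a minimum counts as
confirmed after 10 further epochs without improvement. Window, minimum, cap,
and patience are configurable for desk scale.

## WHO rule engine

Deterministic and auditable: every decision records its fired rules.
IDH-mutant + 1p/19q-codeleted → O, grade = histologic grade (2/3);
IDH-mutant non-codeleted → A, grade 4 iff MVP ∨ necrosis ∨ CDKN2A/B
homozygous deletion, else histologic grade; IDH-wildtype → GBM iff the
histologic glioblastoma picture or TERT promoter mutation or high-level EGFR
amplification or +7/−10. The histologic picture defaults to (MVP ∨ necrosis),
the classical criterion; a config switch tightens it to (MVP ∧ necrosis).
IDH-wildtype tumours with no qualifying feature return an explicit
"indeterminate" outcome (not classifiable as adult-type diffuse glioma in
this scheme). Unknown markers never default: if an unknown lies on the
decisive path the outcome is "unresolved" and names the missing marker. A
1p/19q codeletion recorded together with IDH-wildtype status is flagged as
inconsistent in the rationale but still classified by the wildtype rules.

## Synthetic benchmark

The feature tier plants `n_patterns` = 9 Gaussian pattern clusters in
D = 16 dimensions: centroids sit on mutually orthogonal directions at
pairwise distance 8× the unit within-pattern spread — far enough for the K
scan to recover the planted K, close enough that silhouette values stay in a
realistic 0.2–0.4 range. Three patterns are *informative*: their emission
means carry a per-class shift of 2× the within-spread, giving the per-cluster
classifier a realistic (not ceiling) patch accuracy around 0.8. Each class
concentrates 0.4 of its mixture on a "home" informative pattern shared with
one other class (the hard pairs separable only through the emission), 0.05 on
each other informative pattern, and the rest uniformly on the six
uninformative patterns. Defaults: 6 classes × 20 slides × 64 patches.

The image tier renders each tissue block as a chromatic oriented-sinusoid
grating (pattern-specific hue, orientation, and frequency; small class-coded
hue/frequency shifts for informative patterns) on a pure-white canvas, and
emits the true tissue map and per-block pattern ids. It exercises
segmentation, tiling, and feature extraction. What these tiers do **not**
emulate: stain variability, nuclei-level morphology, scanner artefacts,
uneven illumination, spatial correlation of patterns within a slide, or
class imbalance — so passing tests demonstrate the correctness of the
pipeline's logic and its selection behaviour under planted signal, not
clinical-grade performance on real H&E slides.

## Numerical and design choices

- Seeding: one global seed per run fans out to the split, subsample, and
  clustering stages by fixed offsets; same config ⇒ byte-identical selection
  sets and prediction files.
- Otsu ties → smallest threshold; assignment ties → lowest cluster id; vote
  ties → mean probability, then class order; fold ties → lowest index. All
  tie-breaks are deterministic by construction.
- Problem sizes in the test and acceptance runs (7,680-patch benchmarks,
  480-point K-scan replicates, 2,000-draw bootstrap, 128-px slide tiles) were
  chosen so the whole study runs in minutes on a single CPU while keeping
  every statistic comfortably away from its decision boundary.
- Degenerate inputs: empty masks warn instead of raising; single-class
  training sets raise; probability rows must sum to 1 within 1e−6.

## Known limitations

- The deep feature extractor and CNN patch classifier of a clinical
  deployment are intentionally out of scope; the contract accepts them but
  the shipped learner is linear.
- Selection is global; a per-patient selection variant is not implemented.
- One slide per patient is assumed throughout; multi-slide aggregation is
  not handled.
- No stain normalisation or scanner calibration.
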