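# Methods

## Problem and model

`lnmil` implements a weakly supervised pipeline for predicting lymph-node
metastasis (LNM) in T1 colorectal cancer from H&E whole-slide images (WSIs).
Supervision is at the slide level only: a slide is a *bag* of unlabeled tissue
patches that inherits the patient's binary LNM label (multiple instance
learning, MIL).

The classifier has three parts:

* **Feature extractor (FE).** A small convolutional encoder (four stride-2
  3×3 blocks with 8/16/32/64 channels, global average + max pooling, affine
  map, ReLU, L2 normalization) maps any RGB patch to a 512-dimensional
  feature vector (FV). It is pre-trained as a patch-level binary classifier
  in which every patch inherits its bag's label; the classification head is
  then discarded (but kept in the checkpoint as a diagnostic). Pretraining is
  deliberately *unweighted*: bag-inherited labels are noisy (most patches of
  a positive slide are histologically normal), and inverse-frequency class
  weights would place the optimum for a normal patch near probability 0.5.
  The concatenated max-pool channel preserves focal minority textures inside
  a patch; the L2 normalization puts features on the unit sphere so a rare
  texture is separable by direction without becoming a norm outlier that
  dominates every downstream linear map.
* **Attention module (AM).** Two-layer tanh attention (hidden width 128,
  gated variant behind the `gated` flag): one logit per patch, softmax over
  the bag. Attention scores are in [0, 1] and sum to 1; the slide-level "WSI
  deep feature" is the score-weighted average of the FVs (512-d).
* **Classification module (CM).** Affine map 512 → 1 with logistic output:
  the probability that the slide is LNM-positive.

Training minimizes class-weighted binary cross-entropy on bag labels with
Adam (lr 1e-3, 30 epochs, bags in mini-batches of 8). By default the FE is
frozen after pretraining and bag features are precomputed, which makes
bag-level training cheap; `finetune_fe=True` backpropagates through the
encoder. The CM weight vector is warm-started from the (normalized)
pretraining head: with still-uniform attention the initial bag logit is then
the mean patch evidence score, which gives the attention module a useful
gradient and avoids the cold-start failure mode where attention settles on
diluted mean pooling. Bags above 500 patches are subsampled (seeded) during
training and used in full at inference. All randomness flows from the
caller's seed; two runs with the same seed produce bit-identical weights.

## Evaluation protocol

Four train/test "versions" are built from one global class-by-specimen
stratified 80/20 patient-level split: Version 1 restricts both sides to
surgical patients; Version 2 uses the split as-is; Versions 3 and 4 keep the
full training set and restrict the test set to surgical respectively
endoscopic patients — so the version-3 and version-4 test sets partition the
version-2 test set exactly. Per-stratum training counts are floor(0.8·n)
with largest-remainder reallocation to match the per-class totals; remainder
ties go to the endoscopic stratum. On the study's stratum sizes (71/329
endoscopic and 101/780 surgical positive/negative patients) this reproduces
the published composition exactly (e.g. Version 1: 80/624 train and 21/156
test; Version 2: 137/887 and 35/222).

Training uses stratified 5-fold cross-validation at patient level; each fold
model's FE is pre-trained only on that fold's training patients. The five
fold models are ensembled on the held-out test set: probabilities are
averaged over models per slide, then over slides per patient. The operating
point is chosen by the Youden index (J = sensitivity + specificity − 1) over
all midpoint thresholds, ties resolved toward higher sensitivity, then the
lower threshold; by default the cutoff is selected on the held-out test
predictions (whether the original protocol selected it on CV or test
predictions is ambiguous; both are possible via the API).

The clinical-utility panel compares the model with the guideline strategy
that sends every high-risk patient to surgery (an all-positive classifier:
100% sensitivity, 0% specificity). *Unnecessary additional surgery* =
100 − PPV, *missed LNM* = 100 − sensitivity; percentages are rounded half-up
to one decimal (two for the lymph-node ratio) to match printed clinical
tables, and the "reduction in unnecessary surgery" is the difference of the
rounded values. Published panels are bridged to integer confusion counts by
nearest-integer rounding of rate × n. Strategies are compared with McNemar's
test on paired per-patient correctness (exact two-sided binomial when the
discordant count is below 25, else continuity-corrected chi-square); one p
per comparison is reported, since a per-metric-row p cannot be reconstructed
from a single paired table. A random-forest baseline (500 trees) on the
clinicopathologic covariate table runs under the same CV/ensemble protocol.

## Synthetic data

No public slides exist for this problem, so the `cohort` module generates
the study conditions at desk scale:

* **Cohort.** Two strata — endoscopic (default LNM prevalence 17.8%) and
  surgical (6.6%) — with covariates sampled independently per stratum from
  distributions shaped like the study table (age, sex, BMI, comorbidity,
  family history, smoking, alcohol, location, cancer size, submucosal depth,
  differentiation, LVI, budding, resection margin, MSI). Surgical records are
  never margin-positive. In the default `informative_covariates` mode LVI and
  budding are enriched in positives, so the random-forest baseline can beat
  chance, as a clinicopathologic model should; covariate realism is otherwise
  cosmetic. 10% of patients contribute two slides (the study reports more
  WSIs than patients but not the multiplicity; this is a free choice).
* **Slides.** Near-white background; tissue is a smooth blob (thresholded
  smoothed noise) with a pink low-frequency "gland" texture. Endoscopic
  specimens cover ~10–25% of the raster, surgical ~30–60%, reflecting that
  endoscopic resections contain only part of the submucosal layer. Per-slide
  stain variability (overall strength, colour tint, gland wavelength, nuclei
  density) emulates staining/scanner variation between slides.
* **Planted signal.** Every slide spends the same "dark foci budget"
  (uniform 5–9% of tissue area) on salient dark-speckle disks. In negatives
  the budget is filled entirely with a label-irrelevant *distractor* texture
  (inflammation-like); in positives, 5% of tissue (the `evidence_fraction`)
  is the *evidence* texture — emulating budding/micropapillary foci — and the
  remainder is distractor. Evidence and distractor share dot density,
  darkness and geometry and differ only in hue, by about the magnitude of
  inter-slide stain variation. Consequently (a) total salient area carries no
  label information, (b) an encoder without supervised refinement cannot
  separate the classes, while (c) patch pretraining on thousands of patches
  learns the hue signature reliably. The evidence mask is stored as ground
  truth for localization diagnostics only; the model never sees it.

What the generator does **not** emulate: H&E stain chemistry, pyramidal
multi-resolution formats, scanner colour profiles, nuclei-level morphology,
or correlated covariates. Passing the synthetic benchmark therefore shows
that the implementation learns a planted minority texture from bag labels,
localizes it, and behaves like a null under permutation — not that the model
would reach any particular AUC on real histology.

## Benchmark and null

The default benchmark is 230 patients (80 endoscopic + 150 surgical, 15%
prevalence in both strata, ≈250 bags), 512×512-px slides, 64-px patches,
tissue-fraction threshold 0.5 — sizes chosen so the full pipeline runs in a
few minutes on one CPU while keeping ≥6 patches in the smallest bags. The
generator's full-scale default remains 2048×2048 px with 256-px patches.

The label-permutation null retrains the *entire* pipeline (patch pretraining
included) on permuted training labels and scores the held-out test set
against the true labels. The reported null AUC is the **median over 7
permutations**: with a strong planted signal and ~28 positive training
patients, an occasional permutation retains (or inverts) a real fraction of
the label–evidence association, and its retrained model honestly scores an
extreme AUC; the median reports where the null distribution is centred.
Attention localization is the fraction of positive test bags in which
evidence-overlapping patches receive a higher mean min-max-normalized
attention score than the remaining patches. Patch-level extractor quality is
summarized as *balanced* accuracy (at the Youden point of the head scores)
of evidence-vs-normal classification on held-out ground truth; plain
accuracy would reward ignoring the minority evidence class.

## Numerical conventions and edge cases

* Percent rounding: half-up (`Decimal`), one decimal (two for the LN ratio).
* Count reconstruction from published rates: nearest integer, .5 up.
* Youden candidates: ±∞ plus midpoints between adjacent distinct scores;
  prediction rule "score > threshold".
* Degenerate utility panels (one-class inputs) use the 0/0 → "all correct"
  convention so the all-positive guideline is defined on any label vector.
* Min-max normalization of a constant attention vector returns all zeros: a
  bag with no informative patch renders visually null.
* Empty tissue masks tile to an empty bag with a warning, not an error;
  largest-remainder ties are resolved with remainders rounded to 9 decimals
  so float noise cannot decide a genuine tie.
* Heatmaps use a fixed colormap ("inferno") and carry no timestamps, so
  rendering is byte-stable.

## Known limitations

* The FE is a deliberately small encoder; it is not a stand-in for a modern
  pathology backbone and the 512-d width is the only architectural constraint
  carried over from the protocol being implemented.
* The synthetic task is far easier than real histology: near-ceiling AUCs on
  the benchmark say nothing about clinical performance.
* Patient-level aggregation over multiple slides is the mean probability;
  the original protocol does not state its rule.
* The four versions share one randomization (their published test counts nest
  exactly); independently drawn versions are available via different seeds.
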