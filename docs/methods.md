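# Methods

## Problem and model

Pathological myopia (PM) is a degenerative form of high myopia whose
fundus correlates (notably the parapapillary atrophy crescent next to the
optic disc) are visible in retinal photographs, while risk is also carried
by genetic variants and demographic/behavioral factors. `pmfusion`
implements a screening classifier that fuses three heterogeneous data
sources — retinal fundus images (I), panel SNP genotypes (G) and
demographic/clinical covariates (D) — with a multiple-kernel-learning
(MKL) SVM, and an evaluation harness that compares every non-empty subset
of the three sources under a balanced cross-validation protocol.

### Classifier

Each modality `m` contributes a linear basis kernel
`K_m(x, x') = <x^m, x'^m>` over its `[0,1]`-scaled feature vectors. The
fused kernel is the convex combination

    K = sum_m beta_m K_m,   beta_m >= 0,  sum_m beta_m = 1,

and a soft-margin SVM (hinge loss, penalty `C`) is trained on `K`. The
learned `beta` reports the relative discriminative contribution of each
source.

* **SVM dual solver.** SMO-style pairwise coordinate ascent with
  maximal-violating-pair working-set selection, stopping when the largest
  KKT violation falls below `tol` (default `1e-3` standalone, `1e-9`
  inside the MKL loop). The bias is recovered from the free support
  vectors, or the midpoint of the feasible interval when none are free.
  Tests certify optimality against an independent SLSQP solve of the dual
  and via the primal–dual gap.
* **Kernel-weight update.** L1-norm MKL: after each SVM solve the weights
  are reset to `beta_m ∝ ||w_m||`, where
  `||w_m||^2 = beta_m^2 (alpha y)^T K_m (alpha y)`. This is exact block
  coordinate descent on the group-lasso primal
  `1/2 sum_m ||w_m||^2 / beta_m + C sum_i xi_i`, so the tracked objective
  is non-increasing; iteration stops when its relative decrease drops
  below `1e-5` (at most 100 outer iterations). Weights start uniform at
  `1/M`. Published MKL solvers differ in how they regularize the kernel
  weights; the simplex/L1 formulation is this package's documented
  choice, with the degenerate-equivalence and duplicated-kernel tests
  pinning its behavior.
* **Decision rule.** `score = sum_i alpha_i y_i sum_m beta_m <x_i, x_t> + b`;
  positive scores predict PM, a score of exactly 0 predicts the negative
  class (ties break conservatively toward "no disease" — in screening a
  degenerate all-zero feature vector carries no evidence).
* `C` is fixed at 1 by default (configurable); no tuning grid is built in.

## Image arm (bag of visual words)

Images are resized to height 256 (bilinear, aspect preserved), the green
channel is used (retinal structure contrasts best there), and analysis is
restricted to a disc of 0.95 of the field-of-view radius to avoid rim
artifacts. Interest points come from two complementary detectors over a
5-level scale pyramid (sigma doubling from 1.2): multiscale Harris
(corners; structure tensor at integration scale sigma, k = 0.04) and the
scale-normalized determinant of Hessian (blobs), each with Laplacian
scale selection (a candidate survives only where `sigma^2 |LoG|` is
maximal across neighboring levels). Relative response thresholds (1% and
2% of the per-image maximum, with small absolute floors) put a typical
fundus image at a few hundred keypoints; a structureless raster yields
none, and such images produce a zero BOW vector with a warning rather
than an error — a screening batch must not abort on one bad image.

Each keypoint is described by a 128-bin SIFT histogram (4x4 spatial cells
x 8 orientation bins, cell width 3 sigma, frame rotated to the dominant
gradient orientation, trilinear binning, Gaussian spatial weighting,
L2-normalize / clip at 0.2 / renormalize / quantize to 0–255 integers).
Keypoints whose support window leaves the raster are dropped and logged.

Two numerical choices matter for reproducibility:

* the raster is mean-centered before response and gradient computation —
  truncated Gaussian-derivative kernels do not sum exactly to zero, so a
  uniform brightness shift would otherwise perturb the responses and
  change the detected set;
* detector responses are quantized at 1e-6 relative precision before peak
  selection, making peak ordering (and hence the full image -> BOW path)
  an exactly reproducible function of the raster bytes.

The codebook is k-means (k = 100 by default) over descriptors pooled from
a seeded random half of the images, built once per cohort at assembly
time — not per CV fold; rebuilding 200 codebooks per evaluation would
dominate runtime for no inferential gain, and the codebook construction
never sees labels. Encoding assigns each descriptor to its nearest
centroid (Euclidean, ties to the lowest index) and L2-normalizes the
count histogram (L1 available by config); the un-normalized counts always
sum to the number of surviving descriptors.

## Genotype arm

Calls are read from a TSV of allele-pair strings (or VCF via cyvcf2) and
polarized to minor-allele counts (ties at MAF 0.5 go to the
alphabetically first allele). QC removes, in order: subjects with more
than 5% missing calls; then SNPs that are monomorphic, non-autosomal,
below 1% MAF, or out of Hardy-Weinberg equilibrium at p < 1e-6 by the
exact conditional test (probabilities of all heterozygote counts
compatible with the observed allele totals, summed over configurations no
more probable than the observed one; computed in log space; verified
exhaustively against a full-enumeration oracle for all tables with up to
20 subjects). These thresholds are conventional GWAS-QC values and are
config-exposed. Columns are then restricted to the shipped
myopia-susceptibility panel (57 rs IDs from linkage loci MYP2/3/7/11–14,
TGIF and GWAS loci GJD2, RASGRF1, CTNND2, MIPEP, ZC3H11B, LAMA2, CD55,
ZNF644, BLID, GLULP3), in panel order, and encoded additively
({0,1,2} -> {0, 0.5, 1}) with missing calls imputed by the per-SNP
training-set mode. Live database discovery of the panel (OMIM / GWAS
catalog / tag-SNP expansion) is deliberately out of scope: web resources
drift, so the panel ships as a versioned file.

## Demographic arm

Cleaning removes columns with more than 5% missing values first (rows are
the scarcer resource), then rows over the same threshold, then imputes
the remainder (median / mode from the fitting subjects). Categorical
levels are digitized in lexicographic order and every column min-max
scales to [0,1] with parameters fitted on training subjects only;
out-of-range test values clip. A univariate screen (Welch t-test for
numeric, chi-square without continuity correction for categorical
columns) is reported for inspection only — all surviving variables enter
the classifier, since no principled selection rule exists at the screen's
raw p-values.

## Evaluation protocol

Prevalence in the target population is a few percent, so training on raw
splits would be hopeless. Per test: a stratified random half-split A/B
(per-class counts differing by at most 1; odd counts favor A); round 1
trains on all A-positives plus an equal-count seeded random draw of
A-negatives and scores all of B; round 2 swaps halves. Ten tests give 20
result groups per method. Every method within a (test, round) uses the
identical split and negative draw — RNG streams are derived from the
master seed by fixed offsets, so adding methods never perturbs splits —
making the paired t-test on matched per-group AUCs valid. Min-max scalers
are refit on each balanced training set; single-modality methods take the
plain SVM path and multi-modality methods the MKL path.

Metrics: ROC by threshold sweep (score >= threshold predicts positive,
sentinel at (0,0)); trapezoidal AUC (equal to the tie-corrected
Mann-Whitney statistic, tested against a pairwise-count oracle);
sensitivity at specificity 0.85 by linear interpolation between the
bracketing ROC vertices (interpolation rather than step, documented
choice); balanced accuracy = (sensitivity + specificity)/2.

## Synthetic cohort generator

No suitable cohort with matched images, genotypes and covariates is
publicly deposited, so the generator fabricates one with known truth,
mirroring the target study's scale: 2,258 subjects at prevalence 58/2258
by default (scaled to 600 in the shipped tests and acceptance script for
desk runtime — problem sizes stated here are the package's own choices).
Exactly `round(n * prevalence)` subjects are cases. Conditional on the
label the three modalities are generated independently, so their signals
are complementary by construction:

* **Genotypes** — founder frequencies ~ U(0.1, 0.5); controls in HWE;
  case genotype probabilities proportional to HWE x OR^(minor count)
  (additive risk), with 8 causal panel SNPs at OR 2.0; 1% missing calls.
  Chromosomes follow the panel loci, so the two X-linked panel SNPs are
  exercised by the non-autosomal QC filter.
* **Demographics** — 30 numeric + 14 categorical variables (categoricals
  by thresholding a latent normal); 5 variables carry a 0.4 SD case mean
  shift; 2% missingness.
* **Images** — 512x512 stylized fundus: dark circular field, jittered
  bright optic-disc ellipse, vessel-like dark polylines, Gaussian noise;
  positives get a crescent-shaped bright rim adjacent to the disc with
  contrast 0.8 by default (contrast 0 makes classes pixel-statistically
  indistinguishable).

What the generator does **not** emulate: realistic retinal texture, LD
between panel SNPs, population structure, correlated modalities,
label noise. Passing tests therefore demonstrate pipeline correctness
and the fusion property under complementary signal — not clinical
performance on real cohorts. On this renderer the image arm saturates
near AUC 1.0 at the default contrast; the demographic arm is weakest and
the SNP arm intermediate, matching the qualitative ordering reported for
real multimodal PM screening.

## Known limitations

* Linear kernels only; no RBF/polynomial, no Lp-norm MKL (p != 1), no
  probability calibration, no multi-class support.
* The SMO solver is dense O(n^2) memory; adequate for the balanced
  training sets this protocol produces (tens to hundreds of subjects),
  not for training on full biobank-scale cohorts.
* The univariate screen reports raw p-values without multiplicity
  correction, by design.
* Codebook and imputation are fit once per cohort (see above); only the
  [0,1] scalers are refit per fold.
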