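# Methods

## The measurement model

A pulmonary nodule on thin-section CT is represented as a 3D grid of
attenuation values (Hounsfield units) with known voxel spacing, plus a
binary mask drawn along the visible nodule boundary. Because hand-drawn
boundaries inevitably include aerated lung (≈ −850 HU), the analyzable
voxel set is the mask *refined* by a nulling rule: voxels below a floor of
−500 HU are discarded before any feature is computed. The floor is
inclusive — a voxel at exactly −500 HU is retained — reading "attenuation
less than −500 HU is discarded" as a strict inequality; the floor is a
parameter (`hu_floor`) for sensitivity analyses. One refined segment feeds
*all* features: intensity statistics, co-occurrence pairing, and
morphology operate on the same voxel set, so nulling also removes voxels
from GLCM pairs and from the surface/volume estimates. Refinement is
idempotent and monotone in the floor. Connected-component cleanup exists
(`keep_largest_component`, deterministic lexicographic tie-break) but is
off by default: the nulling rule alone defines the published segment.

## Features

**First-order.** Mean, SD, variance, skewness, excess kurtosis of the
retained HU values. SD/variance use the sample convention (n−1; a
population variant via `ddof=0`); skewness and kurtosis are the biased
standardized central moments m₃/m₂^{3/2} and m₄/m₂² − 3 with 1/n
weighting. Degenerate inputs are errors, not NaNs: fewer than 2 (or 3)
voxels, or zero variance with a standardized moment requested.

**Second-order (GLCM).** Gray levels are `floor((HU − min HU)/w)` with
default bin width w = 1 HU, i.e. levels essentially are HU values. This
unusually fine quantization is deliberate: the magnitudes volumetric
nodule analysis reports for these features (ASM and IDM of order 10⁻³–10⁻²,
contrast of order 10⁴–10⁵ HU², entropy of a few nats) only arise when the
level count is on the order of the HU range; conventional 32/64-level
binning produces IDM and ASM two orders of magnitude larger. One
co-occurrence matrix is accumulated over the 13 unique grid directions at
Chebyshev distance 1 (counted symmetrically, normalized to sum 1), because
a single scalar per feature implies a single direction-pooled matrix;
per-direction feature averaging is available
(`glcm_features_per_direction`) for comparison. Offsets are grid steps,
not physical mm — no anisotropy correction, reasonable at ~1 mm
near-isotropic spacing. Pairs crossing the segment boundary are excluded;
a single-voxel segment has no pairs and is an error. Entropy uses the
natural log by default (base 2 selectable). The matrix is stored sparsely:
with 1 HU bins a calcified nodule can span thousands of levels.

"GLCM moments" has no universally fixed definition; it is implemented here
as the first absolute difference moment Σ P(i,j)·|i−j|. This choice
cannot be validated against an external reference and is flagged as such.

**Morphology.** Volume = voxel count × voxel volume; effective diameter
inverts the sphere volume formula, d = (6V/π)^{1/3}. Surface area defaults
to the area of the 0.5-level iso-surface of the binary segment, extracted
by marching cubes with physical spacing after smoothing the padded
indicator with a Gaussian of σ = 0.5 voxel. The smoothing is an
anti-aliasing step: contouring a raw 0/1 grid facets the surface and
over-estimates convex areas by roughly 8%, which breaks the expectation
that a digital sphere's area approaches the continuum value; with the
smoothed indicator the d = 20 mm sphere at 0.5 mm spacing is within 5% of
π d². A voxel-face-counting variant (exposed faces × face area) is kept as
a conservative upper bound and as the fallback for single-voxel segments.
Wadell sphericity Ψ = π^{1/3}(6V)^{2/3}/A is clipped at 1: the continuum
value is bounded by the isoperimetric inequality, and excesses on very
small digital shapes (a few voxels) are pure discretization artifacts.
Discrete compactness follows Bribiesca's normalization
Cd = (Ac − Ac_min)/(Ac_max − Ac_min) with Ac the number of shared
voxel-face contacts under 6-connectivity, Ac_min = n − 1,
Ac_max = 3(n − n^{2/3}); a k³ cube attains Ac_max exactly, so solid blocks
score 1. Contacts are counted combinatorially (unweighted by anisotropic
spacing) because the definition is lattice-based. A single voxel is
defined as 1.0; a disconnected segment is computed whole with a warning
recorded on the segment. Published volumetric-analysis tables report
*negative* discrete-compactness values with SDs near 0.6–0.9, which are
incompatible with this [0,1] definition — some undocumented transform was
evidently applied upstream there. This package implements the canonical
definition and makes no attempt to match those magnitudes; feature-level
cohort simulation takes the printed summary statistics at face value
instead.

**Conventional arm.** The comparison measurements emulate a reader at a
PACS workstation: on the axial slice with the largest in-plane retained
area (ties to the lower index), the long diameter is the maximum pairwise
in-plane distance between retained voxel centers, and mean/SD attenuation
come from a circular ROI centered at the in-plane centroid with radius
0.8 × (half long diameter + 1.5 mm), evaluated on the raw image *without*
nulling. The 1.5 mm rim margin models the lung-window-visible
partial-volume halo the reader circles; it is what makes the emulation
reproduce the clinically known failure mode — for small nodules the circle
unavoidably samples parenchyma and reads tens of HU lower than the nulled
volumetric mean, a dilution that shrinks with nodule size. Both factor and
margin are config parameters, and no quantitative claim rests on this arm:
the absolute ROI size a human would draw is unknowable, so only the
direction and ordering of the dilution effect are asserted in tests.

## Statistics

**Group comparison.** Pooled (Student) two-sided independent-sample
t-tests are the default: the pooled formula is the one that reproduces,
from the printed group summaries alone, the reference p-values this
implementation is checked against (e.g. 0.002 for subgroup mean
attenuation at (−116.5 ± 91.8, n=7) vs (−242.4 ± 75.7, n=18)). Welch with
Satterthwaite df is available per call. Zero pooled variance is handled
explicitly (t = 0, p = 1 for equal means; an infinite-t flag otherwise).
No multiple-testing correction is applied, matching the analysis being
reproduced.

**Reproducibility.** Two-observer agreement uses ICC(2,1): two-way
random effects, absolute agreement, single measure, from the mean-squares
decomposition, with the standard F-based 95% CI (Satterthwaite df for the
rater term). Interpretation bands: ≥0.90 excellent, ≥0.75 good, ≥0.50
moderate, else poor (boundary membership chosen as closed-below since the
source bands leave it unstated). The second observer is emulated by mask
perturbation — dilation, erosion, or boundary jitter (coin-flip membership
in the band between the magnitude-eroded core and the magnitude-dilated
hull), all seeded.

**Collinearity pruning.** Candidate features (those univariately
significant at 0.05) are clustered by the transitive closure of
|Pearson r| > 0.8; each cluster keeps the smallest-univariate-p feature
(ties to canonical feature order). This representative rule is a
package choice — the analysis being reproduced states only which features
were excluded, not the rule. VIFs (1/(1−R²) from regressing each retained
feature on the rest) are computed for the retained set and values ≥ 5
flagged.

**Model and discrimination.** Logistic regression is fit by maximum
likelihood (statsmodels Newton solver, deterministic); backward
elimination drops the largest-Wald-p predictor while it exceeds 0.10,
refitting each step — the threshold is configurable since the exact
stopping rule upstream is unstated, and 0.10 is the common statistical-
package default. Odds ratios are exp(coefficient) per unit of the
predictor (per HU, per mm) with 95% Wald CIs; the printed reference ORs
(1.014 per HU, 1.745 per mm) are per-unit magnitudes despite a footnote
claiming per-SD scaling, so per-unit is the default and `or_scale="sd"`
provides the alternative. Perfect separation is reported as a flagged,
non-converged model naming the separating predictor rather than as silently
enormous coefficients; a singular (rank-deficient) design raises an error
pointing back at pruning.

ROC thresholds sit at midpoints between consecutive unique marker values
(±∞ sentinels); AUC is the Mann–Whitney concordance probability with ties
counted ½ (identical to the trapezoid area); the operating point maximizes
the Youden index, ties broken toward higher specificity then lower
threshold; the AUC CI uses the DeLong placement-value variance with a
normal approximation truncated to [0,1]. Correlated AUCs on the same
subjects are compared with the paired DeLong test. All of this is
implemented directly (mid-rank placements), with scikit-learn and
brute-force pair counting as independent oracles in the tests only.

## Synthetic data

**Voxel phantoms** emulate the imaging substrate, not lung anatomy: one
nodule (sphere; volume-matched ellipsoid with fixed 0.7:1:1.43 axis
ratios; or a lobulated union of a central sphere and 2–4 offset lobes)
centered in a Gaussian aerated-lung background whose mean must sit below
−500 HU so the nulling rule removes it. Nodule voxels draw i.i.d. from a
Gaussian; calcification sets a random subset of interior voxels (chosen
before blurring) to attenuations uniform in a bone-range window; partial
volume is emulated by Gaussian blurring of the HU grid only — the mask
remains the pre-blur support, so ground truth (analytic volume and
equivalent diameter, generating attenuation parameters) stays exact.
Generators are pure functions of (spec, seed). What phantoms do *not*
model: vessels, airways, pleural attachment, scanner-specific noise
spectra and reconstruction kernels — so passing phantom tests demonstrates
correctness of the computational chain, not clinical performance.

**Feature-level cohorts** draw per-feature values from group Gaussians
((mean, SD) per feature per group), independent by default or coupled by a
user-supplied correlation matrix (Gaussian copula; positive-definiteness
is validated). The default parameters are the published osteosarcoma group
summaries (24 vs 18 total; 7 vs 18 in the ≤5 mm non-calcified subgroup)
recorded in `cohort_params.py`. Gaussian marginals at printed (mean, SD)
can produce physically impossible values (negative variances, ASM outside
(0,1]); for the committed fixture these are clipped at benign floors,
another reminder that the summaries, not a generative model of nodules,
are the anchor.

**The fixture cohort** (42 nodules, committed CSV, seed 20190208) mirrors
the study composition exactly: 24 metastatic of which 7 are small
(effective diameter ≤ 5 mm, clipped) and non-calcified, 17 large (diameter
forced > 5 mm; 8 flagged calcified), and 18 small non-calcified
non-metastatic nodules, so the subgroup filter returns 25 = 7 + 18.
Features are drawn with a latent-factor correlation structure: one
"severity" factor loads every feature in its group-difference direction
(pairwise |r| ≈ 0.36), and the {mean attenuation, SD, variance} and
{diameter, surface area, volume, entropy} clusters share |r| ≈ 0.88.
Without this structure — features drawn independently — eleven strong,
independent group separations make 42 points linearly separable and the
logistic model degenerate, which no real nodule cohort is; with it, the
pruning step reproduces the expected exclusions (SD, variance, surface
area, volume) and the model converges.

## Numerical choices and problem sizes

Quantization bins anchor at the segment minimum; bin centers reconstruct
HU to within half a bin. The logistic Wald z uses Φ⁻¹(0.975); elimination
and all tie-breaks are deterministic, making the full pipeline a pure
function of (inputs, config, seed). Simulation-based checks use 2000
replicates of the 25-subject subgroup for the mean-AUC estimate (Monte
Carlo SE ≈ 0.002, far inside the 0.05 comparison band) and n = 10⁴ for
logistic parameter recovery; phantom convergence checks run at 1.0, 0.5
and 0.25 mm spacing. These sizes were chosen so every stochastic estimate
has sampling error at least an order of magnitude below the tolerance it
is compared at.

## Known limitations

- The GLCM "moments" definition is a documented guess (see above).
- Discrete compactness cannot be reconciled with the negative published
  magnitudes; only its canonical definition is provided.
- The conventional-arm emulation asserts directions, not magnitudes.
- Phantom GLCM magnitudes depend strongly on the (unknown) upstream
  quantization; the 1 HU default reproduces the right orders of magnitude
  for ASM/IDM/contrast but entropy on phantoms runs higher than published
  volumetric values, so no test compares phantom-derived GLCM features to
  published tables — feature-level cohort simulation covers those.
- ICC model choice (two-way random, absolute agreement) is the documented
  default; consistency-type ICCs are not implemented.
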