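# Methods

This note records the models implemented by `wmhkit`, the assumptions behind
them, the default parameter values and why they were chosen, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.  Every empirical number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## 1. WMH detection model

Detection works on a skull-stripped FLAIR volume restricted to
`brain AND NOT exclusion` (the exclusion mask stands for cerebellum and
brainstem, where WMH are rare and bright artifacts common).

**Masked smoothing.** The image is smoothed with a Gaussian kernel of
2 mm FWHM (σ = FWHM / (2√(2 ln 2)) ≈ 0.85 mm).  Near the mask boundary the
kernel is renormalized: `smooth(img·mask) / smooth(mask)` inside the mask.
Naive convolution would mix in the zeroed background, depress edge
intensities, and bias the intensity histogram that the threshold is computed
from; renormalization preserves constants exactly (a property test).

**Threshold.** The WMH threshold is `mean + k·SD` of the in-mask voxels of
the *smoothed* image, with k = 1.5.  The SD is the sample SD (n−1) by
default (`sd_mode="population"` is available); at brain-mask sizes the two
differ by < 10⁻⁵ relative, but the choice is recorded with the result.  An
important and easily overlooked point: this rule only isolates lesions
because the FLAIR brain histogram is **multi-compartment** — dark
CSF/ventricles, a tissue mode, and a thin hyperintense tail.  The dark
compartment inflates the SD and pushes the threshold into the gap above the
tissue mode.  For any unimodal Gaussian image, mean + 1.5 SD would flag
6.7 % of voxels regardless of scale — a useful reminder that the method is
calibrated to FLAIR-like histograms, and the reason the phantom generator
renders ventricles dark (§4).

**Binary map, manual correction, labeling.** Voxels strictly above the
threshold (inside the analysis mask) form the binary WMH map.  A removal
mask can be subtracted (`edited` flag recorded), mirroring the visual
inspection step of semi-automated protocols.  Connected components are
labeled under a 26-neighbourhood by default (6/18 configurable; the
literature rarely states one, and 26 is the most inclusive).  Lesion volume
is voxel count × voxel volume, always in mm³.

**Compartments.** A component is *periventricular* iff the minimum
voxel-center distance from the component to the ventricle mask is
≤ 10 mm, else *subcortical*.  The 10 mm distance-to-ventricle rule is the
most common convention in the WMH literature, but it is a convention of
this package: published volumetry tables that report the split generally do
not define it, so the split cannot be validated against them — only the
compartment-sum identity (periventricular + subcortical = total) can, and
is.

**Subject classification.** WMH+ iff any single lesion is strictly greater
than 150 mm³.  The inequality is strict by the rule's wording ("greater
than"); a lone lesion of exactly 150 mm³ is WMH−, and the boundary is
tested.

**Open choice.** Whether the original semi-automated protocol computed the
histogram statistics on the smoothed or unsmoothed image is not specified
in the sources describing it; smoothing is listed as the last preprocessing
step, so this package thresholds the smoothed image, with the statistics
taken from the same smoothed image.

## 2. Cohort statistics

**Matching.** Cases are paired one-by-one to distinct controls with
|Δage| ≤ 3 y, |Δeducation| ≤ 1 y, same gender.  The matcher is greedy in
order of scarcity (cases with the fewest eligible partners first; ties by
smallest |Δage| then |Δeducation|).  Greedy matching is not guaranteed
optimal; an exhaustive bipartite-matching oracle in the tests confirms it
pairs every case on solvable instances of the sizes used here.  Unmatched
cases are an error listing their ids (the pipeline reports them and
continues, since downstream models use the full cohort).

**Univariate screens.** One binomial logistic regression per predictor,
fitted by Newton/IRLS maximum likelihood to relative tolerance 1e-8
(statsmodels).  Reported: likelihood-ratio model χ² (1 df), OR = e^β, 95 %
Wald CI (z = 1.959964), coefficient p, effective n after listwise deletion.
For a binary predictor the ML odds ratio equals the 2×2 cross-product ratio
ad/bc; the tests verify agreement to 1e-6.  Perfect separation is flagged
on the result and warned about, never silent.

**Tolerance screen.** For each group separately, each surviving predictor j
is regressed (OLS) on the remaining ones; tolerance = 1 − R²ⱼ.  A predictor
enters the multivariable model only if tolerance ≥ 0.30 in **both** groups —
the stricter of the possible readings of a per-group screen, chosen so that
collinearity in either group disqualifies.  Duplicated or constant columns
get tolerance 0.

**Box–Tidwell.** Linearity of the logit is checked by adding X·ln(X) terms
for all retained predictors to one joint logistic model and Wald-testing
each added term (χ², 1 df); any p < 0.05 marks the model invalid.
Instrument scores are non-negative integers, and ln(0) is undefined: zeros
are replaced by +1 before the logarithm (configurable shift), which maps
their augmented term to 0 — the continuous limit of x·ln(x) at 0.  Under a
truly linear logit the test's type-I error is 0.038–0.052 at α = 0.05
(500 reps, n = 1000, two seeds measured); under a strong quadratic logit at
n = 2000 its power is 1.0 (200 reps).

**Multivariable model.** ML logistic fit of group on all retained
predictors after listwise deletion; adjusted ORs with Wald CIs; whole-model
LR χ² (df = number of predictors); pseudo-R² reported as **Nagelkerke**
(named explicitly, since "adjusted R²" in clinical reports is ambiguous),
with Cox–Snell and McFadden also emitted; classification accuracy at the
P̂ ≥ 0.5 ⇒ WMH+ cutoff, overall and per group, with per-group effective n —
listwise deletion makes the two group denominators differ, which is why
accuracies are reported per group.

## 3. ROI morphometry

Voxelwise two-sample pooled-variance t inside the ROI mask
(t = (mean_A − mean_B)/SE; zero pooled variance ⇒ t = 0 with a warning).
FWE control uses the permutation max-statistic: relabel groups, record the
in-ROI maximum of the test statistic (|t| two-sided), and set each voxel's
FWE p to the proportion of permutation maxima at least as large as its
observed statistic.  When C(n, n_A) ≤ the requested permutation count, all
distinct relabelings are enumerated (p = k/N, smallest attainable p = 1/N);
otherwise Monte-Carlo relabelings with the add-one estimate
(1 + k)/(1 + B).  This is a deliberate substitution of an exact,
distribution-free procedure for the parametric random-field small-volume
correction of SPM-style software: random-field theory needs smoothness
estimation machinery out of scope here, while permutation gives exact FWE
control for exchangeable data at these problem sizes.  Measured familywise
false-positive rate under null grey-matter maps: 0.035–0.045 over 200 runs
(two seeds measured), compatible with the nominal 0.05 (slightly
conservative, as add-one Monte-Carlo p-values are).

Voxels at FWE p < 0.05 are grouped into 26-connected clusters; clusters
below the 50-voxel extent threshold are discarded (extent applied *after*
FWE, matching the reporting convention "FWE p < 0.05 and cluster extent
50").  Peaks are maxima of |t| with world coordinates via the affine.  The
group contrast of scientific interest (controls > WMH+, i.e. a deficit) is
directional, so the power experiments use `side="greater"`; the default for
general use remains two-sided.

## 4. Synthetic-data generators

**FLAIR phantoms.** 64³ voxels at 2 mm isotropic — desk-scale, while
keeping the 150 mm³ rule non-trivial (18.75 voxels).  The brain is an
ellipsoid (52×60×44 mm semi-axes), with two ellipsoidal lateral ventricles
and an inferior-posterior exclusion blob standing in for
cerebellum + brainstem.  Tissue intensity is 100 with additive white
Gaussian noise of SD 5 (SNR 20, typical of 3 T FLAIR); ventricles are
rendered at intensity 40 (12 SD below tissue) because FLAIR nulls CSF.
The dark-CSF compartment is not cosmetic: it is what makes the mean+1.5 SD
threshold land between tissue and lesions (§1).  Lesions are ellipsoids
rasterized by center-of-voxel inclusion, so the true volume is an exact
voxel count; they must lie inside the brain, clear of the ventricles, and
pairwise disjoint (overlap would make per-lesion truth ambiguous).  Lesion
intensity before noise is mean + k·SD with k = 4 for "clearly detectable"
(k ≥ 3 clears the threshold by construction at 2 mm smoothing).  The
default phantom carries lesions of radii 5/7/9 mm = 81/179/389 voxels =
648/1432/3112 mm³ — one deep (subcortical) and two periventricular — a
per-subject load within the range published for WMH+ subjects.  Measured
recovery: matched detected volumes within ±12.3 % of truth over 20 seeds
(mean −2 %), with scattered 1–3-voxel false-positive specks, none near
150 mm³.

*Not emulated:* scanner physics, bias fields, Rician noise, partial-volume
ramps at lesion edges, registration misalignment, grey/white tissue
contrast, anatomically shaped ventricles or lesions.  Passing recovery
tests therefore show the algorithmic chain is correct and well calibrated
for FLAIR-like histograms — not that the detector's absolute accuracy on
clinical images equals the measured ±12 %.

**Cohorts.** 2·n_per_group subjects with jointly Gaussian instrument scores
(exchangeable correlation 0.3 by default), clipped at 0 and rounded to
integers — the recorded values feed the generating logit, so the model is
exactly the model of the recorded data and odds-ratio recovery has no
truncation bias.  Group labels are Bernoulli with
logit = intercept + Σ βⱼ·scoreⱼ (intercept defaults to the score-mean
centering value, giving a balanced marginal).  Default predictors are six
neuropsychiatric-style instruments with generating per-point ORs between
1.11 and 1.24.  Missing scores are MCAR per cell — the simplest mechanism
consistent with listwise deletion downstream.  Demographics (age 64 ± 7,
education 13 ± 3, gender 1:1) are drawn independently of group, matching a
matched-cohort design in expectation.  Refitting a univariate model on
n = 20,000 subjects generated at OR 1.18 recovers 1.1806–1.1808 (seeds
measured), well within ±0.03.

**Grey-matter maps.** Constant density baseline 0.5 plus smoothed Gaussian
noise; the smoothed field is rescaled by the exact l2 norm of the discrete
kernel so the marginal per-voxel SD stays at noise_sd (0.08) under the 6 mm
FWHM smoothness default — "effect of 2 SD" therefore means Cohen's d = 2 at
every voxel.  The WMH+ group has effect_size (default 0.16) subtracted at
every ROI voxel, so the in-ROI mean difference equals the planted effect in
expectation and is 0 outside.  The ROI is an ellipsoid of ~470 voxels on a
32³ grid at 1.5 mm, a hippocampal stand-in.  Maps are not clipped to [0, 1]
(clipping would bias the planted mean difference); with these defaults
out-of-range values are ~10⁻⁵ probable.

## 5. Numerical choices and degenerate inputs

- All logistic fits: Newton scoring, tol 1e-8, max 200 iterations;
  separation caught (PerfectSeparationError, non-finite SEs, |β| > 50) and
  flagged.
- Wald CIs use z = 1.959964 throughout.
- Permutation tie comparison uses an absolute 1e-10 slack so the identity
  relabeling always counts against its own statistic and two-sided p-values
  are invariant to swapping group labels.
- Empty WMH map ⇒ empty lesion table (not an error); empty brain mask ⇒
  error; grid mismatches name the offending input.
- `n_permutations` below the number of distinct relabelings triggers
  exhaustive enumeration automatically.
- Pipeline stats stage with fewer than 3 subjects in either detected group
  reports a degenerate outcome and skips the model fits rather than failing.

## 6. Problem sizes used by the validation experiments

Chosen to make every experiment a routine desk-scale run: 20 phantom seeds
for lesion recovery; n = 20,000 for OR recovery; 500/200 replicates for
Box–Tidwell type-I/power; 200 null runs (ROI ~470 voxels, 15 vs 15
subjects, 500 Monte-Carlo permutations each) for FWE calibration and 50
seeded runs for deficit power.  The whole validation battery completes in
about half a minute on one CPU.

## 7. Known limitations

- Spatial normalization is not implemented; all subjects must share one
  grid (true by construction for synthetic data), and overlap maps error
  otherwise.
- The periventricular/subcortical split is a convention (§1); absolute
  compartment volumes from other implementations need not match.
- Greedy matching can fail on adversarial instances where a perfect
  bipartite matching exists; it reports rather than solves them.
- The permutation test assumes exchangeability under the null; covariates
  (age, intracranial volume) are not modeled.
- Box–Tidwell's zero-shift is one of several conventions for zero-valued
  scores; results for predictors with many zeros depend mildly on it.
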