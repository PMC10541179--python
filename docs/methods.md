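# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## EZ-diffusion estimation

The EZ closed form maps the observed moments of one participant-task —
accuracy over all trials, mean and unbiased (n−1) variance of correct-trial
RTs — to drift rate, boundary separation and non-decision time.  Choices:

* **Scaling constant** `s = 0.1`, the conventional diffusion scaling; all
  drift rates and boundaries are reported on that scale.
* **Edge correction** for accuracies of exactly 0, ½ or 1: the half-count
  rule `1/(2n)` (Pc = 1 → 1 − 1/(2n), Pc = 0 → 1/(2n), Pc = ½ → ½ + 1/(2n)).
  This keeps all-correct participants usable.  A chance-level participant
  with no usable correction is an error, not an imputation.
* **Trial QC** (per participant-task, across all conditions): RTs below
  200 ms are removed first; then a *single pass* removes trials more than
  3 sample SDs from the mean of the floor-filtered RTs.  The 3-SD rule is
  deliberately not iterated.  A participant-task with a single correct trial
  has an undefined RT variance and is excluded rather than imputed.
* `ez_forward` is the exact algebraic inverse of `ez_estimate`; the
  round-trip identity holds to machine precision and is enforced in the
  tests at 1e−10.

The Wiener simulator is an independent stochastic oracle: Euler–Maruyama
with `dt = 1 ms`, unbiased start at `a/2`, increments N(v·dt, s²·dt),
absorption at 0 and `a`.  Plain Euler absorption checks have an O(√dt) bias
(the process can cross a boundary inside a step and come back); we remove it
with the Brownian-bridge correction, absorbing between grid points with
probability `exp(−2·d₀·d₁/(s²·dt))` for endpoint distances d₀, d₁ from the
boundary.  With this correction, EZ estimates from 5·10⁴ simulated trials
agree with the generating parameters within 3 bootstrap MC standard errors.

Condition contrasts (attention networks and the distance effects) are plain
differences of condition-cell parameters: alerting = no-cue − double-cue,
orienting = central − spatial, executive = incongruent − congruent,
distance = far − near (digit) and 135° − 45° (rotation).  The digit
distance bins are a package choice (the split is not externally specified):
numerical distance ≤ 3 is "near" (21 pairs), ≥ 4 is "far" (15 pairs).

The composite visuomotor score is the mean of the three per-task z-scored
non-decision times and requires all three tasks (listwise); a mean of three
z-scores has no principled imputation rule for missing components.

## MRS quantification

Starting point: already-quantified metabolite-to-water amplitude ratios with
CRLB (%), SNR and voxel tissue fractions.  The partial-volume correction
uses the literature water concentrations 43300 / 35880 / 55556 mmol/L for
GM / WM / CSF and divides by (1 − fCSF), assuming CSF carries no
metabolites.  The additional T2 step multiplies by `exp(−TE/T2)` — kept in
this multiplicative form for fidelity with the quantification pipeline this
package mirrors, although the conventional relaxation correction *divides*
by the attenuation factor; users combining this output with other pipelines
should be aware of the sign of the convention.

The tissue-water T2 comes from a biexponential fit of the unsuppressed
water integrals over the 13-echo series (32 … 4040 ms) with the CSF T2
fixed at 740 ms and three free parameters.  Numerics: trust-region least
squares with T2 bounds [10, 300] ms and non-negative amplitudes;
initialisation of the CSF amplitude from the longest echo and of the tissue
component from a log-linear fit of the first six echoes; tolerances 1e−15 so
noiseless data are recovered to ≤1e−6 relative.

Exclusions: CRLB > 50% flags that metabolite as not detectable (the
participant's other metabolites survive); SNR values more than 3 sample SDs
from the per-region (and per-wave, when present) mean remove the
participant's whole acquisition in that region.  CRLB flagging runs first;
the order is immaterial because the rules touch disjoint fields.

## Connectivity scoring

The visuomotor network is the fixed 7-ROI set (4 visual, 3 sensorimotor
nodes).  Per participant: optional least-squares nuisance regression of
supplied confound columns, 4th-order zero-phase Butterworth high-pass at
0.01 Hz (sampling interval 0.933 s), frame censoring at framewise
displacement > 2 mm with participant exclusion when *strictly more than* 5%
of frames are removed, then Pearson correlations over the 21 ROI pairs on
retained frames, Fisher r-to-z, and the mean over pairs.  Filtering runs on
the full time base before censoring (the filter needs a contiguous series).
The pairwise-mean definition of "within-network connectivity" follows the
ROI-to-ROI convention; a network-level summary (eigenvector weighting,
seed-average) would differ slightly and the choice is documented here
because the upstream convention is ambiguous.

## Moderated regression and inference

All study-level models are OLS on z-scored (sample SD, n−1) continuous
variables, with interaction terms formed as products of the z-scored
components — *not* z-scored products — so that the ±1 SD simple-slope
algebra (slope at level k = β_focal + k·β_interaction) is exact.
Standardization happens on each model's analysis sample after listwise
deletion and exclusions, and is repeated inside every bootstrap resample so
each draw reproduces the full estimation procedure.

* **Case bootstrap**, B = 5000 by default: percentile CIs (95% for
  regressions, 90% for mediation indirect effects);
  `p_bo = 2·min(#{β* ≤ 0}, #{β* ≥ 0})/B`, floored at 2/B.  Percentile
  rather than BCa intervals: exactly reproducible without acceleration
  constants, at the cost of a small divergence from macro implementations
  defaulting to BCa.
* **Residual exclusion**: after an initial fit, cases with |standardized
  residual| > 3 are removed and the model is refitted *once*; the bootstrap
  runs on the post-exclusion sample.
* **3-SD screens**: neurochemical, connectivity and behavioral scores are
  screened per variable within the five developmental bands (6–7, 10–11,
  14–15, 16–17, 18+ years); age itself enters every model as continuous
  years (centered by the z-scoring).  Groups below 3 members are skipped
  with a warning.
* **FDR**: Benjamini–Hochberg step-up over the enumerated families
  (3 diffusion parameters × 3 neurochemicals × 2 regions × 2 effect types
  = 36; the supplementary design multiplies by 5 cognitive functions
  = 180).  The implementation is the statsmodels step-up; the tests verify
  exact equivalence with a naive quadratic-time threshold search.

## Moderated mediation (model 59)

Two OLS equations on standardized variables, `M ~ X + W + XW` and
`Y ~ X + W + XW + M + MW`; the conditional indirect effect
ω(w) = (a₁ + a₃w)(b₁ + b₂w) and direct effect c₁′ + c₃′w are evaluated at
w = −1, 0, +1 (moderator SD units, exact because products are formed after
z-scoring).  Both equations are refitted in every bootstrap resample and
ω is percentiled per moderator level; an effect is called significant when
its 90% interval excludes zero.  Note the known behavior of product-form
tests: when *both* constituent paths are null the interval is conservative,
so the size simulation in the tests places the null on the b-path only.

## The synthetic cohort

The generator draws ages uniformly within the five bands and builds all
structural relations on the standardized scale: each latent (neurochemistry
per region, connectivity, the three diffusion latents, intelligence) is a
linear-plus-product combination of its parents with an analytically solved
residual SD so that every latent has unit population variance.  Generating
coefficients are therefore directly comparable to recovered standardized
betas.  Observables are built by inverting the analysis stage that will
consume them:

* raw MRS ratios = true concentration ÷ the partial-volume factor of the
  sampled tissue fractions (so the correction recovers truth exactly);
* behavioral trials from the Wiener simulator at the participant's
  parameters, with small fixed condition offsets (cue → Ter, flanker/
  distance → drift) so the contrast scores are non-degenerate; an
  "analytic" mode emits the exact forward moments instead of trials;
* ROI series from an equicorrelated factor model whose target mean-z is a
  linear function of the connectivity latent ("exact" mode recolors the
  series so the *sample* correlation matches the target exactly);
* intelligence scores via a monotone probit link onto 0–30 items (the
  discontinue rule of the source instrument is emulated only as the bounded
  support).

Non-decision-time latents map to seconds as `Ter = base_task + 0.05·z`,
truncated at 0.1 s (bases 0.35/0.40/0.45 s for the attention, digit and
rotation tasks, matching typical developmental magnitudes); drift and
boundary use analogous affine maps.  A second assessment wave ages
participants forward by 1.75 ± 0.2 years (the interval varies across
participants, which also keeps the two age variables non-collinear in
longitudinal models), retains ~70% of the sample, and carries latent
stability 0.7 for neurochemistry.

Per-equation residual multipliers (`equation_noise`) exist so exactness
tests can switch off a single equation's residual — a *global* zero would
collapse every latent onto age and destroy identifiability.

What passing tests show — and what they do not: the generator reproduces the
moment structure, the moderation/mediation path structure and the printed
design counts, so recovery results validate the estimators under correct
specification.  Real data differ in ways the generator deliberately omits:
RT contaminants and non-diffusion outliers, BOLD autocorrelation and
physiological noise (beyond censorable motion spikes), MRS fitting errors
correlated across metabolites, non-normal age distributions, and item-level
structure in the intelligence test.  Recovery here is therefore a
correctness check of the chain, not evidence about effect sizes in any real
cohort.

## Problem sizes

The recovery studies use 200 replicates at n = 258 (regression families)
and n = 250 (mediations), matching the study-scale samples; the bootstrap
coverage check uses 300 outer replicates of n = 200 with B = 499; the
mediation power/size simulations use 200 outer replicates with B = 299; the
noisy water-T2 study uses 500 replicates at 1% multiplicative noise; the
Wiener oracle uses 5·10⁴ trials.  These sizes were chosen so each check's
Monte-Carlo error is small against its tolerance.

## Known limitations

* Full diffusion-model variants (inter-trial variability parameters,
  likelihood-based fitting) are out of scope; EZ uses moments only.
* The T2 correction is implemented in the upstream pipeline's multiplicative
  convention (see above).
* Percentile bootstrap CIs can undercover slightly at small n relative to
  BCa.
* The supplementary 180-hypothesis family is enumerable (including the
  spatial-numerical association label, which has no defined computation
  here) but `run-all` executes only the main, replication and longitudinal
  families; contrast-level models can be run through the library.
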