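# Methods

`glimpse` is a simulation and analysis pipeline for two-pleasure rating
experiments: an observer views two briefly, simultaneously presented
images and is cued — before (precued) or after (postcued) the display —
to rate the felt pleasure of the left image, the right image, or the
combined pleasure of both, on a 1–9 keypad. A final baseline block
collects each image's rating in isolation (its *single-pleasure*),
which serves as the reference value for all error and model
computations. The package generates the experiment design, simulates
observers under explicit generative models, fits the rival models per
participant with leave-one-out cross-validation (LOOCV), and computes
the reliability and variance statistics that distinguish faithful,
averaging, compressive, and expansive accounts of pleasure reports.

## The model family

Reported pleasure is modelled as a linear transformation of a weighted
sum of the two presented images' single-pleasures:

    P_hat = a + b (w P1 + (1 − w) P2),    0.5 ≤ w ≤ 1.

For one-pleasure trials P1 is the target's and P2 the distractor's
single-pleasure; the candidate models fix a = 0, b = 1 and differ in
the target weight: **faithful** (w = 1), **compulsory averaging**
(w = 0.5), and **partial averaging** (w free in [0.5, 1]). For
combined-pleasure trials P1/P2 are the left/right single-pleasures and
all models fix w = 0.5; they differ in the linear transform:
**faithful averaging** (a = 0, b = 1), **compressive** (a > 0,
0 < b < 1), and **expansive** (a < 0, b > 1). Averaging corresponds to
b = 1; summing the two pleasures would be b = 2. Strict inequalities
are implemented as closed boxes with a 10⁻⁶ margin (a ∈ [10⁻⁶, 8],
b ∈ [10⁻⁶, 1 − 10⁻⁶] for the compressive model, mirrored for the
expansive one); optimisers need closed feasible sets, and the margins
are far below the resolution of the data.

## Fitting and model comparison

Models are fitted per participant by minimising the root mean square
error (RMSE) between predictions and single-trial ratings, separately
per trial-type family and per cue timing (pooling the timings is a
configuration option). Predictions are exact arithmetic — no rounding
or clipping — and are compared with the integer ratings by RMSE.

Every named spec is linear in its free parameters once w is fixed (and
the free-w spec with a, b fixed is linear in w), so the box-constrained
least-squares problem is solved exactly: the unconstrained stationary
point if it is feasible, otherwise the best of the four box edges, each
a one-dimensional convex problem solved by clipping. A multi-start
(5 deterministic starts along the feasible box diagonal) bounded
L-BFGS-B path covers custom specs that free w together with a or b, and
is tested to agree with the exact path. LOOCV refits reuse downdated
sufficient statistics, so a full leave-one-out pass costs O(n) for the
one-parameter specs and O(n) small 2×2 solves for the two-parameter
specs; this is what makes the cohort-scale recovery suites cheap.

Per condition, a model's cohort score is the mean of per-participant
LOOCV RMSEs with its standard error (SD/√n). The reported winner
follows a **paired one-standard-error rule**: a model ties with the
best-scoring model if its mean per-participant excess LOOCV RMSE over
the best is within one standard error of those paired differences;
among tied models the fewest free parameters wins. Two reasons. First,
nested specs can agree to within numerical noise (the partial-averaging
fit with its weight clipped at 0.5 reproduces compulsory averaging's
predictions exactly), so an exact-tie rule would flip on hairline
differences. Second, the SE must be paired: per-participant RMSEs are
strongly correlated across models, and a marginal SEM — inflated by
between-participant noise-level differences common to all models —
would over-penalise complexity.

Participants with a missing single-pleasure simply lose the affected
trials in model fits (they are excluded from a condition only when no
usable trials remain); reliability analyses are complete-case and drop
such participants entirely, with a logged warning in both cases.

## The design generator

Stimulus selection emulates choosing 36 main + 4 training images from a
large normed pool (900 images rated for beauty on a 1–7 scale) so that
the selected set spans the full beauty range: the pool is split into
five beauty quintiles (quintile 1 = most beautiful); the 8 most
beautiful images come from quintile 1 and the 8 least beautiful from
quintile 5; quintiles 2 and 4 contribute their 8 nearest-median images;
the middle quintile contributes 8 nearest-median images of which 4 are
main stimuli and 4 are reserved for training trials. ("Near the
middle" is operationalised as smallest absolute distance to the
within-quintile median, ties broken by image id, making selection
deterministic and invariant to row order.) Main images alternate
between sets A and B down the beauty ranking so both sets cover the
range; even-indexed participants see set A on the left.

Each participant completes one training block (6 trials: left, right
and double cue, once under precue and once under postcue instructions),
8 cued blocks of 54 trials alternating precued/postcued starting with
precued, and a 36-trial baseline block showing each main image alone on
its counterbalanced side. Within every cued block each main image
appears exactly once as target, once as distractor, and once in a
combined-pleasure pair; this is realised by three independent uniform
random bijections between left-set and right-set images (left-target,
right-target, combined), and trial order is shuffled with the design
seed. Display timing (200 ms images, 1,000 ms cues) is carried as
metadata only and never simulated. `validate_design` audits all of
these invariants and reports violations rather than raising.

## The synthetic observers

An observer holds a latent pleasure for every catalog image — by
default an affine map of catalog beauty onto the 1–9 response scale
(1 → 1, 7 → 9) plus idiosyncratic taste jitter (Gaussian, SD 0.75,
clipped to the scale), reflecting the substantial between-participant
variation real cohorts show in single-pleasure ratings; a uniform
scheme is available. Ratings follow the combination rule above applied
to noisy pleasure samples, with two Gaussian noise stages:

- **early noise** — drawn independently per presented image before
  combination, so averaging two samples reduces its SD by √2;
- **late noise** — one draw per trial at the response stage, so
  averaging does not reduce it.

Generative presets: faithful (w = 1), compulsory averaging (w = 0.5),
partial (w = 0.8), compressive (a = 0.39, b = 0.85) and expansive
(a = −0.70, b = 1.05), the latter three using the mean best-fit values
reported for human raters. Combined-pleasure trials always combine
left and right with weight 0.5. The study-condition default is pure
late noise with SD 1.4 rating-scale units and no early noise —
the configuration consistent with the empirically observed conservation
of rating variance across set size.

Two generator choices deserve emphasis because the paper-style analysis
depends on them:

- **Baseline ratings are noise-free by default.** The baseline block is
  the reference measurement that *defines* an observer's
  single-pleasures. If the references carried the same 1.4-unit noise
  as cued trials, penalised model comparison would correctly prefer
  shrinkage models (partial averaging, compressive) over a faithful
  generative observer — the classic errors-in-variables effect — and
  the fit quality observed in human data (mean RMSE ≈ 1.1, far below
  the √2·1.4 ≈ 1.98 implied by independent noise on both sides of the
  comparison) would be unattainable. `baseline_noise=True` restores
  fully noisy baselines.
- **Per-participant noise multipliers** (lognormal, log-SD 0.25,
  normalised so the cohort mean squared multiplier is 1). Observers
  differ stably in how reliably they rate; that person-level component
  is what makes error matrices internally consistent across images.
  Without it, Cronbach's alpha of the simulated error matrices is near
  zero for one-pleasure trials while the combined matrix picks up a
  spurious positive alpha from each trial's error being attributed to
  both pair members — inverting the ordering seen in human data.
  Disable with `participant_noise_scale_sd=0`.

Discretisation to the keypad rounds half away from zero and clips to
[1, 9]. Note a genuine limitation: with 1.4 units of noise and stimuli
spanning the full scale, clipping at the scale ends induces a real
compressive nonlinearity outside the fitted model family, and LOOCV
then correctly prefers compressive/partial models even for a faithful
observer. Cohort-level model validation (and the pipeline default)
therefore simulates undiscretised ratings, validating the fitting
machinery under the family's own assumptions; per-trial simulation
keeps `discretize=True` as its default for keypad-faithful datasets.

## Reliability statistics

Errors are scored against the participant's own baseline:
one-pleasure trials as |rating − target single-pleasure|, combined
trials as |rating − mean of the two single-pleasures|, attributed to
both images. Averaging per participant × image gives, per condition
(trial type × cue timing), a cases-by-items matrix for **Cronbach's
alpha** (k/(k−1) · (1 − Σ item variances / variance of case totals),
unbiased variances). Agreement of raw baseline ratings across
participants is the **intraclass correlation** for absolute agreement,
two-way random effects, single measure (ICC(2,1) via the mean-squares
decomposition), cross-checked against an independent implementation.

Two conditions' reliabilities bound their observable error correlation
by the **attenuation ceiling** √(α_X·α_Y) — printed with a "≥" in the
classical inequality but used here, as in practice, as the maximum
attainable correlation. Observed Pearson correlations between
conditions' error profiles (per-participant mean absolute errors by
default; a per-item mode is available) are reported alongside their
ceiling and the observed/ceiling ratio. Sample alphas can be
non-positive when there is no shared structure; the ceiling is then
reported as undefined rather than raising.

## Variance analysis

Rating SDs are computed per participant × trial type × cue timing ×
target-pleasure level, the level being the relevant single-pleasure (or
pair mean) rounded to the nearest integer; cells with fewer than two
ratings are excluded and SDs use the n−1 denominator. Per-participant
mean SDs are compared between trial types with a **paired** two-tailed
t-test within each cue timing (both conditions come from the same
participants). Identical conditions are reported as t = 0, p = 1
rather than NaN.

Under the noise model the predicted one-pleasure/combined SD ratio is
√((σe² + σl²)/(σe²/2 + σl²)) — √2 for pure early noise, 1 for pure
late noise — and a Monte-Carlo twin of this quantity is provided; the
two agree within three delta-method standard errors at n = 10⁵ across a
parameter grid. Discretisation changes mid-scale SDs by well under
0.15 units for σ ∈ [1, 2], justifying comparing keypad data with the
continuous theory.

## Problem sizes and numerical choices

Cohort-scale checks use 25 participants (the replication's sample
size); recovery suites run 20 independent master seeds per generative
model and score a cohort as recovered when the generative account wins
its family's LOOCV comparison in both cue timings. All randomness
flows from a single master seed through spawned, independent
sub-streams (design, latent pleasures, observer noise per participant),
so every dataset and report is exactly reproducible; repeated pipeline
runs with the same configuration produce byte-identical JSON reports
embedding the configuration hash and seed. Optimiser convergence
tolerance is 10⁻⁸ on the cost for the numeric path; the exact path has
no iterative tolerance. Whether trials should be left out within or
across cue timings is not identifiable from the published analysis
description; the pipeline fits within condition.

## What the synthetic data do and do not show

The generator reproduces the structural conditions of the study (trial
counts, counterbalancing, scales), the noise architecture the data
support (late, response-stage noise with person-level reliability
differences), and latent pleasures tied to normative beauty with
idiosyncratic taste. It does not emulate sequence, habituation or
memory effects, reaction times, image content, or genuinely nonlinear
responding beyond the keypad's rounding and clipping. Passing
recovery tests therefore show that the fitting and selection machinery
identifies the generative account under the model family's own
assumptions at realistic noise levels and sample sizes — not that the
family is the true model of human pleasure reports, nor that real
single-pleasure references are noiseless.
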