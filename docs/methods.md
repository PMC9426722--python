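# Methods

## Curve models

**LinExp gastric-volume curve.** `V(t) = V0 (1 + k t / T) exp(-t / T)`,
`t` in minutes post-ingestion (t = 0 at end of ingestion).  `V0 > 0` (mL)
is the curve value at t = 0; `k >= 0` (dimensionless) produces an initial
volume rise for `k > 1` (interior maximum at `t = T (k - 1) / k`) or a
delayed decrease for `0 < k <= 1`; `T > 0` (min) is the emptying time
constant.  `k = 0` reduces to a pure exponential decay.  During fitting
`T` is bounded to (1, 600) min to keep the sampler on physiological
scales; `k` is unbounded above.

**Power-exponential DOB curve.**
`C(t) = AOB·k·β (1 - e^{-kt})^{β-1} e^{-kt}` with `k > 0` (1/min) and
`β >= 1`.  The parameterisation makes the scale parameter exactly the
integrated response: `∫0^∞ C dt = AOB`, since `C` is the derivative of
`AOB (1 - e^{-kt})^β`.  Setting `dC/dt = 0` gives `t_max = ln β / k`
(natural log) and `A_max = C(t_max) = AOB·k (1 - 1/β)^{β-1}`.  `β < 1`
is excluded because it makes the curve diverge at t = 0, whereas all
measured responses start at baseline; `β = 1` is the boundary case
`C(0) = AOB·k`.  The curve is linear in `AOB`, so responses below
baseline (gallbladder volume, glucose) are handled by a negative
amplitude, with `t_max` marking the trough.

**CaBER post-processing.**  Hencky strain `ε = 2 ln(D0 / D_mid)` of the
thinning filament, and apparent extensional viscosity from the
mid-filament force balance `η_app = σ / (-dD_mid/dt)` with centred finite
differences on the raw trace.  No smoothing is applied by default (a
moving-average window is available); no axial-force correction factor is
applied.  Instants where the filament is not thinning are dropped and
counted.  Units must be consistent (m, s, N/m give Pa·s).

## Hierarchical model and sampler

Each (measure, arm) pair is fitted separately.  Subject-level parameters
live on transformed scales — `(log V0, log k, log T)` for LinExp,
`(AOB, log k, log(β - 1))` for the power-exponential — and are partially
pooled:

    phi_s  ~ Normal(mu, tau)        componentwise
    y_st   ~ Normal(curve(phi_s, t), sigma)

Priors are weakly informative and centred on a per-subject nonlinear
least-squares initialisation (winsorised at 3 robust SDs around the
subject median, so boundary solutions such as k -> 0 on a monotone-looking
series cannot distort the centring): Normal on `mu` with scale
`max(2, 2·SD(inits))` on log components and `10x` the amplitude scale for
AOB; half-Normal on the between-subject scales `tau` (unit scale on log
components, amplitude scale for AOB) and on the residual SD `sigma`
(scaled from the initialisation residuals).  Independence across arms
within subject is assumed; the crossover correlation structure is not
modelled.

The posterior is sampled with an adaptive Metropolis-within-Gibbs sweep:

1. per-subject joint 3-d random-walk Metropolis with a proposal covariance
   adapted (Haario-style, with Robbins–Monro scale tuning toward 0.3
   acceptance) during warmup only, then frozen;
2. a group-shift Metropolis move translating `mu` and all `phi_s`
   together along the pooled parameter-correlation structure — this is the
   direction (e.g. the k–T ridge of the LinExp model) in which
   subject-wise updates alone mix slowest;
3. an exact conjugate Gibbs draw of `mu`;
4. univariate slice-sampling updates of `log tau` and `log sigma`
   (floored at 1e-4 and ~1e-6·SD(y) respectively so that degenerate
   noise-free data cannot underflow the scales).

Defaults: 2 chains, 1000 warmup and 1500 kept iterations per chain
(optionally thinned); at least 2 chains and 500 kept draws are required
for any reported summary.  Convergence is gated at split-R̂ <= 1.05
(arviz) per reported parameter; non-converged summaries are flagged and
returned, never silently retried with a new seed.  Weakly identified
configurations — e.g. a strongly blunted response whose amplitude barely
exceeds the assay noise — legitimately produce wide HPDs and benefit from
`thin = 2–3`.

Arm-level draws are reported on the natural scale; for the
power-exponential family the derived `t_max` and `A_max` are computed
draw-wise from the `(AOB, k, β)` draws and then summarised — never from
ratios of summaries.  Contrasts are draw-wise differences (second arm
minus first); a contrast "excludes zero" exactly when its HPD lies
entirely on one side of zero.  Because arms are fitted independently,
contrast draws pair independent posterior samples, which is exact for the
difference distribution of independent posteriors.

**HPD intervals** are the shortest contiguous window containing
`ceil(mass·n)` sorted draws (cross-checked against `arviz.hdi` in the
test suite).  For symmetric unimodal posteriors this coincides with the
equal-tail interval and is never longer on skewed samples.

## Synthetic study generator

The generator emulates the statistical shell of an unbalanced three-way
crossover trial: 21 recruited subjects each uniformly assigned 3 of the 4
emulsion arms (PS-LE1, WPI-LE5, MC-LE6, CNC-LE7); whole-subject dropouts
are then chosen deterministically under the seed (first feasible
combination) so per-arm completer counts hit 14/14/13/10 exactly.
Volumes are sampled on the MRI grid 0–210 min (9 blocks), blood and
sensation measures on the 10–300 min grid (11 draws) with two fasting
baseline rows at sentinel times −15/−5 min; observations are dropped
completely at random at a default rate of 1%, roughly matching the
handful of missing scans/samples such studies report.

Subject-level parameters are log-normal around the arm-level values
(median-parameterised, so the arm value is the population median);
`AOB` is drawn on its magnitude with the sign reapplied, `β` on `β - 1`,
keeping all invariants valid by construction.  Residual noise is
homoscedastic Gaussian per measure; volumes are floored at 0 and VAS DOB
values clipped to ±100 mm.  By default blood/sensation measures are
emitted directly on the DOB scale (baselines scatter around zero); a raw
mode adds a fasting mean so the pipeline's baseline-subtraction step
(`compute_dob`) is exercised.

Arm-level defaults are seeded from the scale of published estimates for
this study design (fat V0 ≈ 35 mL with one arm ~5% lower; secretion
T ≈ 112 vs 166 min; CCK AOB 76 vs 38 with the Pickering arm strongly
blunted; gallbladder AOB ≈ −245 mL·min; intake intercept 555 kcal with a
−390 kcal arm×sex interaction).  Published (AOB, A_max, t_max) triplets
are not exactly mutually consistent with a single `(AOB, k, β)`, so AOB
and t_max anchor each arm, `β` is set to 1.8–2.5, and A_max follows.
Between-subject CVs (0.25 on amplitudes/volumes/times, 0.20 on shapes)
and residual SDs are not published anywhere and were chosen once as
realistic for repeated physiological measurements; they are not claimed
to match any particular dataset.  Two consequences worth noting:

* the marginal mean of the observations converges to the curve averaged
  over the subject-parameter distribution, which differs from the
  arm-level curve by a Jensen gap of order CV²; the test suite checks the
  exact statement via an independent Monte-Carlo oracle and the
  approximate one at small CV;
* a single simulated study's arm median carries ~7% sampling error at
  n = 14, so recovery *bias* is assessed as the mean error across six
  replicate studies, not from one draw.

What the generator does **not** emulate: physiological feedback (e.g.
secretion responding to emptying), within-subject correlation across a
subject's three arms, heteroscedastic assay noise, informative
missingness, or circadian drift.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated sampling model,
not robustness to those real-data features.

## Intake model

Ordinary least squares of each kcal outcome (total, fat, carbohydrate,
protein) on emulsion arm, sex, buffet time (hours from the 12 pm
reference, continuous) and arm×sex, treatment-coded against the
(PS-LE1, female) reference; t-based 95% CIs.  Completers contribute up to
three rows each and no subject random effect is included, so standard
errors ignore within-subject correlation — a deliberate mirroring of the
plain-`lm` analysis this model reproduces.  Empty arm×sex cells are
rejected with the offending cell named.

## Power simulation

The detection-rule calibration works on a subject-level summary scale:
each subject contributes a fat-emptying rate (mL/h), Gaussian around the
arm mean with between-subject SD 0.76 mL/h — the value at which a
two-sample z-test with alpha = 1% and n = 15 per arm has 85% power for a
1 mL/h difference, i.e. the middle of the 80–90% regime this design
targets.  A replicate detects an effect when the (1 − alpha) HPD of the
draw-wise arm-mean contrast (known-SD Gaussian posteriors) excludes zero.
The closed-form two-sample z-power is the exact oracle for this
reduction, which is what makes tight Monte-Carlo calibration tests
possible at hundreds of replicates in seconds.

## Problem sizes used in the checks

The acceptance checks use: noise-free oracle recovery on the full
four-arm design; six replicate noisy studies at arm sizes 14/14/13/10 for
the bias bound; 200 one-arm replicates of 10 subjects for HPD coverage of
the initial-volume location; 500–800 replicates for the detection-rule
calibrations.  `scripts/acceptance.py` fits three measures on one default
study and completes in well under a minute on a single core.
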