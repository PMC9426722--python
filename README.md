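# gastrokin

Postprandial kinetics of lipid-emulsion meals: curve models, hierarchical
Bayesian fitting, and crossover-study simulation.

## What this package is for

When healthy volunteers ingest an oil-in-water lipid emulsion, its digestion
can be tracked as a set of time courses: MRI-derived gastric fat and
secretion volumes, plasma satiation hormones (CCK, GLP-1, PYY) and
metabolites (triglycerides, betahydroxybutyrate, free glycerine, glucose)
expressed as delta over baseline (DOB), visual-analogue hunger/fullness
ratings, and finally ad-libitum buffet intake.  `gastrokin` provides the
statistical machinery to analyse such crossover studies — and, because raw
subject-level data of this kind are rarely shared, a synthetic study
generator with known ground truth so every stage of the analysis can be
validated end to end.

Two parametric curve families carry the kinetics:

* **LinExp** gastric-volume curve
  `V(t) = V0 (1 + k t / T) exp(-t / T)` with initial volume `V0` (mL),
  shape `k` (a rise for `k > 1`, peaking at `t = T (k-1)/k`), and emptying
  time constant `T` (min);
* **power-exponential** DOB response curve
  `C(t) = AOB·k·β (1 - e^{-kt})^{β-1} e^{-kt}`, whose scale parameter is
  exactly the area over baseline (`∫ C dt = AOB`), with peak time
  `t_max = ln β / k` and amplitude `A_max = C(t_max)`.

Curve parameters are estimated per emulsion arm with a **hierarchical
Bayesian model** (subject-level parameters partially pooled around
arm-level locations; adaptive Metropolis-within-Gibbs MCMC), summarised as
posterior medians with 95% highest-posterior-density (HPD) intervals, and
compared across arms with draw-wise contrasts flagged when the HPD
excludes zero.  Buffet intake is modelled with a fixed-effects OLS
(arm + sex + buffet time + arm×sex).  A small rheology module post-processes
capillary-breakup (CaBER) filament traces into Hencky strain and apparent
extensional viscosity.

## Worked example

```python
from gastrokin import (StudyDesign, HierarchicalModelSpec, default_ground_truth,
                       simulate_timeseries, fit_hierarchical, contrasts)

design = StudyDesign(seed=1)             # 21 recruited -> arms of 14/14/13/10
truth = default_ground_truth().subset(["fat"])
records, _ = simulate_timeseries(design, truth)
fit = fit_hierarchical(records, HierarchicalModelSpec("fat", "linexp", seed=2))
for s in fit.summaries:
    print(s.arm, s.parameter, round(s.median, 2), (round(s.hpd_low, 2), round(s.hpd_high, 2)))
```

prints (excerpt)

```
PS-LE1 v0 33.92 (28.84, 39.64)
PS-LE1 k 0.87 (0.73, 1.02)
PS-LE1 t_const 121.44 (102.14, 147.38)
...
```

i.e. the arm-level posterior median initial fat volume for the
surfactant-stabilised reference emulsion is ~34 mL with a 95% HPD of
29–40 mL, recovering the generating value of 35.3 mL to within the
between-subject sampling error at 14 subjects.  `contrasts(fit, "v0")`
then yields the six pairwise arm differences with their HPDs and
excludes-zero flags.  The `examples/` directory holds one short script per
capability (curve models, simulation, hierarchical fit, intake model,
power/HPD calibration, CaBER rheology); each prints what it computes and
what the numbers mean.

A thin CLI mirrors the pipeline: `gastrokin simulate | fit | contrast |
intake | report`, each taking `--config` (YAML), `--seed` and `--out`.
Exit codes: 0 ok, 2 configuration error, 3 data error, 4 non-convergence.

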