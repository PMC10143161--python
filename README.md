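# lssrobust

Robustness evaluation of Bayesian limited sampling strategies (LSS),
exemplified by serum iohexol clearance for measured glomerular
filtration rate (mGFR).

## The problem

An LSS estimates a drug's full exposure — the area under the
concentration-time curve, AUC₀₋∞ — from a few optimally timed blood
samples combined with Bayesian estimation against a population
pharmacokinetic prior.  For an intravenous iohexol bolus, clearance
(and hence mGFR) is `dose / AUC₀₋∞`.  In clinical practice actual
sampling times drift from the nominal schedule; this package quantifies
how much such drift degrades the GFR estimate, for people developing or
validating LSS protocols.

The pipeline, for a two-compartment IV-bolus model parameterised as
(CL, V, Vp, Q) with a 4-point schedule at 10 min, 30 min, 2 h, 5 h
after a 3235 mg dose:

1. **Nonparametric prior.**  The population distribution is a set of
   support points θᵢ with probabilities pᵢ (Σpᵢ = 1).  The original
   points are not published, so a synthetic stand-in prior is generated
   whose weighted means land near the published population summaries.
2. **Semi-parametric simulation.**  The discrete prior is widened into
   a Gaussian mixture `p(x) = Σᵢ πᵢ N(x | μᵢ, σ)` with one fitted
   common σ per parameter; virtual subjects are drawn by sampling a
   component and a bounded (rejection-sampled) normal around it.
   Simulation validity requires a kernel-density overlap ≥ 85% between
   simulated and observed parameter distributions.  Noiseless curves
   are simulated at 1-min resolution over 0–24 h; subjects with GFR
   outside [15, 115] mL/min are excluded.
3. **Discrete Bayesian estimation.**  Each subject's posterior is a
   reweighting of the support points, `wᵢ ∝ pᵢ Lᵢ`;
   `AUC₀₋∞ = Σᵢ wᵢ (dose/CLᵢ)` and GFR = dose/AUC.
4. **Shift protocols and metrics.**  Single-point shifts over empirical
   grids and truncated random multi-point error (RSD 5–25%); summarised
   by the mean absolute GFR error (MAE), mean relative error, P15 (the
   percentage of subjects with relative error above 15%), and the same
   per chronic-kidney-disease stage.  Optimal sample windows are
   derived from the single-shift MAE profile (threshold 2 mL/min) and
   from the truncated random-shift quantiles.

## Worked example

```python
from lssrobust import RobustnessStudy, StudyConfig

report = RobustnessStudy(StudyConfig(seed=1)).run()
print(report.summary())
```

prints

```
Robustness of the 4-point sampling strategy
-------------------------------------------
retained subjects: 333 (excluded 30 below / 37 above the GFR range)
overlap indices (simulated vs observed): CL=90%, V=97%, Vp=93%, Q=91%
reference run: MAE 1.61 +/- 1.31 mL/min, relative error 5.1 +/- 5.5%, P15 3.9%
worst single-point shift MAE: 3.55 mL/min
RSD 5%: MAE 1.63 mL/min, P15 3.9%
RSD 10%: MAE 1.61 mL/min, P15 3.6%
RSD 15%: MAE 1.64 mL/min, P15 3.9%
RSD 20%: MAE 1.85 mL/min, P15 5.4%
RSD 25%: MAE 1.91 mL/min, P15 6.6%
```

Reading this: of 400 simulated subjects, 333 fall in the validated GFR
range; the simulation is valid (all overlaps ≥ 85%); with optimally
timed samples the LSS misses true GFR by 1.61 mL/min on average and
only 3.9% of subjects err by more than 15%; no single-point shift in
the tested grids pushes the mean error past 4 mL/min; and 25% random
timing error raises P15 to 6.6%.  `report["single_shift"]`,
`report["rsd_windows_h"]` and friends hold the full per-protocol and
per-CKD-stage breakdowns, and `lssrobust.plot_shift_mae(report)` draws
the MAE-versus-shift profile.

Individual estimation follows the Model/Results convention:

```python
from lssrobust import BayesianIndividualModel
results = BayesianIndividualModel(obs, prior).fit()
results.gfr, results.ess, results.summary()
```

A `lssrobust` console script exposes the pipeline
(`simulate`, `fit-sigma`, `evaluate`, `windows`, `report`).

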