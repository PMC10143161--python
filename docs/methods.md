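# Methods

## Disposition model

Iohexol disposition after an IV bolus follows a two-compartment model
parameterised in clearance CL (L/h), central and peripheral volumes V
and Vp (L), and inter-compartmental clearance Q (L/h); micro-constants
are k10 = CL/V, k12 = Q/V, k21 = Q/Vp.  The package evaluates the
closed-form bi-exponential solution

C(t) = (dose/V) · [ (α−k21)·e^(−αt) − (β−k21)·e^(−βt) ] / (α−β),

with α > β the roots of s² − (k10+k12+k21)s + k10·k21 = 0, rather than
integrating the ODE system: it is exact and keeps a 1-min, 24-h,
400-subject simulation grid trivial.  A numerical Runge–Kutta oracle is
retained in the tests (agreement to 1e−6 relative).  When |α−β|/α <
1e−10 the repeated-root limit (dose/V)·e^(−αt)(1+(k21−α)t) is used; the
study never reaches it, but the sampler may.  Units are fixed to mg, L,
h; GFR = dose/AUC₀₋∞ × 1000/60 in absolute mL/min (no body-surface
normalisation), and AUC₀₋∞ = dose/CL exactly under linear elimination.
The model is covariate-free; no allometric weight scaling is applied.

## Support-point prior and its synthetic stand-in

The population prior is a discrete set of K support points with
probabilities.  The real points behind the published iohexol model are
unavailable, so `lssrobust.fixtures` generates a synthetic stand-in
(every function and file that uses it labels it synthetic):

* Per-parameter values are drawn from log-normals calibrated so that
  the *weighted mean / weighted median* pairs match the published
  population summaries (means 2.89, 10.36, 9.20, 10.65; medians 1.95,
  10.11, 7.95, 8.03 for CL, V, Vp, Q), truncated to the model bounds
  (CL 0.5–12 L/h, V 3–30 L, Vp 1–40 L, Q 0.5–60 L/h).  The mean >
  median right skew is the log-normal's.
* Probabilities are then assigned by maximum-entropy exponential
  tilting (a convex dual solved with BFGS) so the weighted means hit
  the targets essentially exactly; a 5% miss raises an error.
* The CL marginal deliberately spans clearances mapping to GFR below
  15 and above 115 mL/min, so the inclusion filter excludes subjects on
  both sides and the cohort's CKD-stage mix is skewed toward low GFR.
  Because a single log-normal carries all of the CL skew, the fixture
  excludes more subjects *above* 115 mL/min than a real renal cohort
  would; the stage composition below 60 mL/min is the part that
  matters for the stage-wise metrics.

Default K = 50 and all seeds are explicit; the generator is
deterministic per seed.

## Semi-parametric widening and the common σ

Each support point receives an isotropic-per-parameter Gaussian,
giving the mixture p(x) = Σᵢ πᵢ N(x|μᵢ, σ) per parameter with a single
common σ (the covariance is diagonal — one univariate fit per
parameter, no cross-parameter covariance).  Virtual subjects are drawn
by choosing a component by probability and sampling a diagonal normal
around it, rejecting vectors outside the bounds.

**Generating σ.**  The widening σ represents how far individual
posterior parameter values scatter around their support points.  In a
rich-data nonparametric fit the individual posterior means concentrate
essentially *at* the support points — their deviation is on the order
of half the relative spacing of a ~50-point grid, a few percent — so
the default generating σ is 4% of each parameter's weighted mean
(0.116, 0.414, 0.368, 0.426 for CL, V, Vp, Q).  This widens the
discrete prior into a continuum while keeping the simulated population
inside the envelope on which the 4-point strategy was validated.
Published σ estimates obtained by matching raw mixture densities to
kernel density estimates of observed values are not transferable here:
for near-discrete samples such estimates absorb the KDE bandwidth
itself (they are close to Silverman's rule evaluated on the observed
sample) rather than the underlying scatter.

**Fitting σ back.**  Two fitters are provided.

* `fit_common_sigma` — the density-match objective: sum of squared
  distances between the mixture density and a Gaussian KDE of the
  observed values on a fixed 512-point grid spanning the pooled range,
  minimised by bounded Brent.  Two corrections keep it unbiased: the
  model density is convolved with the KDE kernel (component spread
  √(σ²+h²)), and the bounds truncation of the observed draws is
  carried into the model density in closed form.  Even corrected, the
  univariate objective is weakly identified when components overlap:
  at n = 500 its sampling error is tens of percent.
* `fit_sigmas_joint` — the default in the pipeline: maximises the
  exact likelihood of the bounds-truncated diagonal mixture over all
  four σ jointly (Nelder–Mead in log-σ, started from the univariate
  fits).  Because all four coordinates of a draw share one component,
  the joint likelihood resolves overlapping components and recovers σ
  to a few percent at n = 500.

**Validity check.**  The overlapping index η = ∫ min(f̂ₐ, f̂_b) between
kernel density estimates on a shared 1024-point grid (padded by three
bandwidths) compares each simulated parameter distribution with the
observed values; η ≥ 0.85 on all four parameters is required.
Silverman bandwidths are used with a floor of 1e−6 of the grid span
for degenerate samples.

## Cohort simulation and inclusion filter

400 subjects (default) are sampled from the fitted mixture, each
simulated noiselessly on a 1-min grid from 0 to 24 h inclusive
(C(0) = dose/V; the grid start is configurable) after a 3235 mg bolus.
True GFR is CL × 1000/60.  Subjects with GFR < 15 or > 115 mL/min are
excluded (strict inequalities: the boundaries are retained), with
below/above counts reported separately.

## Individual estimation

The posterior over support points is wᵢ ∝ pᵢ·exp(ℓᵢ), computed in log
space with max-subtraction; ℓ is a Gaussian log-likelihood with
residual SD(C) = c0 + c1·C.  The simulation adds no measurement error,
so the polynomial acts purely as the width of the likelihood kernel;
the default c0 = 0.1 mg/L, c1 = 0.05 mirrors common assay-polynomial
practice in nonparametric PK software and the metrics are insensitive
to it over a wide range (halving or doubling the width moves cohort
MAE by a few percent).

AUC₀₋∞ is the posterior mean of dose/CLᵢ — the integral of the
posterior-mean predicted curve, since integration is linear — and GFR
is dose over that AUC.  This differs (Jensen) from dose divided by the
posterior-mean CL, and is the quantity that stays accurate even when
Vp and Q are individually misidentified, which they routinely are.
Posterior means are the default point parameters (medians are also
exposed); the effective number of support points 1/Σwᵢ² is reported.

"Cycling" is fixed-grid EM reweighting of the population
probabilities, pᵢ ← (1/N)Σⱼ wᵢⱼ, with support locations fixed; the
cohort marginal log-likelihood is non-decreasing per cycle.  Adaptive
grid refinement (moving or adding support points) is intentionally out
of scope; the default number of cycles is 0 — the pure Bayesian
posterior against the fixed prior — because on this pipeline
reweighting leaves the metrics essentially unchanged (the generating
weights already equal the prior weights).

## Shift protocols, metrics, windows

* Single-point shifts (minutes): 10 min ± {2,4,5,6}; 30 min ± {5,10,15};
  2 h ± {5,15,30,60}; 5 h ± {5,15,30,60,120} and +{180,420,1140}.  One
  point is moved for all subjects alike; a shifted time ≤ 0 or an
  ordering violation marks the cell "not evaluable" rather than being
  estimated.  Observations are taken from the closed form at the exact
  shifted times, never snapped to the 1-min grid.
* Random multi-point error: per point k, t ~ N(t_k, (RSD·t_k)²)
  truncated by rejection to disjoint windows 5–15 min, 15–60 min,
  1–3 h, 3–8 h (so samples cannot overlap); RSD ∈ {5,10,15,20,25}%.
* Metrics: MAE (mean ± SD), mean relative error (± SD), P15,
  proportions of |error| > 5 and > 10 mL/min, all repeated per CKD
  stage.  Stages are left-closed bins of *true* GFR: 4 = [15,30),
  3B = [30,45), 3A = [45,60), 2 = [60,90), 1 = [90,115] — exactly 90
  belongs to stage 1, 115 is included.
* Windows: (a) from the single-shift MAE profile, the maximal
  contiguous interval around the nominal time with MAE < 2 mL/min,
  endpoints linearly interpolated between grid neighbours; (b) from
  the truncated random-shift distribution at RSD 25%, the empirical
  5th–95th percentiles (200,000 draws by default in the study runner),
  with the untruncated ±1.645·RSD·t_k interval reported alongside,
  since the truncation the protocol prescribes makes the two differ.

## What the synthetic pipeline does and does not show

The generator reproduces the population's weighted summaries, its
right skew, the low-GFR-heavy stage mix and the discrete-prior +
mixture structure, so the pipeline exercises every step of the method
end to end and the published acceptability bounds (overlap ≥ 85%,
reference P15 < 15%, reference MAE < 2 mL/min, single-shift MAE
< 4 mL/min) are meaningful on it.  It does not reproduce the real
support points' joint correlation structure (parameters are drawn
independently before weighting), real assay noise (observations are
noiseless by design), or adaptive-grid re-estimation.  One consequence
is worth flagging: with noiseless, model-true observations, delaying
the 5 h sample to 24 h *adds* terminal-phase information and improves
the GFR estimate on this pipeline, whereas the source study observed
marked degradation there — that degradation evidently arises from
estimation machinery (adaptive grids, measurable-range effects)
outside this package's scope, and the pipeline should not be used to
draw conclusions about very late samples on real data.

## Numerical choices

* Posterior normalisation by log-sum-exp; weights underflowing to zero
  are floored at 1e−300 only inside the EM update.
* Weighted quantiles invert the step CDF left-continuously (smallest
  value with cumulative probability ≥ q).
* The population-summary "95% credibility interval" is reported two
  ways: the distribution's own weighted 2.5/97.5 percentiles
  (default) and a seed-controlled bootstrap interval for the weighted
  median (B = 1000), since the two answer different questions.
* Rejection samplers abort if acceptance falls below 1e−4 over a
  probe batch (infeasible bounds or windows).
* All stochastic stages take explicit seeds; the study runner derives
  stage seeds from one root seed via `SeedSequence.spawn`, so reports
  are byte-identical across runs of the same configuration.

## Problem sizes

Default study: K = 50 support points, 400 simulated subjects, 500
observed posterior vectors for the σ fit, 10,000 draws for the overlap
check, 200,000 draws for the truncated-window quantiles.  A full study
runs in a few seconds on one CPU; the acceptance script and test suite
use these same sizes.
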