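# Methods

## The kinetic response model

The temperature time course of an endotoxin-challenged animal is modelled
as a logistic thermal autoregulation perturbed by a transient clearance
process:

    dT/dt = r·T·(1 − T/T_n) − p0·f(t; s, k)·T,      T(0) = T_n

The logistic term is a phenomenological description of homeostatic control:
close to equilibrium it reduces to proportional control
dT/dt ≈ r(T_n − T), but it adds an inflection point in deep hypothermia,
where linear control is known to be oversimplified. The perturbation term
is multiplicative in T with time profile f, a gamma density with integer
shape s and rate k — the residence-time distribution of s serial transit
compartments each clearing exponentially. s = 1 recovers a pure
exponential clearance (bolus hits immediately); s ≥ 2 delays the onset,
producing the roughly two-hour initial plateau seen in measured curves at
s = 3. p0 is the dimensionless total strength of the perturbation.

The model is a *summary process*: p0 aggregates pro-inflammatory damage
mechanisms and k anti-inflammatory clearance; neither maps onto a single
molecular process. The initial condition is pinned at T(0) = T_n (animals
are normothermic at injection), which is also what makes group fits well
posed with five samples per subject.

Phenomenology of the minimum, computed exactly from the model at the
canonical parameter set (T_n = 37.5 °C, r = 0.04 1/h, k = 0.4 1/h,
p0 = 0.25, s = 3): raising p0 from 0.25 to 0.35 deepens the minimum by
2.19 °C while moving its time by only 0.11 h; raising k from 0.4 to
1.2 1/h moves the minimum 7.9 h earlier. Damage strength sets the depth,
clearance the timing — the two parameters are experimentally
distinguishable through curve shape, and reliable estimation requires
samples beyond the minimum (the recovery phase identifies r and T_n).

### Numerical integration

`simulate` integrates the ODE with LSODA at rtol = atol = 1e-10 (the RHS
is non-stiff for physiological parameters; at these tolerances
trajectories agree with closed-form benchmarks to better than 1e-6 °C).

`predict_temps` exploits that the equation is of Bernoulli type: u = 1/T
obeys the *linear* equation u' = −(r − p0 f) u + r/T_n, solved by an
integrating factor exp(A(t)) with A(t) = r·t − p0·P(s, kt), P the
regularized lower incomplete gamma function. The only quadrature,
∫ exp(A), is evaluated by cumulative Simpson integration on a grid built by
subdividing the intervals between requested times (≤ 0.02 h steps), which
gives ~1e-9 relative accuracy. A trapezoid variant on a ≤ 0.05 h grid
(~1e-7 relative) serves as the fast evaluator inside optimizer loops. The
two routes — adaptive ODE solver and semi-analytic reduction — are
cross-checked against each other in the test suite.

The grid is constructed by subdividing between anchor times rather than by
merging two float grids: merging creates near-duplicate nodes (spacing
~1e-15) that destabilize Simpson weights.

## Regression

Fits minimize Σ (log T_obs − log T_pred)² — repeated temperature
measurements are approximately lognormal, and the log scale makes the
residual variance homoscedastic. Each of T_n, r, p0, k is independently
`shared` across groups or `by_group` (the pred0–pred4 ladder); s is fixed
per fit. All four parameters are strictly positive and optimized as
logarithms (trust-region reflective least squares inside generous
positivity bounds: T_n ∈ [20, 50] °C, r ∈ [1e-4, 2] 1/h, p0 ∈ [1e-4, 50],
k ∈ [1e-3, 10] 1/h).

Starting values are deterministic, from coarse curve features: T_n starts
at the maximum of the group's mean temperature profile, p0 at
ln(T(0)/T_min) of that profile (the depth the damage term alone would
produce), r at 0.05 1/h and k at 0.4 1/h; a small deterministic multistart
grid (p0 and k starts × {0.5, 1, 2}) guards against local minima, with the
best RSS winning. Fits are therefore reproducible without randomness;
noise-free data are recovered to ~1e-6 relative, and perturbed starts
(±50%) land on the same optimum to 1e-4.

The working likelihood is the concentrated Gaussian likelihood
ℓ = −(n/2)(log(2π·RSS/n) + 1), shared between the fitting and inference
layers so that all deviances reduce to n·log(RSS_reduced/RSS_full).

Standard errors come from the Gauss–Newton curvature of the log-parameter
objective with σ² = RSS/(n − p). Confidence intervals are Wald intervals
on the log scale with Student-t quantiles (df = n − p), exponentiated to
the natural scale — hence asymmetric about the point estimate. (Whether t
or normal quantiles are more appropriate here is not settled; with the
smallest realistic cohorts df > 60, the difference is cosmetic.) In a
120-replicate simulation at the default noise level, empirical coverage of
the nominal 95% intervals is 93–96% for all four parameters.

Parameter contrasts between groups are two-sided t-tests of log-scale
differences using the full covariance (strata covary through shared
parameters), Benjamini–Hochberg adjusted per parameter per call (one
family = all 15 pairs for six groups).

## Inference

**Nested LR tests.** Deviance n·log(RSS_red/RSS_full) referenced to
χ²(Δp). Deviance is additive along nested chains by construction. Under a
two-identical-groups null (n = 20/group, homogeneous subjects) the
whole-curve test rejects at 5.6% for nominal α = 5% (500 replicates), with
the deviance distribution matching χ²(4) (mean 3.9, KS p ≈ 0.9).

**Shape selection.** s is an integer, so no Hessian-based CI exists; the
conventional ad-hoc criterion compares successive shapes by a 1-df LR
test and steps upward while the larger shape significantly improves the
likelihood, stopping at the first non-improvement. Comparisons across s at
fixed stratification use this 1-df convention in `lr_test` as well.

A finding from the synthetic experiments worth knowing: subject-level
heterogeneity in p0 and k (lognormal, CV 0.1) *attenuates* the
population-level effective shape — a mixture of gamma(3) curves with
varying rates resembles a slightly lower shape. With realistic cohort
sizes (14–64 per group, 237 subjects) the selector recovers the generating
s ∈ {1, 3} in ≥ 95% of replicates; at very small cohorts (≤ 8/group) it
regularly stops at s = 2 for s = 3 truth. Shape selection needs
study-sized data.

**Whole-curve pairwise comparison.** Each pair of groups is relabelled as
one group, the model refitted, and the deviance against the fully
stratified fit referenced to χ² with df = number of stratified parameters.
These p-values are reported raw (unadjusted), as is conventional for this
table; parameter contrasts and AUC post-hoc tests are BH-adjusted, and
every table labels its adjustment.

**Comparators.** Single-time-point comparisons are Welch t-tests on raw
temperatures (Welch being the default of the reference statistical
environment for this field). The linear-model comparator tests
log T ~ group + time + group:time against log T ~ time with time
continuous, by the same Gaussian LR; on curved data it is consistently
less discriminative than the kinetic LR test, and on truly linear null
data its rejection rate is nominal.

**Reduced-sample experiments.** `subsample_experiment` redraws
n-per-group subjects (seeded, without replacement), reruns the kinetic LR
table and the linear comparator, and reports per-pair concordance of
significance calls with the full-data conclusions.

## AUC inflammation index

AUC = ∫₀^tmax (T_n − T(t)) dt on the *fitted* curve, trapezoid rule at
0.01 h steps (converged far below reporting precision). Excursions above
T_n are integrated signed, not clipped. Default t_max = 24 h, the terminal
observation; extrapolation beyond the data is allowed but logged as a
warning because it inflates the coefficient of variation.

Group comparisons need subject-level AUCs, hence subject-level fits. Five
observations cannot support four free parameters per animal, so T_n and r
are fixed at the population-fit values (group-specific where stratified)
and log p0, log k are estimated per subject, falling back to fixing k as
well if that fails; failures are excluded with a logged count. This
fixed-(T_n, r) choice is an assumption the data cannot check at this
sampling density; it anchors every subject to the population recovery
dynamics and will shrink between-subject AUC dispersion slightly.

With zero between-subject variability the mean subject AUC equals the
group-curve AUC to ~1e-3 °C·h, and subject AUCs rank-correlate > 0.9 with
the true per-subject damage strengths.

AUC and whole-curve LR tests answer different questions: a pair of groups
differing only in clearance rate has time-shifted curves (LR-significant)
but nearly identical cumulative damage (AUC-non-significant). The default
synthetic scenario encodes exactly this constellation (groups C and D,
k = 0.4 vs 0.45 1/h, 24-h AUCs ~3.6% apart).

## Power analysis

Cohen's d = Δ/SD_pooled; minimal per-group n for a two-sided two-sample
t-test by integer search on the exact noncentral-t power function
(df = 2n − 2, noncentrality d√(n/2)). The worked benchmark comparisons
give d = 0.89 → n = 21 on a single-time-point temperature difference and
d = 1.34 → n = 10 on the AUC index: the model-based summary roughly halves
the required group size, which is the 3R payoff of curve-level analysis.

## Synthetic data generator

Emulates the standard design: six groups, t ∈ {0, 6, 12, 18, 24} h,
multiplicative lognormal measurement noise on temperature (additive
Gaussian on log T, default SD 0.01 ≈ 0.37 °C at 37 °C — chosen to resemble
observed scatter; no quantitative residual SD is established for this
assay, so this is a tunable assumption), and subject-level mean-one
lognormal multipliers on p0 and k (default CV 0.1; T_n and r are held
fixed within group, matching the finding that only p0 and k carry group
differences). Default cohort sizes are 56/17/57/14/64/29 — a realistic
unequal design spanning 14–64. Each subject draws from a deterministic
substream of a single integer seed, so datasets are byte-identical across
runs; parameter draws that break the simulation are redrawn with a
bounded, logged retry.

What the generator does **not** emulate: dropout/mortality (all subjects
complete the series), fever (negative perturbations), circadian baseline
variation, autocorrelated within-subject measurement error beyond the
shared random effects, and any dependence of p0/k on dose. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to these real-data features.

## Numerical and design choices

* t = 0 with s ≥ 2: f(0; s, k) = 0 by definition (no 0⁰ ambiguity);
  (s−1)! is evaluated through the log-gamma function.
* Extremum search: 0.01 h dense grid plus parabolic refinement of interior
  minima; boundary minima are flagged degenerate.
* Group-level fits require ≥ 5 distinct sampling times per group;
  subject-level fits require ≥ 3.
* `lr_test` clips deviance at 0; identical fits give p = 1; df = 0 gives
  p = 1.
* BH adjustment via the standard step-up procedure; adjusted p ≥ raw p
  always.
* All simulation sizes used in the test suite and the acceptance script
  (e.g. 500 null replicates at n = 20/group, 50 shape-recovery replicates
  at study-size cohorts, 120 coverage replicates) are desk-scale choices
  that keep each experiment's Monte-Carlo error well inside the asserted
  margins.

## Known limitations

* The Gaussian iid working likelihood ignores within-subject correlation
  induced by subject-level random effects; with heterogeneous subjects the
  whole-curve LR test is anti-conservative. The principled fix is a
  mixed-effects formulation, which is out of scope here; the null
  calibration is therefore stated under homogeneous subjects.
* Wald/Gauss–Newton intervals assume local quadratic log-likelihood; at
  high noise or near-unidentifiable designs (records stopping before the
  temperature minimum) they will under-cover. r and k are correlated when
  the recovery phase is short.
* The integer shape s is selected, not estimated with uncertainty; the
  1-df criterion is a precision heuristic, not an exact test.
* AUC beyond the observation window depends on extrapolated dynamics and
  on the fixed-(T_n, r) subject-fit assumption.
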