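# Methods

## Models

Single-dose disposition is described by sums of first-order exponential
phases.

**IV bolus, two-compartment open model.** Plasma concentration

    C_P(t) = A·e^(−αt) + B·e^(−βt),    α > β > 0,  A, B ≥ 0,  A + B > 0.

α is the distribution rate (drug moving from blood into tissue), β the
elimination rate. The 1-minute infusion used for IV dosing is treated as a
bolus: at the rates of interest (α of order a few h⁻¹) the infusion
duration is negligible against 1/α.

**IM injection, one-compartment model with first-order absorption** (the
Bateman function)

    C_P(t) = a·(e^(−βt) − e^(−γt)),    γ > β > 0,  a > 0,

with γ the uptake rate from muscle into blood. Derived quantities are
closed-form: t_max = ln(γ/β)/(γ−β), C_MAX = C_P(t_max), AUC = a(1/β − 1/γ)
(IV: A/α + B/β).

All rate constants are h⁻¹ and appear multiplicatively in the exponent;
presentations that quote phase "lifetimes" use the reciprocal, exposed as
`lifetimes_h` on both parameter types.

**Canonical parameterization.** The Bateman form has an exact exchange
symmetry — swapping γ and β while negating the amplitude reproduces the
same curve. All fitted and simulated parameter sets are canonicalized to
γ > β (IV: α > β, amplitudes travelling with their rates) so that "β"
stably names the slow elimination phase across Monte Carlo replicates;
this is what makes per-parameter quantiles meaningful. The degenerate
γ = β limit (the t·e^(−βt) form) is rejected rather than special-cased:
it is a measure-zero set never reached by the optimizer when rates start
distinct.

## Fitting

Ordinary (unweighted) least squares, minimized with the Nelder-Mead
simplex. The simplex runs in log-parameter space: every parameter is
positive, so optimizing logarithms gives unconstrained simplex moves while
eliminating sign-flip pathologies. Tolerances are relative 1e−8 on both
simplex size and objective (the function tolerance is scaled by the SSE at
the start point; the coordinate tolerance is applied to log-parameters,
which are O(1)), with at most 5,000 iterations and up to 3 restarts from
±20% multiplicatively jittered starts on non-convergence. Restart jitter
comes from a fixed-seed generator so fits are bit-reproducible. The
simplex never discards its best vertex, so the returned SSE never exceeds
the SSE of the initial guess. Non-convergence is reported on the result
(`converged=False`), never silently.

Initialization is automatic. The terminal 30% of points (log-linear fit,
requiring ≥ 3 positive values) gives the elimination rate and its
amplitude. For IM, the uptake rate comes from inverting the t_max relation
at the observed peak time (Brent root find; the peak-in-first-sample and
peak-later-than-1/β edge cases fall back to γ₀ = 2β₀), the amplitude from
the peak height. For IV, the fast phase is curve-peeled from the early
residual after subtracting the terminal exponential, with a fallback
(α₀ = 5β₀) when the distribution phase is invisible. Pre-dose baseline
rows (negative times) are excluded at ingest; t = 0 is administration.

A + B is left free in the IV fit (no dose/volume constraint), matching the
fully unconstrained regression the procedure is modelled on.

## Monte Carlo RMSE propagation

Uncertainty is a parametric-bootstrap variant: each of `n_iter` (default
5,000) iterations adds iid N(0, RMSE²) noise to the *observed*
concentrations — not the fitted curve; to first order both choices give
the same draw distribution because the original residuals are absorbed by
the point fit — refits starting from the point-estimate parameters, and
records the canonicalized parameters plus their analytic AUC (and C_MAX,
t_max for IM). Confidence intervals are empirical percentile intervals of
the retained draws, using linear interpolation between order statistics
(Hyndman–Fan type 7), pinned for reproducibility. Failed or non-converged
refits are dropped and counted rather than imputed — sentinel values would
bias the quantiles — and more than 20% failures is an error, not a wider
interval. AUC/C_MAX uncertainty is full nonlinear propagation (the derived
quantity is evaluated on every draw), never reconstructed from parameter
interval endpoints. Summaries report both the percentile CI and the draw
standard deviation, labelled, since "±" conventions differ.

On a dense design with small noise the procedure agrees with the
linearized (Jacobian) standard error; the test suite checks the β CI
half-width against an independently coded σ²(JᵀJ)⁻¹ oracle within 25%.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

- **Sampling designs.** `dense-EAB`: one sample every 7 s for 3 h
  (1,543 points), the indwelling-sensor design. `sparse-HPLC`: draws at
  0, 1, 5, 10, 30, 60 min, the blood-draw design; the ~1 min collection
  time of a real draw is ignored (instantaneous samples).
- **Subjects.** Sex (default 1:1), weight normal by sex (means 300 g male
  / 200 g female, CV 10%, truncated at 40% of the mean), BSA from the Meeh
  relation BSA = k·W^(2/3) with rat coefficient k = 9.83 (cm² from g); k
  and the exponent are configurable, not constants.
- **Inter-subject variability.** Log-normal per parameter (median +
  geometric SD), matching the multiplicative fold-spread language of
  animal PK. Defaults: IM medians a = 50 μM, γ = 6 h⁻¹, β = 0.5 h⁻¹
  (peak ≈ 37 μM, inside the ~11–88 μM therapeutic window quoted for
  aminoglycosides); IV medians A = 60, B = 30 μM, α = 3, β = 0.5 h⁻¹.
  β's geometric SD is exp(ln 6 / (2·1.96)) ≈ 1.58, which makes the
  2.5th–97.5th percentile ratio exactly 6-fold; other parameters use the
  analogous 3-fold value.
- **Null covariate structure.** By default the PK parameters are drawn
  independently of weight/BSA/sex — the regime in which BSA-adjusted
  dosing fails — with an optional per-parameter coupling exponent
  (BSA/BSA_ref)^c to simulate the alternative for power studies.
- **Noise.** Additive iid Gaussian, default sd 2 μM — a few percent of the
  peak, plausible for a sensor with a ~5 μM detection limit; it is a
  configuration default, not a claim about any instrument. An optional
  slow sinusoidal modulation of β (default fractional amplitude 0.15,
  period 2 h, off by default) stands in for hour-scale renal fluctuation;
  it is applied quasi-statically, re-evaluating the curve pointwise with
  β(t).

What the generator does **not** emulate: correlated sensor drift/fouling,
heteroscedastic or non-Gaussian measurement error, assay calibration
error, absorption-time dispersion, multi-dose accumulation, or any
physiological coupling beyond the optional BSA term. Passing tests
therefore demonstrate correctness of the estimator under its own model
assumptions, not robustness to real-sensor artifacts.

## Variability analysis

Per-cohort summaries: fold-range (max/min) of each quantity's point
estimates; OLS regressions of each quantity on BSA, weight and sex (coded
0/1; reported descriptively, no inferential test attached) with slope,
intercept and R². Under the independence null, cohort R² follows
Beta(1/2, (n−2)/2) — mean 1/(n−1) ≈ 0.059 at n = 18 (the median of this
skewed null is lower, ≈ 0.029) — so single-cohort R² values up to ~0.2 are
unremarkable. A constant response is reported as R² = 0; a constant
covariate (e.g. sex in a single-sex cohort) is rejected and surfaced as
NaN in cohort reports.

"Precision" of a sampling design is operationalized as Monte Carlo 95% CI
width. The dense-vs-sparse comparison simulates one profile per design
from the same truth and noise sd and reports width ratios per parameter.
The fold improvements are design- and noise-dependent, so the suite
asserts the ordering (dense strictly narrower) and the 1/√n thinning trend
(4× thinning ≈ 2× wider β interval) rather than any particular fold value.

## Problem sizes and numerical choices

Simulation-backed checks use deliberately chosen scales: noiseless
round-trips on the full 7 s grid; noisy recovery over 50 replicates;
coverage of the β CI over 80 replicates × 150 MC iterations on a
1-per-minute grid in the test suite, and 100 × 300 in
`scripts/acceptance.py` (coverage is a binomial proportion, so these
scales resolve the [90%, 99%] acceptance band without resolving, say,
94% vs 95%); the null-R² study uses 1,000 simulated cohorts. Seeds are
threaded through `numpy.random.SeedSequence` spawning so every stage is
independently reproducible. All file writes are atomic (temp file +
rename).

## Known limitations

- Percentile bootstrap intervals undercover slightly on strongly
  nonlinear/skewed parameters at small n; the dense designs used here are
  close to the linear regime.
- RMSE uses n rather than n − p in the denominator (the propagation noise
  therefore underestimates σ by √(1−p/n), negligible for dense profiles,
  a few percent for the 6-point sparse design).
- The sparse 6-point design barely identifies three parameters; its MC
  refits can fail more often, which is surfaced via the failure count.
- No weighted or robust regression, no mixed-effects population fitting,
  no ≥3-compartment or nonlinear-elimination models.
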