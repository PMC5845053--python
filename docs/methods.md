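# Methods

`dexpopk` implements the full population-pharmacokinetic analysis workflow
for dexmedetomidine given as long, variable-rate intravenous infusions to
ICU patients: structural two-compartment kinetics, nonlinear mixed-effects
(NLME) estimation, shrinkage-gated stepwise covariate search, nonparametric
case bootstrap, and prediction-corrected visual predictive checks, together
with a synthetic cohort generator that reproduces the study design so every
stage can be exercised and validated without access to patient data.

## Structural model

Plasma concentration in the central compartment follows linear
two-compartment disposition under a piecewise-constant infusion `R(t)`:

    V_C dC_P/dt = R(t) − CL·C_P − Q·C_P + Q·C_T      C_P(0) = 0
    V_T dC_T/dt = Q·C_P − Q·C_T                       C_T(0) = 0

Units are fixed package-wide — doses in μg, volumes in L, times in h — so
concentrations come out in μg/L, numerically identical to the assay's
ng/mL, and literature parameter values can be used without conversion.

The closed form used everywhere is the bi-exponential unit-step response
superposed over segment start/stop events, with hybrid rate constants
λ₁ > λ₂ > 0 obtained from the cancellation-free discriminant
√((k10+k12−k21)² + 4·k12·k21).  When the relative eigen-gap falls below
1e−7 a confluent (repeated-eigenvalue) series branch is used; with
physiological parameters this branch is effectively unreachable but keeps
the solver total.  Concentration is continuous across segment boundaries
(only its derivative jumps), so boundary evaluation needs no left/right
convention.  An adaptive stiff ODE integration with event stops at every
segment boundary serves as the independent numerical oracle; its state is
augmented with the eliminated mass so exact mass balance can be asserted.

## Statistical model

Individual parameters are lognormal around covariate-adjusted typical
values, and residual error is proportional:

    P_i   = TV_P(x_i) · exp(η_P,i),    η_P,i ~ N(0, ω_P²)   (diagonal Ω)
    C_obs = C_P(t; P_i) · (1 + ε),     ε ~ N(0, σ²)

Between-subject variability is reported as percent CV.  Two conventions
circulate; the package's primary convention is the exact lognormal CV,
`100·√(exp(ω²)−1)`, with the first-order `100·√ω²` also emitted in every
report.  All simulation truth and all recovery reporting use the lognormal
convention consistently, so recovery checks are convention-invariant.  For
the proportional residual error, `%CV = 100·σ`.

A diagonal Ω is deliberate: the study found no clear correlations between
random effects, and the sparse cohort would not support estimating them.

## Likelihood approximation

The per-subject marginal likelihood integrates the conditional likelihood
over η.  Two approximations are implemented, selectable per fit:

- **FOCE-I** (default): linearize the structural model in η around the
  per-subject posterior mode η̂ and evaluate the proportional residual
  variance at η̂ ("interaction"), giving a closed-form Gaussian marginal
  assembled with the Woodbury identity and the matrix determinant lemma.
- **Laplace**: mode plus log-determinant of the full finite-difference
  Hessian of the joint −2·log-likelihood.

Both are exact when the model is linear-Gaussian in η; the test suite
verifies this against the closed form and against 41-node adaptive
Gauss–Hermite quadrature (the engine-independent oracle, implemented for
small random-effect dimensions by cloning the subject across quadrature
points).  On nonlinear problems the two differ from quadrature by their
usual approximation error — Laplace tracked quadrature to ~0.05 OFV and
FOCE-I to ~0.7 OFV on a four-subject single-η benchmark — which is the
expected behavior, not a defect.

The OFV is −2·log marginal likelihood *including* the 2π constants, so
absolute values differ from NONMEM's customary output by n·log 2π; all
model selection uses OFV differences, which are unaffected.

### Inner problem

Each objective evaluation finds every subject's η̂ by a batched two-phase
Newton method: a Gauss–Newton phase using the exact residual curvature
∂²h/∂f² (clipped positive; always PD together with the prior term), then
full Newton steps with a finite-difference Hessian for quadratic terminal
convergence.  Gradients use a central-difference Jacobian of the
predictions (step 1e−4 on η); convergence is declared at a max-gradient of
3e−7, the resolution the finite-difference Jacobian supports.  Modes are
warm-started across outer iterations; if a warm start strands the solver
(gradient above 1e−3), it is re-run cold and the better mode kept per
subject.

### Outer problem

Population parameters are optimized by L-BFGS-B in transformed space —
log θ, log ω², log σ², covariate coefficients β unconstrained — which
enforces positivity without constraints.  The gradient uses *central*
finite differences (relative step 1e−4): the OFV carries small
inner-solver noise that forward differences amplify into a useless
gradient.  Infeasible regions (non-positive covariate-adjusted typical
values, overflowing parameters, failed factorizations) return a large
finite penalty rather than infinity, which keeps the Fortran line search
well-behaved.  Wide box bounds are imposed in transformed space; the one
that matters is the floor on log ω² (−8, about 1.8% CV): the likelihood
is flat once a variance is effectively zero, and without the floor the
optimizer crawls toward −∞ burning iterations.  A variance ending on this
floor is what the bootstrap bookkeeping reports as "terminated at a
boundary".  Because L-BFGS-B line searches can still stall on residual
noise, the optimizer is restarted from the incumbent optimum until the
gain per round drops below 0.01 OFV (at most 3 rounds by default) — a
fresh round that cannot improve the incumbent also serves as the
convergence criterion — and a first round defeated outright by an
ill-scaled start (this happens with near-zero residual variance and badly
wrong initial values) is rescued by one unbounded round whose result is
clipped back into the box.

Initialization is a naive two-stage fit: each subject's profile is fitted
by log-scale least squares (starting from a crude clearance estimate,
mean infusion rate over mean concentration), typical values are the
geometric medians of the per-subject estimates, and the starting ω² is the
spread of those estimates capped at 0.5 — the spread includes estimation
noise, so starting modest and letting the population fit expand it proved
much more reliable than starting wide.  σ² starts at 0.04.

### Standard errors, shrinkage, diagnostics

%RSE comes from the inverse of the central-finite-difference Hessian of
OFV/2 at the optimum, on the natural scale (θ, β, ω², σ²); a non-positive
definite Hessian yields missing values with a warning, never fabricated
numbers.  η-shrinkage is `100·(1 − SD(η̂)/ω)` with the population (n)
denominator.  Diagnostics export PRED (η = 0), IPRED (η = η̂) and weighted
residuals `(DV − PRED)/(PRED·σ)` as a tidy table.

## Covariate search

Only parameters with η-shrinkage strictly below 25% are screened — shrunk
empirical Bayes estimates are uninformative about covariate relationships.
Candidates are (parameter, covariate) pairs; continuous covariates are
tried as both a linear and a power relationship (the better OFV
represents the candidate; a single form can be forced), categorical ones
as indicator terms.  Continuous references are the study medians (weight
75 kg, age 59.5 y, infusion duration 42.8 h, SOFA 12), keeping θ the
typical-reference-patient value.  Forward selection includes the candidate
with the largest OFV drop when it exceeds χ²₁(0.95) = 3.84 (p < 0.05);
backward elimination removes the cheapest term while removal costs less
than χ²₁(0.99) = 6.63 (p < 0.01).  Exact ΔOFV ties break by enumeration
order (parameters CL, V_C, V_T, Q; covariates age, weight, sex, duration,
inotropes, SOFA).  Candidate fits that fail to converge are skipped for
that step and logged in the trace, which is exportable as a tidy CSV.

The published inclusion rule is quoted as "ΔOFV < 3.84"; read literally it
would admit every candidate, so the package implements the standard
meaning — include when the drop *exceeds* 3.84 — consistent with the
stated p < 0.05.

## Bootstrap

Nonparametric case bootstrap: whole subjects resampled with replacement at
the original cohort size, fresh ids per draw, each replicate refitted from
the base-model optimum (mirroring common practice; it sharply reduces
replicate failures).  Early terminations — optimizer non-convergence,
non-finite OFV, a parameter at its transformed-scale bound — are counted,
reasons logged, and excluded from the percentile summaries; more than 50%
failures flags the whole result unreliable.  Intervals are plain
percentiles (5th–95th for the 90% interval); no BCa.  Resampling is
unstratified by default with optional strata (e.g. sampling protocol).
The full index matrix is drawn up front from the seed, so results are
bit-reproducible.

## Prediction-corrected VPC

Weight-scaled rates, mid-course dose adjustments and two sampling
protocols make raw percentile VPCs incoherent across subjects, so observed
and simulated values are prediction-corrected:
`pcY = Y · PRED_bin / PRED`, with PRED the population prediction (η = 0)
of the final fit.  The bin reference is the *median* PRED by default (the
robust choice in the reference methodology; the mean is selectable and the
choice is recorded in the summary metadata).  Bins default to 10
equal-count quantile bins of observed time, computed once and shared by
observed and simulated values; a distinct-time strategy reproduces nominal
design times when sampling is exactly nominal.  Replicate datasets redraw
η and ε on the original design; the observed 10th/50th/90th percentiles
are compared per bin against the 2.5–97.5 percentile band of the same
statistic across replicates.

## Synthetic cohort generator

The generator reproduces the study design: 27 subjects by default (22 on
the short-protocol rich sampling, 5 on the extended protocol), weight
45–100 kg, age 19–84 y, infusion durations 23.7–102 h, infusion started at
0.8–1 μg/kg/h and maintained at 0.4–1.5 μg/kg/h with 0–3 recorded step
adjustments at random times (step changes, not ramps — the only reading
consistent with discrete recorded dose adjustments), no loading dose.
Weight and age come from range-truncated normals and duration from a
truncated lognormal whose location parameters are calibrated numerically
so the *post-truncation* median matches the study median exactly; only
medians and ranges were reported, so the distributional shapes are
declared assumptions carried in the config.  Sex (17:10 male:female),
inotrope use (21:27) and SOFA (integers 5–16 centered at 12) match the
demographic table.  Rate-adjustment frequency is not reported; 0–3
adjustments per subject is the package's documented default.

Simulated observations apply the lognormal η and proportional ε draws with
ε truncated at −0.999 so concentrations stay positive (the study reported
no below-quantification measurements).  The pre-dose sample carries zero
drug and a proportional-error model is undefined at zero concentration, so
the design's t = 0 draw produces no concentration record.  The latent
truth (η draws, noise-free profiles) always accompanies the observable
table for recovery scoring.

What the generator does *not* emulate: assay error structure beyond the
proportional model, deviations from nominal sampling times (available but
off by default), time-varying covariates, dropout beyond duration
truncation, and any PK nonstationarity over long infusions.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the declared model, not robustness to real-data
misspecification.

## Validation experiments and problem sizes

- **Parameter recovery**: cohorts of 100 subjects simulated at the
  published estimates, refitted from the two-stage initializer, medians
  compared with truth (±10% for CL, ±20% for the other typical values,
  ±25% on the CV scale for CL IIV and σ).  100 subjects rather than 27
  separates estimator bias from small-cohort noise; a cohort fit takes
  tens of seconds with the closed-form model.  The reproduction script
  runs 20 replicate cohorts; the test suite runs 10, which already pins
  the medians well inside the declared tolerances.
- **Covariate type-I error**: 200 null cohorts, one-compartment reduction,
  30 subjects each.  With rich per-subject data the covariate LRT behaves
  like a t²(n−2) test, whose true level at the 3.84 cut is ≈8.3% at
  n = 10 but ≈6.0% at n = 30 — the smallest size whose small-sample
  inflation is below what a 200-replicate binomial check can resolve.
- **pcVPC calibration**: six model-true datasets, 200 simulation
  replicates each; observed percentiles must sit inside their 95% bands
  in ≥90% of bin×percentile cells on average.

## Known limitations

- FOCE-I shares the well-known small-sample biases of linearized NLME
  estimators; with the study's large IIV (80–124 %CV) the inter-
  compartmental clearance recovers with a mild upward median bias (~10%,
  within the declared tolerance) while the other parameters center well.
- The covariate LRT is anticonservative for small cohorts (see above);
  at the study's n = 27 the effective forward α is closer to 0.07 than
  0.05, which is a property of the method, not of this implementation.
- Standard errors use the OFV Hessian only (no sandwich estimator).
- No below-quantification-limit likelihood, no inter-occasion
  variability, no full Ω, no three-compartment disposition — all outside
  the analysis this package reproduces (the engine does fit the
  one-compartment reduction for model-comparison exercises).
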