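# Methods

## The model family

Respiratory CO2 exchange under mechanical ventilation is described with two
well-mixed compartments — lung gas and body tissue — exchanging CO2 via the
circulation, with gas transport between them approximated as pure delays.
With the linearised dissociation relation C = αP + β (α = 0.0065
l_STPD/(mmHg·l), β = 0.244 l_STPD/l) and the BTPS/STPD factor λ = 863 mmHg,
the state equations in alveolar (x1 ≈ PetCO2) and mixed-venous (x2) tension
are

    ẋ1 = −θ1·x1·u + θ2·[x2(t−τ1) − x1]
    ẋ2 =  θ3·[x1(t−τ2) − x2] + θ4

with u the minute ventilation (l/min, dead space neglected) and

    θ1 = 1/VL,  θ2 = αλQ/VL,  θ3 = Q/VB,  θ4 = V̇CO2/(αVB).

The physical parameters (lung volume VL, tissue volume VB, cardiac output Q,
metabolic production V̇CO2) are uniquely recoverable from Θ; only the total
circulatory delay τ = τ1 + τ2 is visible in PetCO2 data, a fact the package
verifies numerically (different τ1/τ2 splits of the same total give
identical x1 trajectories).

Three nested candidates are compared:

* **M3** — the model above, discretised by forward differences into a
  second-order regression with five lumped coefficients
  Ω3 = [θ1, θ2+θ3, θ1θ3, θ2θ3, θ2θ4] and an integer-sample delay;
* **M2** — the same without the delay column (four coefficients);
* **M1** — lungs and tissue merged into one compartment, a first-order
  regression with two coefficients [1/(VL+αλVB), λV̇CO2/(VL+αλVB)], whose
  lumping is deliberately not inverted (the volumes are not separable).

M2 is nested in M3 only at τ = 0, where the delay regressor
x1(k−τ) − x1(k) vanishes identically.  For τ ≥ 1 the delay coefficient
θ2θ3 is pinned by the other coefficients (θ3 = Ω[2]/Ω[0] etc.), so the M3
optimum can sit a small structural margin *above* the M2 optimum when the
delay grid excludes zero; comparisons therefore use medians and paired
tests, not per-subject inequalities.

## Simulation

The continuous reference integrator is a fixed-step classical 4th-order
Runge–Kutta with a solution-history buffer and linear interpolation for
the delayed lookups (constant pre-history; zero delays fall back to plain
ODE coupling).  Fixed step was chosen over adaptive stepping for bitwise
reproducibility; the dynamics are smooth and non-stiff at the default
dt = 0.1 s.  The unmeasured venous state defaults to its quasi-equilibrium
offset x2(0) = x1(0) + θ4/θ3.

The discrete predictors are the exact identification recursions: the model
is run forward from the first one (M1) or two (M2/M3) measured PetCO2
samples, driven only by the measured ventilation and its own past output
("pure", infinite-step-ahead prediction).  Samples before the record start
are held at the first value (steady pre-record breathing); the input's
forward difference at the last sample holds u constant.  Internally all
rates are per minute (5 s = 1/12 min), so cardiac output and ventilation
in l/min enter without conversion; file interfaces use seconds.

Verified behaviour: at constant ventilation both simulators settle on the
hyperbolic steady state x1 = λ·V̇CO2/u (the slow mode — whole-body CO2
store washout — has a ~16-min time constant at cohort-median physiology,
so the 0.1 % band needs a ~2-h horizon); the recursion converges to the
delay-ODE solution with observed order ≈ 1.0 as the 5-s step is halved,
leaving a ~0.3 mmHg peak discretisation error at trend resolution.

## Identification

Each model is fitted per subject by minimising the mean-squared pure
prediction error J(Θ, τ) (seed samples excluded from N).  Because τ enters
the regressor non-linearly it is searched exhaustively over an integer
grid, default 1..12 samples (5–60 s at 5-s sampling, the physiologic
circulatory-delay window; the reported subject-level delays fall inside
it).  At each τ the rate parameters are optimised by multi-start (default
8) trust-region least squares on log-parameters — the objective is a sum
of squares and the parameters span orders of magnitude across subjects —
inside generous positive boxes (θ1 ∈ [0.01, 100] l⁻¹, θ2 ∈ [0.01, 100]
min⁻¹, θ3 ∈ [0.001, 50] min⁻¹, θ4 ∈ [0.01, 500] mmHg/min).  Start points
are log-uniform from a seeded generator; the previous delay's optimum is
recycled as an extra warm start; ties prefer the smaller delay.  Divergent
recursions are capped at ±10⁷ mmHg so the trust region sees finite (huge)
residuals, and the scalar objective reports +inf for such points.  Fits
are bitwise deterministic given the record and options.

## Comparison metrics

* **RMSE** of the pure prediction, mmHg, over predicted samples.
* **Asymptotic variance** (prediction-error-method approximation):
  Var ≈ (1/N)·λN·SN with SN the inverse sensitivity covariance.  It is
  evaluated on *equation-error* residuals — second forward difference of
  the data minus Ωᵀψ for M2/M3, first difference for M1 — because in that
  convention the sensitivity has the closed form −(∂Ω/∂Θ)ᵀψ(k, τ).
  Reported as percent standard deviation per parameter.  A near-singular
  sensitivity covariance is pseudo-inverted and flagged; the weakly
  excited direction in this family is θ4, whose regressor is the constant
  1 — the synthetic cohorts reproduce the expected pattern (θ4's percent
  deviation largest).
* **AIC** with the small-sample correction, AIC = N·ln λN + 2K +
  2K(K+1)/(N−K−1); K counts optimised quantities (M1: 2, M2: 4, M3: 5 —
  Θ plus the delay).  By default λN here uses *pure-prediction* residuals,
  not equation errors: the natural equation error is first-order for M1
  and second-order for M2/M3, so its variance carries different units
  across models and N·ln λN would shift the cross-model comparison by an
  arbitrary unit factor (≈ N·ln 144 at 5-s sampling).  Prediction
  residuals are in mmHg for every model, making the per-subject AIC
  frequency count meaningful.  Both conventions are exposed via a switch
  on every metric.
* **Cohort comparison**: median (IQR) tables of RMSE and recovered
  physiology, two-sided paired t-tests (per-subject RMSE for each model
  pair; each θ's asymptotic variance for M2 vs M3; no multiplicity
  correction, plain p < 0.05), and per-model counts of minimum-AIC
  subjects.

## Synthetic cohort

No clinical records are available, so the generator emulates the study
conditions: 24-min records at 5-s trend sampling; caregiver-style
protocols of 5 constant-setting segments with respiratory rate drawn from
7–13 min⁻¹ and tidal volume from 150–300 ml (mean V̇ ≈ 2.25 l/min,
matching the reported medians), first-order transitions (15 s); segment
draws are rejected until the ventilation excursion max|u−ū|/ū reaches
40 %, which reproduces both the ">30 % change in every subject" property
and the reported cohort-mean (max−min)/mean of ~0.8–0.9.  Ventilation is
u = RR·TV with no dead-space correction, consistent with the model's
assumption.  Peak pressure and I:E ratio are carried as annotations only.

Ground-truth physiology is drawn log-normally with medians at the
reported subject-level values (VL 2.28 l, VB 4.67 l, Q 1.20 l/min, V̇CO2
0.12 l/min) and σ set from the reported IQRs; draws are truncated by
resampling to each marginal's central 90 % because the unbounded tails
(e.g. Q > 20 l/min) are not physiologic and alias at 5-s sampling.  The
total delay is uniform on 10–60 s, split evenly between the two legs (only
the sum is identifiable).  Because production and ventilation are drawn
independently, each subject's tidal-volume scale is titrated so the mean
ventilation targets normocapnia (PetCO2 ≈ 40.8 mmHg) — mirroring how
caregivers actually set the ventilator and keeping the cohort PetCO2 in
the observed 30–55 mmHg band.  (Record-mean PetCO2 still sits slightly
above the target because PetCO2 ∝ 1/u and the time-average of 1/u exceeds
1/ū.)  Records are simulated continuously at dt = 0.1 s, sampled at 5 s,
and corrupted with i.i.d. Gaussian noise on PetCO2 only (default
σ = 0.5 mmHg, ~1 % of normocapnia; the real monitor's trend filtering is
unknown, so white noise is a modelling choice, not a device claim).  A
"discrete" generation route runs the identification recursion itself —
the self-consistent oracle used by recovery studies.

What the synthetic cohort does *not* emulate: breath-by-breath tidal
dynamics, dead space and shunt, time-varying cardiac output or metabolism,
monitor filtering, and any unmodelled physiology.  Passing tests on this
cohort therefore demonstrate correctness of the pipeline and the
information content of trend data under the model's own assumptions — not
clinical validity.

## Identifiability of the transport delay

A central empirical finding of the recovery studies: the delay is only
weakly identifiable from noisy trend data once the rate parameters are
re-optimised.  Expanding the delay regressor for small τ,

    x1(k−τ) − x1(k) ≈ −τ·Ts·ẋ1(k) + (τ·Ts)²/2·ẍ1(k) − …,

the first-order term is collinear with the existing −ẋ1 regressor (it
shifts θ2+θ3) and the second-order term is collinear with the ẍ1
left-hand side (it rescales all of Ω).  Only third-order structure and
transition kinks distinguish delays.  Measured on noiseless synthetic
subjects, the re-optimised objective varies by only ~1e-4..2e-3 mmHg²
across the whole delay grid, while the discrimination threshold at
σ = 0.5 mmHg over N ≈ 286 samples is ~2λ/N ≈ 2e-3 mmHg².  Consequences,
all reproduced by the studies here:

* noiseless recovery is exact (delay sample-exact, rates to ~1e-13);
* under 0.5 mmHg noise the delay estimate scatters across the grid and
  drags VL (and partly Q) tens of percent along the compensation ridge,
  while V̇CO2 and VB remain well determined;
* the delay model's RMSE edge over the delay-free model is small
  (medians ~0.526 vs ~0.534 mmHg at the 0.5-mmHg noise floor), its paired
  t-test hovers near p ≈ 0.07–0.09, and the per-subject AIC count splits
  toward the delay-free model (≈ 17 vs 8 of 25), because most subjects'
  delay-misfit penalty falls below the AICc threshold e^(2/N) − 1 ≈ 0.7 %.

This is a property of the model family and data modality, insensitive to
protocol shaping (step vs smoothed transitions, more segments, wider
excursions were all tried).  On real records — whose ~1 mmHg residuals are
dominated by unmodelled physiology rather than sensor noise — the AIC
comparison can favour the delay model, but such residual structure cannot
be honestly synthesised from the model itself plus white noise.

## Numerical choices and degenerate inputs

* Delays are stored as integer sample counts, rounding (τ1+τ2)/Ts to the
  nearest integer; sub-sample delays are not represented.
* The recursion seeds are the first measured samples (exactly as many as
  the recursion order needs); their noise persists on the slow mode and
  is part of the noisy-recovery error budget.
* Equation-error residual counts: N−1 (M1), N−2 (M2/M3); prediction
  residual counts exclude the seeds.  AIC refuses N ≤ K+1; zero residual
  variance (perfect fit) raises rather than returning −∞.
* θ → Ω inversion uses coefficients {0,1,2,last} and checks the redundant
  M3 coefficient θ2θ3 as a consistency residual (warning above 1e-6
  relative).
* Protocols failing the excursion requirement after 100 redraws raise
  with advice to widen the ranges; a single-segment protocol always fails.

## Problem sizes

Default study sizes were chosen to resolve the quantities of interest:
2-h steady-state runs at dt = 0.1 s; three-step convergence studies on
20-min records; recovery studies of 10 subjects; cohort comparisons of
25 subjects × 3 models with an 8-start, 12-delay search (~4 minutes on a
single core).
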