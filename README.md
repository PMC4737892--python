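# co2exchange

Compartmental modelling and identification of respiratory CO2 gas exchange
under mechanical ventilation.

Closed-loop end-tidal CO2 controllers need a low-order, physiologically
transparent model of how end-tidal CO2 tension (PetCO2) responds to minute
ventilation.  This package implements, end to end, a comparative data-based
modelling analysis of three such candidate models, fitted per subject from
routine 5-s trend data (PetCO2 + minute ventilation) and compared for
predictive capability and reliability.  Because clinical records of this
kind are not publicly available, the package also includes a synthetic
cohort generator that emulates the relevant study conditions (24-min
records, normocapnic ventilation, large caregiver-style ventilation
changes), so the whole analysis is reproducible from a single seed.

## The models

Lungs and tissue are treated as well-mixed compartments exchanging CO2 via
the circulation, with transport approximated as pure delays.  With Henry's
law C = αP + β and the BTPS/STPD factor λ = 863 mmHg:

    ẋ1 = −θ1·x1·u + θ2·[x2(t−τ1) − x1]        x1 = PACO2 ≈ PetCO2
    ẋ2 =  θ3·[x1(t−τ2) − x2] + θ4             x2 = PvCO2 (unmeasured)

    θ1 = 1/VL,  θ2 = αλQ/VL,  θ3 = Q/VB,  θ4 = V̇CO2/(αVB)

* **M3**: the model above, discretised into a second-order regression with
  lumped coefficients Ω3 = [θ1, θ2+θ3, θ1θ3, θ2θ3, θ2θ4] and an
  integer-sample combined delay τ = τ1 + τ2;
* **M2**: the same without the delay term;
* **M1**: a single merged compartment (first-order, two coefficients).

Each model is identified per subject by minimising the mean-squared *pure*
(infinite-step-ahead) prediction error, with multi-start bound-constrained
least squares over log-rate-parameters and exhaustive search over the
integer delay.  Models are compared by prediction RMSE, Ljung-style
asymptotic parameter variance, small-sample-corrected AIC, and paired
t-tests across the cohort.  Lung volume VL, tissue volume VB, cardiac
output Q, and CO2 production V̇CO2 are recovered uniquely from the fitted
Θ; only the total delay is identifiable.

## Worked example

```python
from co2exchange import FitOptions, PhysioParams, fit_model
from co2exchange.cohort import ProtocolSpec, SubjectSpec, generate_subject

truth = PhysioParams(VL=2.28, VB=4.67, Q=1.20, VCO2=0.12, tau1=10.0, tau2=10.0)
subject = generate_subject(
    SubjectSpec(physio=truth, protocol=ProtocolSpec(seed=3), noise_sd=0.5, seed=11)
)
fit = fit_model(subject.record, "M3", FitOptions(seed=1))
est = fit.physio_star
print(f"RMSE ~ {fit.J_star**0.5:.3f} mmHg, tau* = {fit.tau_star*5} s")
print(f"VL={est.VL:.2f} l  VB={est.VB:.2f} l  Q={est.Q:.2f} lpm  VCO2={est.VCO2:.3f} lpm")
```

prints

```
RMSE ~ 0.586 mmHg, tau* = 5 s
VL=0.51 l  VB=5.00 l  Q=1.38 lpm  VCO2=0.120 lpm
```

The fit reaches the 0.5-mmHg measurement-noise floor, and V̇CO2, VB and Q
land near their true values — but the delay (truth 20 s) and lung volume
do not.  That is not an optimiser failure: with the same subject generated
noiselessly the fit returns `tau* = 20 s, VL=2.28, VB=4.67, Q=1.20,
VCO2=0.120` exactly (objective ~1e-28).  The transport delay enters the
regression almost collinearly with the other terms, so 0.5 mmHg of trend
noise erases it and drags VL along the compensation ridge — a central
finding of the recovery analysis, dissected in
`docs/methods.md` ("Identifiability of the transport delay").

## The analysis

Numbered drivers under `analysis/` run the full study and write their
tables under `results/`:

1. `01_simulate_cohort.py` — generate 25 synthetic subjects from
   ground-truth M3 physiology (log-normal around the reported medians,
   delays 10–60 s, 0.5 mmHg noise) and summarise the cohort;
2. `02_fit_models.py` — fit M1/M2/M3 to every record;
3. `03_compare_models.py` — median (IQR) tables, paired t-tests, AIC
   minimum-frequency counts, and estimate-vs-truth recovery tables;
4. `04_parameter_recovery.py` — noiseless and noisy recovery studies.

A thin CLI wraps the same pipeline (`co2exchange run-all --out runs/demo
--seed 7`), and `co2exchange generate/fit/report` run the stages
separately on CSV records.

On the default cohort the comparison reproduces the expected structure:
median RMSE 1.30 / 0.534 / 0.528 mmHg for M1 / M2 / M3, with the
one-compartment deficit strongly significant (paired p ≈ 2e-4).  The
delay model's edge over the delay-free one at this noise level is small
(p ≈ 0.08; AIC minima split 18 M2 / 7 M3) — see the methods note for the
identifiability analysis behind that.

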