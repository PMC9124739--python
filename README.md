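# vancosorb

Population pharmacokinetics of vancomycin in critically ill patients on
continuous renal replacement therapy (CRRT) whose circuit intermittently
contains a **CytoSorb** hemadsorption cartridge.  The adsorber is intended to
remove cytokines, but it also binds vancomycin: serum concentrations drop
while it is installed, and a finite cartridge capacity means the loss is
front-loaded.  This package implements the full analysis chain needed to
quantify that loss and to derive a compensatory dosing rule:

* a one-compartment disposition model with zero-order (infusion) input and a
  **saturable adsorption clearance**,
* nonlinear mixed-effects (Laplace) estimation with likelihood-ratio model
  selection and profile-likelihood confidence intervals,
* a synthetic therapeutic-drug-monitoring (TDM) cohort generator with known
  ground truth, and
* a stochastic dosing simulator (n = 3000 virtual patients) for
  exposure-based dose adaptation.

## Model

For individual *i* at time *t*, with central amount `A(t)` and amount
`A_f(t)` already bound to the installed cartridge:

```
CL_base,i = CL_typ * (1 + θ_Q * (Q - 2000)) * exp(η_i),   η_i ~ N(0, ω²)
CL_ads(t) = V * k_max * (1 - A_f(t)/A_max)        (linear saturable, while on)
dA/dt   = R(t) - (CL_base,i + CL_ads(t)) * A(t)/V
dA_f/dt = CL_ads(t) * A(t)/V
C(t)    = A(t)/V,   observed y = C + ε,  ε ~ N(0, σ²)
```

`Q` is the CRRT effluent flow (mL/h, centered at 2000), `R(t)` the infusion
rate (mg/h).  A hyperbolic decrease (`k_max·A50/(A_f + A50)`) and a
categorical on/off clearance effect are available as competing adsorption
models.  Reference estimates (`vancosorb.reference_parameters()`):
CL 2.29 L/h, V 98.1 L, θ_Q 3·10⁻⁴ per mL/h, k_max 0.068 h⁻¹, A_max 572 mg,
ω 14.4 CV%, σ 3.55 mg/L.

## Worked example

```python
import vancosorb as vs

p = vs.reference_parameters()

# clearance bookkeeping at a fresh cartridge
env = vs.EnvironmentAtTime(infusion_rate=0, effluent_flow=2000, cyto_on=True)
print(vs.total_clearance(p, 0.0, env, a_filter=0.0))   # 8.9608 L/h
print(vs.base_clearance(p, 0.0, 2000.0))               # 2.29 L/h
print(vs.classify_adsorption(291.3))                   # 'moderate'

# how much one cartridge can ever bind
print(vs.closed_form_adsorbed(p, conc=16.0, duration=1000.0))  # 572.0 mg

# exposure with and without the adsorber (3000 virtual patients)
base = vs.DosingScenario(maintenance_rate=46.0)
cyto = vs.DosingScenario(maintenance_rate=46.0, cytosorb_start=10.0)
comp = vs.DosingScenario(maintenance_rate=46.0, cytosorb_start=10.0,
                         extra_dose_mg=500.0)
study = vs.compare_scenarios(p, base, [cyto, comp], n_replicates=3000, seed=0)
print(round(study["base"].auc_median, 1))          # 486.0 mg·h/L
print(round(study["variants"][0].auc_median, 1))   # 396.9 mg·h/L
print(round(study["variants"][1].auc_median, 1))   # 484.4 mg·h/L
print(vs.find_minimum_rate(p)["rate"])             # 46.0 mg/h
```

Interpretation: at the minimum maintenance rate keeping the median
steady-state concentration above 20 mg/L (46 mg/h), installing a fresh
adsorber costs roughly 90 mg·h/L of 24-h exposure; a single extra 500 mg
infusion over 2 h at installation time recovers almost all of it.  The same
workflow is scriptable from the shell (`vancosorb generate / fit / lrt /
profile / simulate / gof / summarize`); every stochastic command writes a
manifest (seed, config hash, version) for bit-identical regeneration.

Fitting on a synthetic cohort:

```python
ds, truth = vs.generate_cohort(vs.study_mimic_config(seed=1))
spec = vs.ModelSpec(adsorption_model="linear_saturable",
                    fixed={"v": 98.1, "cov_effluent": 0.0003})
result = vs.fit(spec, ds)          # Laplace mixed-effects fit
print(result.ofv, result.eta_shrinkage)
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the clearance identities of the final
model (percent clearance increase at a fresh cartridge; effect of doubling
the effluent flow), the saturation plateau of the adsorbed amount (ODE
integration cross-checked against the closed form), the median 24-h AUC of
the compensated dosing scenario and its paired deficit versus the
no-adsorber reference (n = 3000, common random numbers), and the
minimum-rate search — and writes them as JSON.

## Layout

```
src/vancosorb/
  params.py    parameter containers, reference estimates
  model.py     clearance laws, ODE right-hand side, event-driven simulator
  _fast.py     likelihood-grade trajectory kernel (numba optional)
  dataset.py   event-record CSV IO, validation, cohort summary
  cohort.py    synthetic TDM cohort generator + ground truth
  estimate.py  Laplace OFV, fits, LRT, profile CIs, shrinkage, GOF
  dosing.py    stochastic exposure simulation, dose-adaptation search
  cli.py       command-line pipeline
docs/methods.md   modelling and numerical documentation
```
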