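# Methods

## Model and assumptions

Vancomycin disposition is a one-compartment model with zero-order input
(every administration is an infusion; bolus records are rejected by the
dataset schema) and first-order elimination.  In an anuric CRRT population
the circuit is the dominant elimination route, so clearance carries a linear
covariate in the effluent flow `Q` (dialysate + substitution, mL/h),
centered at the reference intensity of 2000 mL/h:

    CL_base,i = CL_typ · (1 + θ_Q (Q − 2000)) · e^{η_i},  η_i ~ N(0, ω²).

Between-patient variability is a single lognormal random effect on
clearance; none is carried on V (a sparse 7-patient design cannot support
more).  Residual error is additive on the concentration scale by default;
proportional and combined error models are selectable and enter the same
likelihood machinery.

While a CytoSorb cartridge is in the circuit it contributes an extra,
capacity-limited clearance.  Three competing formulations are implemented:

* **linear saturable** (final model): `CL_ads = V·k_max·(1 − A_f/A_max)` —
  the adsorption rate constant decays linearly in the amount already bound,
  reaching zero at the cartridge capacity `A_max`;
* **hyperbolic saturable**: `CL_ads = V·k_max·A50/(A_f + A50)`;
* **categorical**: a constant proportional clearance increase while the
  adsorber is on (no amount dynamics).

The random effect multiplies only the base clearance, not the adsorption
term, mirroring the additive structure of the individual-clearance equation;
the adsorption term is a device property, not a patient property.

At a held concentration the linear model has the closed form
`A_f(t) = A_max(1 − exp(−V·k_max·C·t/A_max))`, which the test-suite uses as
an integrator-independent oracle.  Severity of an adsorption interaction is
classified from the maximal percent clearance increase: >10% mild, >100%
moderate, >400% strong (strict inequalities).

### States and mass balance

The simulator tracks central amount, cartridge-bound amount, and
cumulatively eliminated amount, so that at every output point
`input = A + A_f(+previous cartridges) + A_eliminated` is checkable; tests
require ≤1e-6 relative error.  Each new `filter_id` resets the bound amount
to zero: capacity is per cartridge, which is exactly why a compensatory dose
is needed again at every exchange.

## Numerical choices

* **Reference integration** (`simulate_profile`): LSODA, rtol 1e-8,
  atol 1e-10 mg, restarted hard at every event boundary (dose start/end,
  covariate change, adsorber on/off, cartridge exchange) so discontinuities
  never sit inside a solver step.  Cut points closer than 1e-9 h (float
  noise from `amt/rate` reconstruction) are merged.  A bound amount
  overshooting `A_max` by more than 1e-6·A_max raises; smaller overshoot is
  clamped.
* **Likelihood kernel** (`_fast.py`): off-adsorber segments are advanced by
  the exact closed form of the linear constant-coefficient system;
  on-adsorber segments by fixed-step RK4 with step ≤ 0.02 h.  Numba-jitted
  when available, with an identical pure-Python fallback.  Agreement with
  the reference path is pinned at ≤1e-6 relative in tests — the fast path is
  never its own oracle.
* **Exposure simulator** (`dosing.py`): all replicates advance together
  through a vectorized RK4 (step 0.02 h, scenario times quantized to the
  step); the AUC is carried as an auxiliary quadrature state, not a
  trapezoid afterthought.  Validated against an adaptive solve at 1e-11
  tolerance.
* **Laplace OFV**: per subject, the conditional objective
  `g(η) = Σ r²/var + Σ log var + η²/ω²` is minimized by safeguarded Newton
  (central differences, tolerance 1e-10, started at 0, bounded fallback),
  and `OFV_i = g(η*) + log(ω²·g''(η*)/2)`.  The reported OFV drops the
  `n·log 2π` constant (common pharmacometric convention, stated in the
  FitResult metadata); only differences between nested models on the same
  data are meaningful, which is all that model selection uses.  The ω→0
  limit reduces exactly to the fixed-effects weighted least-squares −2LL.
  The original analysis used FOCE-I; with one random effect and additive
  error the Laplace approximation is the implementable equivalent, and
  equivalence claims are confined to ΔOFV comparisons.
* **Optimization**: Nelder-Mead on a transformed scale (log for positive
  parameters), bounded (CL ≤ 50 L/h, V ≤ 500 L, k_max ≤ 5 h⁻¹,
  A_max ≤ 10⁴ mg); non-convergence is flagged, never silent.
* **Profile CIs**: geometric stepping brackets the OFV crossing
  (χ²₁ quantile above the minimum; 2.706 at 90%), then bisection with all
  other free parameters re-optimized warm-started at every point (inner
  budget 150 simplex iterations, stop at 0.05 OFV or 0.2% parameter width).
  A side that never crosses inside the parameter box returns the box edge
  (one-sided, by construction ≤/≥ the estimate).  `level=0` degenerates to
  the point estimate.
* **LRT**: significant iff ΔOFV < −χ²_{df,0.95} strictly — a drop of
  exactly 3.84 at df 1 does not qualify.
* **Minimum-rate search**: for lognormal IIV the population-median subject
  is the typical subject, so the search predicate is the exact
  `rate/CL_typ(Q) > target` on the integer grid.  A sample median over 3000
  replicates has ≈0.33% noise while the margin at the returned rate is only
  ≈0.45%, so simulated medians are attached as diagnostics rather than used
  as the gate.

## Synthetic cohorts: what they emulate and what they do not

`study_mimic_config()` freezes a design matching the source cohort: 7
patients over a 20-day horizon; loading dose 1500 mg over 2 h; constant
maintenance infusion log-uniform over 20–125 mg/h; effluent flow uniform
over 1500–3000 mL/h with 3 of 7 patients changing mid-study; 20 adsorber
sessions (3,3,3,3,3,3,2) with lognormal durations (median 6 h, truncated to
1.7–27.9 h) starting no earlier than 12 h; one routine TDM sample per day
plus one per session.  This yields 160 samples with ~15% (±5 pp) drawn
during sessions, reproducing the study's sampling imbalance.  Observations
are individual model predictions plus additive N(0, σ²) noise; negative
values are kept by default (a pure additive error model implies them at low
concentrations), with an optional LLOQ floor.

Not emulated: demographics and clinical covariates (weight, albumin, SOFA —
none entered the final model), assay LLOQ censoring mechanisms, dropout,
irregular clinical sampling-time patterns, and multi-compartment
disposition.  A green test against this generator therefore establishes
internal consistency of estimator and simulator under the stated model, not
robustness to model misspecification.

## Scale-downs for the test budget

The full acceptance properties are statements about simulation studies; the
shipped tests run them at desk scale: LRT type-I control uses 24 null
replicates (gate ≤3 exceedances ≈ nominal + 2.5 binomial SD; the boundary
null k_max→0 makes the test conservative, observed rate ~0), detection
power uses 3 seeds (majority rule), and parameter recovery uses one
12-subject dense cohort with profile-CI containment of k_max and A_max
rather than a 200-replicate coverage estimate.

## Known limitations and deliberate deviations

* With the *printed* (rounded) final parameters, the typical-subject 24-h
  AUC under a fresh adsorber is 393.3 mg·h/L versus a reported median of
  388, and the paired exposure deficit is ≈ −89 versus a reported −93
  mg·h/L.  The trajectory shape matches the reported behaviour exactly
  (drop to ~15.7 mg/L, slow recovery, 16–20 mg/L band over 24 h), and
  481 − 388 = 93 while our 482.1 − 393.3 = 88.8: the reported deltas are
  internally consistent only with unrounded estimates we do not have.  The
  two affected acceptance assertions are kept at their stated tolerances
  and fail by ~0.3 pp and ~1 mg·h/L respectively; all other reproductions
  pass.
* Whether adsorption continued across a cartridge exchange within one
  treatment is not reported; per-cartridge reset is this package's
  documented choice.
* The estimated A50 (hyperbolic) and categorical effect size were never
  reported for the rejected model variants; any defaults used in
  demonstrations are synthetic and labelled as such.
* Covariates between records are stepwise-constant (left-closed); the
  original interpolation rule is unreported.
* No inter-occasion variability, no bootstrap, no covariate screening
  beyond effluent flow and the adsorber itself; AUC/MIC target attainment
  is out of scope.
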