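# Methods

## The estimation problem

The package estimates feasible parameter sets for compartmental
pharmacokinetic models from sparse aggregate observations. The shipped
application: an irinotecan disposition model with 55 (other-cancer, OC) or
56 (bile-duct-cancer, BDC) unknown parameters, constrained only by 9 or 14
cumulative accumulation values (urinary, fecal and — for BDC — biliary
amounts of the parent drug and four metabolites). The problem is severely
underdetermined; the object of interest is the *set* of parameter vectors
compatible with the data, approximated by the final ensemble ("cluster") of
virtual samples.

## PBPK model structure

Five compounds are tracked: CPT-11 and the metabolites SN-38 (via CES2),
APC and NPC (via CYP3A4), SN-38G (from SN-38 via UGT1A); NPC is further
converted to SN-38 by CES2. Amounts are carried in **parent-mass
equivalents** (µg/kg), so metabolic conversion moves mass 1:1 between
compound pools and the sum over all compartments equals total
radioactivity — this matches how the accumulation data are reported and
makes the model exactly conservative.

Per compound, the compartments and first-order transfers are:

* **rapid equilibrium** (volume `V_rapid`, per-compound): receives the
  zero-order infusion (CPT-11 only; 1500 µg/kg over 90 min), exchanges with
  a **late equilibrium** compartment (`CL_12` out, `k_21` back), is cleared
  renally (`CL_r`) into cumulative urine, and exchanges with the liver via
  hepatic blood flow `Q_H = 20.7 ml/min/kg`;
* **liver** (well-stirred, volume `V_liver = 24.1 ml/kg`, partition
  coefficient `K_p,liver`): all hepatic elimination — biliary excretion
  `CL_bile`, T-tube drainage `r_T · CL_bile`, metabolic clearances — is
  driven by the blood-side (outflow) concentration
  `C_out = A_liver / (V_liver · K_p)`; metabolite formation enters the
  product's liver pool;
* **biliary transit** (chain of `n_bile_transit` compartments, default 1,
  emptied by `k_transit`) feeding the **small intestine**, from which drug
  is either reabsorbed into the liver (`k_a`, closing the enterohepatic
  loop) or passed on (`k_LI`) to the **large intestine** and excreted into
  cumulative feces (`k_feces`);
* for the BDC group, a **biliary T-tube** collects `r_T · CL_bile · C_out`;
  the drainage ratio `r_T` is shared across compounds (it represents the
  bile-flow split, not a compound property) and is fixed at 0 for OC.

Parameter ranges (the sampling box) and the dosing constants ship in
`src/clusternewton/data/{oc,bdc}.yaml`; disposition parameters are
compound-specific (5 × 10 blocks), the five metabolic clearances are single
edges, plus `r_T` — 56 parameters in all.

The equations of the original study's model are not publicly available;
this system is a reconstruction from the published compartment diagram and
rate-constant list. Structural choices that could differ (absorption routed
small-intestine→liver rather than to the rapid compartment, the
well-stirred liver convention, a single bile-transit compartment) are each
isolated in `pbpk.build_rate_matrix` / `DosingConfig` so they can be
amended; their measured impact on the headline estimate is below.

### Integration

All transfers are first order and the infusion is piecewise constant, so
the system is linear time-invariant within each phase. The default
integrator propagates the exact solution with matrix exponentials on the
infusion-augmented system — exact for arbitrarily stiff rate constants and
fast enough for ~30 000 model evaluations per fit. A stiff BDF solver
(`scipy.integrate.solve_ivp`) is built in as an independent route; the test
suite cross-checks the two to ~1e-5 relative. Mass balance holds to ~1e-13
of the dose; tiny negative amounts beyond 1e-6 × dose or non-finite states
flag the evaluation as failed.

Objectives are read at `t_end = 7200 min` (5 days), long enough for the
excreta to plateau under the sampled rate constants; the observed values
themselves sum to ≈ the dose, consistent with complete recovery. The fecal
SN-38 and SN-38G amounts are combined into one objective because intestinal
β-glucuronidase deconjugates SN-38G in feces; no deconjugation reaction is
modelled.

## The ensemble solver

Work is done in `z = ln x` throughout (positivity for free; the box becomes
a log-box; the observed values enter as `w = ln y`, with a configurable
linear-objective variant). Per iteration, with the cluster `{z_j}` and its
evaluations `{w_j}`:

1. **Surrogate**: ordinary least squares with intercept over all
   successfully evaluated samples, `w ≈ A z + b`; rank-deficient designs
   fall back to the minimum-norm solution with a warning. The Moore–Penrose
   pseudoinverse `A⁺` (relative cutoff 1e-10) is computed once per
   iteration and reused by both update steps.
2. **Targets**: each sample steers toward the observed vector perturbed by
   a per-sample multiplicative log-normal factor (default scale 0.1, drawn
   once at initialisation), so the ensemble tracks a cloud of nearby
   targets. Setting the scale to 0 disables this.
3. **Update**: `z_a,j = z̄ + A⁺ (w*_j − (A z̄ + b))` — the minimum-norm
   solution of the linearised system anchored at the cluster centroid `z̄`,
   where the linearisation is most trustworthy. On a consistent affine
   model this reproduces every target exactly in one iteration. Because the
   anchor is shared, the unmodified update collapses the ensemble's spread
   along `null(A)`; that is precisely the failure mode the next step
   repairs.
4. **dS replication**: `z_i = z_a + dS (z_b − z_a)`, then
   `z_a' = z_i + A⁺ (w*_j − (A z_i + b))` with the same `A⁺`. The
   correction lies in `row(A)`, so `z_a'` satisfies the same target while
   inheriting `z_i`'s null-space component — a dS-fraction of the sample's
   own history. Each sample of the next cluster is `z_a` or `z_a'` with
   probability ½, independently. `dS = 0` makes `z_i = z_a` and the
   re-solve idempotent, so the step short-circuits to an exact no-op; the
   engine with replication disabled is bitwise identical. `dS ∈ [0, 1)` is
   enforced. The opposite interior-point orientation
   (`z_i = z_b + dS (z_a − z_b)`) is available via
   `ds_orientation="toward_after"`; the default orientation is the one
   under which dS = 0 reduces to the unmodified algorithm and larger dS
   preserves more diversity, matching the observed role of the parameter.

Design notes, in brief: failed evaluations are isolated per sample and
either replaced by a copy of a random successful member (`resample`,
default) or carried (`carry_over`); more than 50% failures in one iteration
aborts with a diagnostic. Iterates may leave the initial box — clipping
would destroy exactly the diversity the method maintains — and are counted
instead. A run is flagged diverged when >10% of samples fail or the median
|ln(sim/obs)| exceeds twice its initial value, and converged when the final
median is ≤ 0.25 (~28% typical mismatch); both thresholds are configurable
diagnostics, never hard stops. A single master seed spawns independent
streams for initialisation, target perturbation and each iteration's
selection/resampling, so extending `n_iterations` never perturbs earlier
iterations.

## Post-fit statistics

* `SS_log = Σ [ln(A_sim / A_obs)]²` over matched cumulative time points,
  summed over routes (urine, feces, T-tube totals by default; per-compound
  scoring optional). Simulated amounts are floored at 1e-12 µg/kg so a
  vanishing prediction gets a large finite penalty. Ranking ties break by
  sample id. Only terminal accumulation values are published; intermediate
  "observed" points used in examples/tests are generated by
  `synthetic_observed_profile` (a saturating first-order rise to the
  published terminal totals) and are labelled synthetic.
* Geometric summaries report `exp(mean(ln p))` with both the multiplicative
  SD `exp(sd(ln p))` and the plain ln-scale SD, since "geometric mean ± SD"
  is ambiguous between the two conventions.
* Correlation screening: pairwise Pearson r on ln-parameters (invariant
  under unit rescaling), screened at `r² > 0.64`, sign retained so inverse
  relationships are visible; zero-variance parameters are reported as
  undefined rather than imputed. An optional scatter-matrix plot mirrors
  the screened subset.
* `ds_sweep` re-runs the fit across dS values with a shared seed and
  reports per-dS convergence, divergence iteration, residual quantiles and
  ensemble diversity (median per-parameter log-range).

## Synthetic problems and what the tests show

`make_affine_problem` builds log-log-affine maps of prescribed rank with
closed-form solution manifolds and null-space bases; `make_pbpk_problem`
draws a ground truth from the central half of the parameter box (keeping
the truth away from the bound effects), simulates it, and perturbs the
objectives with multiplicative log-normal noise (default σ = 0.1, matching
the log-residual metric). These generators emulate the *structure* of the
estimation task — underdetermination, positivity, log-scale noise — but not
inter-patient variability or model misspecification, so passing recovery
tests demonstrate algorithmic correctness, not clinical validity.

"Identifiable parameters" in the recovery test means the two quantities the
accumulation data pin down individually — the parent drug's renal clearance
and the biliary drainage split `r_T`. Local Jacobian rank is deliberately
not used as the criterion: the hepatic clearances lie on curved trade-off
ridges (the same renal/CES2/CYP3A4 proportionality the correlation screen
reveals), so parameters that look locally identifiable can drift many-fold
along a ridge while every objective stays within 10%. Measured recovery for
the two named parameters is within ×1.25 of truth at σ = 0.1.

## Problem sizes used

Default study conditions are 3000 samples × 9 iterations (≈ 30 000 forward
evaluations, ~15 s for a full OC fit with the exponential propagator).
Property tests use smaller ensembles (25–500 samples) on affine or
scaled-down PBPK problems; the full-scale OC fit runs in the acceptance
test and in `scripts/acceptance.py`.

## Known limitations

* The ODE system is a reconstruction; the original equations are not
  available for verification. The headline estimate — the OC-group renal
  clearance of irinotecan, published as 5.7 ± 1.2 ml/min/kg — comes out at
  ≈ 7.2 ml/min/kg here (3000 samples, dS = 0.5), with all nine objectives
  reproduced to within ~7%. The dominant sensitivity is not the ODE
  structure (bile-transit chain length and horizon move it < 2%) but the
  update anchoring convention: anchoring each sample's Newton step at its
  own position instead of the centroid yields ≈ 4.7 ml/min/kg, bracketing
  the published value. In an underdetermined problem this statistic is a
  feature of the algorithm's sampling of the feasible set as much as of the
  data.
* `k`-parameters whose catalogued unit reads "/min/kg" are treated as plain
  first-order constants (/min); a per-kg first-order constant is not
  dimensionally meaningful.
* The collection horizon of the source study is not published; 7200 min is
  the package's plateau-checked default.
* No M4 metabolite, no plasma-concentration objectives, no inter-individual
  variability; OC is one aggregate profile.
* The low-dS regime of this implementation stalls into a degenerate
  (collapsed) ensemble rather than blowing up; divergence detection covers
  both, but exact low-dS failure iterations of the original implementation
  are not reproducible.
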