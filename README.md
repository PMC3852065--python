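# clusternewton

Ensemble estimation of the **feasible parameter space** of underdetermined
inverse problems with the Cluster Newton method, plus a whole-body
physiologically-based pharmacokinetic (PBPK) model of the anticancer drug
**irinotecan (CPT-11)** and its metabolites (SN-38, SN-38G, NPC, APC) with
enterohepatic circulation and biliary T-tube drainage.

## Who this is for

PBPK and systems-pharmacology modellers who need to estimate many more
parameters than they have observations — e.g. 55–56 kinetic parameters from
9–14 cumulative urinary/fecal/biliary accumulation values — and who want the
*set* of parameter vectors consistent with the data rather than a single,
initial-guess-dependent optimum.

## The method

A cluster of `N` virtual samples `x_j` is drawn log-uniformly from broad
parameter ranges. Each iteration:

1. the forward model maps every sample to its objective vector
   `y_j = f(x_j)`;
2. an affine surrogate `ln y ≈ A ln x + b` is fitted to the whole cloud by
   least squares;
3. every sample is sent to the minimum-norm solution of the linearised
   system for its (individually perturbed) target `y*_j`, anchored at the
   cluster centroid `x̄`:
   `ln x_a,j = ln x̄ + A⁺ (ln y*_j − (A ln x̄ + b))`;
4. **diversity maintenance (dS):** the interior point
   `x_i = x_a + dS (x_b − x_a)` between each sample's pre-update position
   `x_b` and its update `x_a` is re-solved with the same pseudoinverse,
   giving an alternative solution `x_a'` that retains a dS-fraction of the
   sample's own spread along the surrogate's null space; the next cluster
   picks `x_a` or `x_a'` per sample with probability ½.

With `dS = 0` step 4 is an exact no-op and the plain algorithm — which
collapses the ensemble along the non-identifiable directions — is recovered
bit-for-bit. With `dS ≥ 0.5` the ensemble keeps populating the null space
while the residuals `|ln(y_sim / y_obs)|` contract, which is what makes the
final cluster an estimate of the feasible solution space. Sample quality is
ranked afterwards by the sum of squared log residuals over accumulation
time-profiles, `SS_log = Σ [ln(A_sim / A_obs)]²`, and parameter
interdependencies are screened by pairwise Pearson `r² > 0.64` on the
ln-parameters.

The PBPK forward model tracks five compounds through rapid/late equilibrium
compartments, a well-stirred liver, a biliary transit chain, small and large
intestine, and cumulative urine/feces/T-tube, with first-order transfer
throughout; the system is linear, so the default integrator is an exact
matrix-exponential propagator (a stiff BDF solver is built in as an
independent cross-check). See `docs/methods.md` for the equations,
conventions and limitations.

## Worked example

```bash
cnm run -c oc --samples 1000 --iterations 9 --ds 0.5 --seed 1 --out ocfit
```

```
iter  0  median|ln r|=1.2964  q95=4.3245  failed=0  out_of_box=0
iter  1  median|ln r|=0.1973  q95=0.5989  failed=0  out_of_box=252
...
iter  9  median|ln r|=0.0549  q95=0.1721  failed=0  out_of_box=0
Cluster Newton fit
==================================================================
samples: 1000    iterations: 9    dS: 0.5    seed: 1
objectives: 9    free parameters: 55
converged: True    diverged_at: None    failed evaluations: 0
final median |ln(sim/obs)|: 0.0549 (x/ 1.056 fold)
------------------------------------------------------------------
parameter             unit        geo mean  geo SD   ln-SD
Kp_liver_CPT11        -              1.061   1.012   0.012
...
CLr_CPT11             ml/min/kg      6.814   1.102   0.097
```

Reading: starting from samples whose simulated accumulations are typically
3.7-fold off the observations (median `|ln r| = 1.30`), nine iterations
bring the typical mismatch to 5.6%. `out_of_box` counts samples that left
the initial ranges (they are tracked, never clipped). The per-parameter
table gives the ensemble geometric mean and multiplicative spread — here
the renal clearance of the parent drug converges to ≈ 6.8 ml/min/kg
(×/÷ 1.10) although only cumulative accumulations were fitted.

The same objects are available programmatically:

```python
from clusternewton import ClusterNewton

res = ClusterNewton.from_scenario("oc").fit(n_samples=1000, n_iterations=9,
                                            ds=0.5, seed=1)
print(res.summary())
res.correlations(threshold=0.64).screened_parameters  # r^2-screened subset
```

Other entry points: `cnm sweep` (convergence/diversity diagnostics across a
range of dS values), `cnm simulate` (accumulation time-profiles for one
parameter vector), `cnm analyze` (summaries + correlation screen of a saved
run), `cnm synth` (self-contained synthetic problems with known ground
truth).

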