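"""Cluster Newton Method engine with dS diversity maintenance.

The Cluster Newton Method (CNM) estimates the *feasible solution space* of an
underdetermined inverse problem: instead of one optimum it co-evolves an
ensemble ("cluster") of parameter vectors.  Each iteration

1. evaluates the forward model on every cluster member,
2. fits a single affine surrogate ``w ~ A z + b`` to the cloud of
   (ln parameter, ln objective) pairs by least squares,
3. sends every member to the minimum-norm solution of the linearised system
   for its (individually perturbed) target, anchored at the cluster centroid,
4. optionally *replicates*: an interior point ``X_i`` between each member's
   pre-update position ``X_b`` and its updated position ``X_a`` is re-solved
   with the same pseudoinverse, giving an alternative point ``X_a'`` that
   retains a dS-fraction of the member's previous spread; the next cluster
   picks ``X_a`` or ``X_a'`` per member with probability one half.

Step 4 is the diversity-maintenance modification.  With ``ds = 0`` the
interior point coincides with ``X_a``, the re-solve is idempotent, and the
algorithm reduces exactly to the unmodified method; larger ``ds`` preserves
more ensemble spread along the null space of the surrogate, which is what
keeps the inverse problem's non-identifiable directions populated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .space import ConfigurationError, ObjectiveSpec, ParameterSpace

__all__ = [
    "CNMConfig", "Cluster", "Surrogate", "IterationRecord", "EvaluationError",
    "sample_initial_cluster", "evaluate_cluster", "fit_affine_surrogate",
    "newton_update", "ds_replicate", "run_cnm",
]


class EvaluationError(RuntimeError):
    """A forward-model evaluation failed irrecoverably."""


class CNMAbort(RuntimeError):
    """The solver aborted (e.g. too many failed evaluations)."""

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class CNMConfig:
    """Solver settings.

    Parameters
    ----------
    n_samples : int
        Ensemble size (number of virtual samples).
    n_iterations : int
        Number of update iterations.
    ds : float in [0, 1)
        Diversity-maintenance fraction.  0 disables replication and
        reproduces the unmodified algorithm exactly.
    target_perturbation : float
        Log-scale s.d. of the per-sample multiplicative perturbation of the
        target objectives (~relative scale; 0.1 = about 10%).  Drawn once at
        initialisation and reused every iteration; 0 disables it.
    seed : int or None
        Master seed; per-stage streams are spawned from it so changing
        ``n_iterations`` never perturbs earlier iterations.
    failure_policy : {"resample", "carry_over"}
        What to do with samples whose evaluation failed: replace them by a
        copy of a randomly chosen successful member (default), or keep them
        and exclude them from the surrogate fit.
    surrogate_coords : {"log", "linear"}
        Objective-side coordinates of the affine surrogate.  Parameters are
        always handled in ln-space; objectives are ln-transformed by default.
    ds_orientation : {"toward_before", "toward_after"}
        Placement of the interior point.  Default ``"toward_before"``:
        ``X_i = X_a + ds (X_b - X_a)`` so ds is the fraction of the
        pre-update position retained.  ``"toward_after"`` flips the roles.
    """

    n_samples: int = 3000
    n_iterations: int = 9
    ds: float = 0.5
    target_perturbation: float = 0.1
    seed: int | None = None
    failure_policy: str = "resample"
    surrogate_coords: str = "log"
    ds_orientation: str = "toward_before"
    replication: bool = True
    rcond: float = 1e-10
    objective_floor: float = 1e-12
    max_failure_fraction: float = 0.5
    divergence_failure_fraction: float = 0.1
    divergence_residual_factor: float = 2.0
    convergence_tol: float = 0.25
    store_history: bool = True

    def __post_init__(self):
        if not (0.0 <= self.ds < 1.0):
            raise ConfigurationError(f"ds must lie in [0, 1), got {self.ds}")
        if self.n_samples < 1 or self.n_iterations < 0:
            raise ConfigurationError("n_samples >= 1 and n_iterations >= 0 required")
        if self.failure_policy not in ("resample", "carry_over"):
            raise ConfigurationError(f"unknown failure_policy {self.failure_policy!r}")
        if self.surrogate_coords not in ("log", "linear"):
            raise ConfigurationError(f"unknown surrogate_coords {self.surrogate_coords!r}")
        if self.ds_orientation not in ("toward_before", "toward_after"):
            raise ConfigurationError(f"unknown ds_orientation {self.ds_orientation!r}")


@dataclass
class Cluster:
    """An ensemble of parameter vectors in free-parameter ln-space."""

    Z: np.ndarray                      # (n_samples, n_free)
    iteration: int = 0
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ConfigurationError("cluster matrix must be 2-D")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.Z.shape[0])
        self.sample_ids = np.asarray(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_free(self) -> int:
        return self.Z.shape[1]

    def copy(self) -> "Cluster":
        return Cluster(self.Z.copy(), self.iteration, self.sample_ids.copy())


@dataclass
class Surrogate:
    """Affine surrogate ``w = A z + b`` with its pseudoinverse.

    ``A`` has shape (n_objectives, n_free); the Moore-Penrose pseudoinverse
    is computed once per iteration and reused by the update and the
    replication step ("the same inverse matrix").
    """

    A: np.ndarray
    b: np.ndarray
    pinvA: np.ndarray
    rank: int
    fit_rms: float
    coords: str = "log"

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.A.T + self.b

    def solve_min_norm(self, anchor: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Minimum-norm solutions of ``A z + b = target`` anchored at *anchor*.

        Returns ``anchor + A^+ (target - (A anchor + b))`` row-wise; the
        correction lies in the row space of A, so the anchor's null-space
        component is inherited unchanged.
        """
        resid = targets - (anchor @ self.A.T + self.b)
        return anchor + resid @ self.pinvA.T


@dataclass
class IterationRecord:
    """Snapshot of one iteration: cluster, objectives and residual summary."""

    iteration: int
    cluster: Cluster
    objectives: np.ndarray          # (n_samples, n_objectives), NaN where failed
    ok: np.ndarray                  # (n_samples,) bool
    residual_median: float          # median over ok samples/objectives of |ln(sim/obs)|
    residual_q: tuple               # (q25, q50, q75, q95)
    n_failed: int
    n_out_of_box: int
    surrogate: Surrogate | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _spawn_streams(config: CNMConfig):
    """Master-seeded independent streams: init, perturbation, then
    (selection, failure) per iteration."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + 2 * config.n_iterations)
    init_rng = np.random.default_rng(children[0])
    perturb_rng = np.random.default_rng(children[1])
    iter_rngs = [
        (np.random.default_rng(children[2 + 2 * k]),
         np.random.default_rng(children[3 + 2 * k]))
        for k in range(config.n_iterations)
    ]
    return init_rng, perturb_rng, iter_rngs


def sample_initial_cluster(space: ParameterSpace, config: CNMConfig,
                           rng: np.random.Generator | None = None) -> Cluster:
    """Draw the initial ensemble uniformly in ln-space over the parameter box.

    Each free parameter is sampled independently and uniformly between
    ``ln lower`` and ``ln upper``; fixed parameters do not appear in the
    cluster (they are re-inserted at evaluation time).
    """
    if rng is None:
        rng, _, _ = _spawn_streams(config)
    if config.n_samples < space.n_free:
        warnings.warn(
            f"n_samples={config.n_samples} is smaller than the number of free "
            f"parameters ({space.n_free}); the surrogate fit will be rank-deficient",
            stacklevel=2)
    Z = rng.uniform(space.log_lower, space.log_upper,
                    size=(config.n_samples, space.n_free))
    return Cluster(Z, iteration=0)


def evaluate_cluster(model, cluster: Cluster, space: ParameterSpace,
                     config: CNMConfig | None = None):
    """Forward-sweep the model over the cluster.

    Returns ``(Y, ok)``: the (n_samples, n_objectives) objective matrix with
    NaN rows where the model failed, and a boolean success mask.  Evaluation
    is row-independent, so ordering cannot affect results.  More than
    ``max_failure_fraction`` failures aborts with a diagnostic.
    """
    config = config or CNMConfig()
    X = space.to_original(cluster.Z)
    n = cluster.n_samples
    Y = None
    ok = np.ones(n, dtype=bool)
    for j in range(n):
        try:
            y = np.asarray(model.evaluate(X[j]), dtype=float)
        except EvaluationError:
            y = None
        except (ValueError, FloatingPointError, ArithmeticError):
            y = None
        if Y is None:
            m = model.n_objectives if y is None else y.shape[0]
            Y = np.full((n, m), np.nan)
        if y is None or y.shape != (Y.shape[1],) or not np.all(np.isfinite(y)):
            ok[j] = False
        else:
            Y[j] = y
    if Y is None:
        Y = np.full((n, model.n_objectives), np.nan)
    if (~ok).sum() > config.max_failure_fraction * n:
        raise CNMAbort(
            f"{(~ok).sum()}/{n} forward evaluations failed "
            f"(> {config.max_failure_fraction:.0%}); check parameter ranges "
            f"and the model", iteration=cluster.iteration)
    return Y, ok


def _objective_transform(Y: np.ndarray, config: CNMConfig) -> np.ndarray:
    if config.surrogate_coords == "linear":
        return Y
    return np.log(np.maximum(Y, config.objective_floor))


def fit_affine_surrogate(cluster: Cluster, objectives: np.ndarray,
                         ok: np.ndarray | None = None,
                         config: CNMConfig | None = None) -> Surrogate:
    """Least-squares affine fit of transformed objectives on ln-parameters.

    Ordinary least squares with intercept over all successfully evaluated
    samples; rank-deficient designs fall back to the minimum-norm solution
    with a warning.  The Moore-Penrose pseudoinverse of the slope matrix is
    computed here, once, for reuse by both the update and replication steps.
    """
    config = config or CNMConfig()
    Z = cluster.Z
    if ok is None:
        ok = np.all(np.isfinite(objectives), axis=1)
    Zok = Z[ok]
    W = _objective_transform(objectives[ok], config)
    n, p = Zok.shape
    if n < p + 1:
        warnings.warn(
            f"only {n} successful samples for {p} free parameters; surrogate "
            "fit is underdetermined (minimum-norm solution used)", stacklevel=2)
    D = np.column_stack([np.ones(n), Zok])
    coef, _, rank, _ = np.linalg.lstsq(D, W, rcond=None)
    if rank < p + 1:
        warnings.warn(
            f"rank-deficient surrogate design (rank {rank} < {p + 1}); "
            "proceeding with minimum-norm least squares", stacklevel=2)
    b = coef[0]
    A = coef[1:].T                       # (m, p)
    fit_rms = float(np.sqrt(np.mean((D @ coef - W) ** 2))) if n else np.nan
    pinvA = np.linalg.pinv(A, rcond=config.rcond)
    return Surrogate(A=A, b=b, pinvA=pinvA, rank=int(rank), fit_rms=fit_rms,
                     coords=config.surrogate_coords)


def perturbed_targets(spec: ObjectiveSpec, config: CNMConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-sample targets in surrogate coordinates.

    Each virtual sample is steered toward the observed values perturbed by a
    multiplicative log-normal factor of scale ``target_perturbation``
    (inherited from the original ensemble method; 0 disables it), so the
    ensemble tracks a cloud of nearby targets rather than a single point.
    """
    w0 = spec.log_observed if config.surrogate_coords == "log" else spec.observed
    n, m = config.n_samples, spec.n_objectives
    if config.target_perturbation > 0:
        eta = rng.normal(0.0, config.target_perturbation, size=(n, m))
    else:
        eta = np.zeros((n, m))
    if config.surrogate_coords == "log":
        return w0 + eta
    return w0 * np.exp(eta)


def newton_update(cluster: Cluster, surrogate: Surrogate,
                  targets: np.ndarray) -> Cluster:
    """One Newton step of the whole ensemble against the affine surrogate.

    Every sample is sent to the minimum-norm solution of the linearised
    system for its own target, anchored at the current cluster centroid
    (the point where the surrogate is most trustworthy):

        z_a,j = z̄ + A⁺ (w*_j − (A z̄ + b))

    On a consistent affine model this reproduces each target exactly.  Note
    the anchor is shared: the unmodified method therefore collapses the
    ensemble's spread along the surrogate's null space — the behaviour the
    dS replication step exists to counteract.
    """
    anchor = cluster.Z.mean(axis=0)
    Za = surrogate.solve_min_norm(anchor, targets)
    if not np.all(np.isfinite(Za)):
        raise CNMAbort("non-finite Newton update", iteration=cluster.iteration)
    return Cluster(Za, iteration=cluster.iteration + 1,
                   sample_ids=cluster.sample_ids.copy())


def ds_replicate(before: Cluster, after: Cluster, surrogate: Surrogate,
                 targets: np.ndarray, config: CNMConfig,
                 rng: np.random.Generator) -> Cluster:
    """Diversity-maintaining replication step.

    For each sample the interior point ``X_i`` divides the segment between
    the pre-update position ``X_b`` and the updated position ``X_a`` with
    ratio ``ds : (1 - ds)``; the same pseudoinverse used for the update is
    then applied to re-solve from ``X_i``, giving ``X_a'`` which satisfies
    the same target but retains a ds-fraction of the sample's previous
    null-space component.  The next cluster takes ``X_a`` or ``X_a'`` for
    each sample independently with probability one half.

    ``ds = 0`` is an exact no-op (returns ``X_a``): the interior point then
    coincides with ``X_a`` and the re-solve is idempotent.
    """
    if not (0.0 <= config.ds < 1.0):
        raise ConfigurationError(f"ds must lie in [0, 1), got {config.ds}")
    if before.n_samples != after.n_samples or \
            not np.array_equal(before.sample_ids, after.sample_ids):
        raise ConfigurationError("before/after clusters are not row-aligned")
    if config.ds == 0.0 or not config.replication:
        return after.copy()
    if config.ds_orientation == "toward_before":
        Xi = after.Z + config.ds * (before.Z - after.Z)
    else:                                # the flipped convention
        Xi = before.Z + config.ds * (after.Z - before.Z)
    Zap = surrogate.solve_min_norm(Xi, targets)
    take_after = rng.random(after.n_samples) < 0.5
    Z = np.where(take_after[:, None], after.Z, Zap)
    return Cluster(Z, iteration=after.iteration,
                   sample_ids=after.sample_ids.copy())


def _residual_summary(Y, ok, spec, config):
    """Quantiles of |ln(sim/obs)| over successful samples and objectives."""
    if ok.sum() == 0:
        return np.nan, (np.nan,) * 4
    R = np.abs(np.log(np.maximum(Y[ok], config.objective_floor)) -
               spec.log_observed)
    q = np.quantile(R, [0.25, 0.5, 0.75, 0.95])
    return float(q[1]), tuple(float(v) for v in q)


def run_cnm(model, space: ParameterSpace, spec: ObjectiveSpec,
            config: CNMConfig, callback=None) -> "FitResult":
    """Run the full ensemble fit; returns a :class:`FitResult`.

    Orchestrates initial sampling, then ``n_iterations`` rounds of
    evaluate → surrogate fit → Newton update → dS replication, recording a
    per-iteration residual summary.  Deterministic under a fixed seed.
    """
    from .results import FitResult   # local import to avoid a cycle

    init_rng, perturb_rng, iter_rngs = _spawn_streams(config)
    cluster = sample_initial_cluster(space, config, init_rng)
    targets = perturbed_targets(spec, config, perturb_rng)

    history: list[IterationRecord] = []
    failed_evals = 0
    diverged_at = None

    def record(cluster, Y, ok, surrogate=None):
        med, q = _residual_summary(Y, ok, spec, config)
        rec = IterationRecord(
            iteration=cluster.iteration,
            cluster=cluster.copy() if config.store_history else None,
            objectives=Y if config.store_history else None,
            ok=ok, residual_median=med, residual_q=q,
            n_failed=int((~ok).sum()),
            n_out_of_box=int(space.out_of_box(cluster.Z).any(axis=1).sum()),
            surrogate=surrogate)
        history.append(rec)
        if callback is not None:
            callback(rec)
        return rec

    try:
        Y, ok = evaluate_cluster(model, cluster, space, config)
    except CNMAbort as exc:
        raise CNMAbort(f"iteration 0: {exc}", iteration=0) from exc
    rec0 = record(cluster, Y, ok)
    base_median = rec0.residual_median

    for k in range(config.n_iterations):
        select_rng, fail_rng = iter_rngs[k]
        failed_evals += int((~ok).sum())
        if config.failure_policy == "resample" and (~ok).any() and ok.any():
            # redraw failed members from the cluster's empirical distribution
            donors = fail_rng.choice(np.flatnonzero(ok), size=int((~ok).sum()))
            cluster.Z[~ok] = cluster.Z[donors]
            Y[~ok] = Y[donors]
            ok = np.ones_like(ok)
        surrogate = fit_affine_surrogate(cluster, Y, ok, config)
        after = newton_update(cluster, surrogate, targets)
        cluster = ds_replicate(cluster, after, surrogate, targets, config,
                               select_rng)
        try:
            Y, ok = evaluate_cluster(model, cluster, space, config)
        except CNMAbort as exc:
            raise CNMAbort(f"iteration {k + 1}: {exc}",
                           iteration=k + 1) from exc
        rec = record(cluster, Y, ok, surrogate)
        if diverged_at is None:
            fail_frac = rec.n_failed / config.n_samples
            blown = (np.isfinite(base_median) and np.isfinite(rec.residual_median)
                     and rec.residual_median >
                     config.divergence_residual_factor * max(base_median, 1e-12))
            if fail_frac > config.divergence_failure_fraction or blown:
                diverged_at = k + 1

    final_median = history[-1].residual_median
    diagnostics = {
        "diverged_at": diverged_at,
        "converged": bool(np.isfinite(final_median)
                          and final_median <= config.convergence_tol),
        "failed_evaluations": failed_evals,
        "final_residual_median": final_median,
        "final_residual_quantiles": history[-1].residual_q,
        "out_of_box_final": history[-1].n_out_of_box,
    }
    R = (np.log(np.maximum(history[-1].objectives, config.objective_floor))
         - spec.log_observed) if config.store_history else None
    return FitResult(model=model, space=space, objectives=spec, config=config,
                     final_cluster=cluster, history=history, residuals=R,
                     diagnostics=diagnostics)
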