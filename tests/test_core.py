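import warnings

import numpy as np
import pytest

from clusternewton import (CallableModel, Cluster, CNMConfig,
                           ConfigurationError, LogAffineModel, ObjectiveSpec,
                           ParameterSpace, ds_replicate, evaluate_cluster,
                           fit_affine_surrogate, make_affine_problem,
                           newton_update, run_cnm, sample_initial_cluster)
from clusternewton.core import CNMAbort, EvaluationError, Surrogate


def _surrogate(A, b, rcond=1e-10, coords="log"):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    return Surrogate(A=A, b=b, pinvA=np.linalg.pinv(A, rcond=rcond),
                     rank=np.linalg.matrix_rank(A), fit_rms=0.0, coords=coords)


class TestSurrogateFit:
    def test_exact_recovery_on_affine_data(self, rng):
        A = rng.standard_normal((3, 4))
        b = rng.standard_normal(3)
        Z = rng.standard_normal((60, 4))
        Y = np.exp(Z @ A.T + b)           # ln y = A z + b exactly
        sur = fit_affine_surrogate(Cluster(Z), Y)
        np.testing.assert_allclose(sur.A, A, atol=1e-9)
        np.testing.assert_allclose(sur.b, b, atol=1e-9)
        assert sur.fit_rms < 1e-9

    def test_collinear_columns_warn_but_solve(self, rng):
        Z = rng.standard_normal((30, 3))
        Z = np.column_stack([Z, Z[:, 0]])          # duplicated parameter
        Y = np.exp(Z[:, :1] + 0.5)
        with pytest.warns(UserWarning, match="rank-deficient"):
            sur = fit_affine_surrogate(Cluster(Z), Y)
        assert np.all(np.isfinite(sur.A))

    def test_slope_converges_to_jacobian_at_centroid(self, rng):
        # smooth nonlinear map; finite-difference Jacobian is the oracle
        def f(z):
            return np.array([np.sin(z[0]) + z[1] ** 2, z[0] * z[1]])

        z0 = np.array([0.4, 0.8])
        h = 1e-6
        J = np.column_stack([(f(z0 + h * e) - f(z0 - h * e)) / (2 * h)
                             for e in np.eye(2)])
        errs = []
        for radius in (0.3, 0.03, 0.003):
            Z = z0 + radius * rng.standard_normal((120, 2))
            Y = np.exp(np.array([f(z) for z in Z]))
            sur = fit_affine_surrogate(Cluster(Z), Y)
            errs.append(np.abs(sur.A - J).max())
        # OLS slope bias is O(radius) from curvature; it must shrink with it
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 5e-3


class TestNewtonUpdate:
    def test_minimum_norm_split_two_params_one_objective(self):
        # y = x1 + x2 (in fitted coords), target 2, cluster at (3,3):
        # pseudoinverse of [1 1] splits the correction equally -> (1,1)
        sur = _surrogate([[1.0, 1.0]], [0.0])
        cl = Cluster(np.array([[3.0, 3.0]]))
        upd = newton_update(cl, sur, np.array([[2.0]]))
        np.testing.assert_allclose(upd.Z, [[1.0, 1.0]], atol=1e-12)
        # independent oracle: explicit least-norm solve
        dz = np.linalg.lstsq(np.array([[1.0, 1.0]]), np.array([-4.0]),
                             rcond=None)[0]
        np.testing.assert_allclose(upd.Z, cl.Z + dz, atol=1e-12)

    def test_identity_surrogate_with_current_targets_is_fixed_point(self, rng):
        Z = rng.standard_normal((10, 3))
        sur = _surrogate(np.eye(3), np.zeros(3))
        upd = newton_update(Cluster(Z), sur, Z.copy())
        np.testing.assert_allclose(upd.Z, Z, atol=1e-12)

    def test_consistent_affine_targets_hit_exactly(self, rng):
        A = rng.standard_normal((2, 5))
        b = rng.standard_normal(2)
        sur = _surrogate(A, b)
        Z = rng.standard_normal((40, 5))
        targets = np.tile(A @ rng.standard_normal(5) + b, (40, 1))
        upd = newton_update(Cluster(Z), sur, targets)
        np.testing.assert_allclose(upd.Z @ A.T + b, targets, atol=1e-9)


class TestDsReplicate:
    def _setup(self, ds, rng, n=80):
        prob = make_affine_problem(6, 2, rank=2, seed=3)
        A, b = prob.extras["A"], prob.extras["b"]
        sur = _surrogate(A, b)
        Z = rng.uniform(prob.space.log_lower, prob.space.log_upper, (n, 6))
        before = Cluster(Z)
        targets = np.tile(prob.objectives.log_observed, (n, 1))
        after = newton_update(before, sur, targets)
        cfg = CNMConfig(n_samples=n, ds=ds, seed=0)
        mixed = ds_replicate(before, after, sur, targets, cfg,
                             np.random.default_rng(5))
        return prob, sur, before, after, mixed, targets

    def test_ds_zero_is_an_exact_noop(self, rng):
        _, _, _, after, mixed, _ = self._setup(0.0, rng)
        assert np.array_equal(mixed.Z, after.Z)

    def test_replicated_points_also_satisfy_targets(self, rng):
        prob, sur, _, _, mixed, targets = self._setup(0.5, rng)
        A, b = prob.extras["A"], prob.extras["b"]
        np.testing.assert_allclose(mixed.Z @ A.T + b, targets, atol=1e-8)

    def test_mixed_cluster_retains_null_space_spread(self, rng):
        # after the update all samples share the anchor's null-space
        # component; the dS=0.5 replicate keeps half of each sample's own
        prob, _, before, after, mixed, _ = self._setup(0.5, rng)
        N = prob.extras["null_basis"]
        var_after = (after.Z @ N).var(axis=0).sum()
        var_mixed = (mixed.Z @ N).var(axis=0).sum()
        var_before = (before.Z @ N).var(axis=0).sum()
        assert var_after < 1e-20
        assert var_mixed > 1e-4 * var_before

    def test_row_misalignment_rejected(self, rng):
        a = Cluster(rng.standard_normal((4, 2)))
        b = Cluster(rng.standard_normal((4, 2)), sample_ids=[9, 8, 7, 6])
        sur = _surrogate(np.eye(2), np.zeros(2))
        with pytest.raises(ConfigurationError, match="row-aligned"):
            ds_replicate(a, b, sur, np.zeros((4, 2)),
                         CNMConfig(ds=0.5), np.random.default_rng(0))

    def test_invalid_ds_rejected(self):
        with pytest.raises(ConfigurationError, match="ds"):
            CNMConfig(ds=1.0)
        with pytest.raises(ConfigurationError, match="ds"):
            CNMConfig(ds=-0.1)


class TestEvaluateCluster:
    def _space(self, p=2):
        return ParameterSpace([f"p{i}" for i in range(p)],
                              lower=np.full(p, 0.1), upper=np.full(p, 10.0))

    def test_failing_rows_are_isolated(self):
        def f(x):
            if x[0] > 1.0:
                raise EvaluationError("boom")
            return np.array([x[0] + x[1]])

        model = CallableModel(f, ["p0", "p1"], ["y"])
        Z = np.log(np.array([[0.5, 0.5], [2.0, 0.5], [0.3, 0.2]]))
        Y, ok = evaluate_cluster(model, Cluster(Z), self._space())
        np.testing.assert_array_equal(ok, [True, False, True])
        assert np.isnan(Y[1]).all() and np.isfinite(Y[[0, 2]]).all()

    def test_too_many_failures_abort_with_diagnostic(self):
        model = CallableModel(lambda x: np.array([np.nan]), ["p0", "p1"], ["y"])
        Z = np.zeros((10, 2))
        with pytest.raises(CNMAbort, match="failed"):
            evaluate_cluster(model, Cluster(Z), self._space())


class TestRunCnm:
    def test_one_iteration_exact_on_affine(self):
        prob = make_affine_problem(5, 3, rank=3, seed=11)
        cfg = CNMConfig(n_samples=30, n_iterations=1, ds=0.5, seed=2,
                        target_perturbation=0.0)
        res = run_cnm(prob.model, prob.space, prob.objectives, cfg)
        assert np.abs(res.residuals).max() < 1e-8

    def test_same_seed_reproduces_fit_bitwise(self):
        prob = make_affine_problem(4, 2, rank=2, seed=11)
        cfg = CNMConfig(n_samples=25, n_iterations=3, ds=0.5, seed=9)
        r1 = run_cnm(prob.model, prob.space, prob.objectives, cfg)
        r2 = run_cnm(prob.model, prob.space, prob.objectives, cfg)
        assert np.array_equal(r1.final_cluster.Z, r2.final_cluster.Z)
        for a, b in zip(r1.history, r2.history):
            assert np.array_equal(a.cluster.Z, b.cluster.Z)

    def test_more_iterations_extend_not_perturb_earlier_ones(self):
        # per-iteration RNG streams: iterations 0..3 identical in both runs
        prob = make_affine_problem(4, 2, rank=2, seed=11)
        short = run_cnm(prob.model, prob.space, prob.objectives,
                        CNMConfig(n_samples=25, n_iterations=3, ds=0.5, seed=9))
        long = run_cnm(prob.model, prob.space, prob.objectives,
                       CNMConfig(n_samples=25, n_iterations=6, ds=0.5, seed=9))
        for a, b in zip(short.history, long.history[:4]):
            assert np.array_equal(a.cluster.Z, b.cluster.Z)

    def test_history_length_and_fixed_parameter_immutability(self):
        prob = make_affine_problem(4, 2, rank=2, seed=1)
        space = prob.space.fix("p4", 2.5)
        model = LogAffineModel(prob.extras["A"], prob.extras["b"])
        # re-derive consistent observations with p3 fixed at 2.5
        z = np.log(np.array([1.0, 1.0, 1.0, 2.5]))
        obs = model.evaluate(np.exp(z))
        spec = ObjectiveSpec(model.objective_names, obs)
        cfg = CNMConfig(n_samples=20, n_iterations=4, ds=0.5, seed=3)
        res = run_cnm(model, space, spec, cfg)
        assert len(res.history) == cfg.n_iterations + 1
        for rec in res.history:
            X = space.to_original(rec.cluster.Z)
            assert np.all(X[:, 3] == 2.5)

    def test_resample_policy_recovers_failed_samples(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if x[0] > 5.0:                 # fails on part of the box
                raise EvaluationError("region failure")
            return np.array([x[0] * x[1]])

        model = CallableModel(flaky, ["p0", "p1"], ["y"])
        space = ParameterSpace(["p0", "p1"], lower=[0.1, 0.1],
                               upper=[10.0, 10.0])
        spec = ObjectiveSpec(["y"], [2.0])
        cfg = CNMConfig(n_samples=40, n_iterations=3, ds=0.5, seed=5,
                        failure_policy="resample")
        res = run_cnm(model, space, spec, cfg)
        assert res.diagnostics["failed_evaluations"] > 0
        assert res.diagnostics["final_residual_median"] < 0.5

    def test_out_of_box_iterates_are_tracked_not_clipped(self):
        # a target far outside what the box can produce forces exits
        prob = make_affine_problem(3, 3, rank=3, seed=21)
        big = ObjectiveSpec(prob.objectives.names,
                            prob.objectives.observed * 1e6)
        cfg = CNMConfig(n_samples=20, n_iterations=1, ds=0.0, seed=0,
                        target_perturbation=0.0)
        res = run_cnm(prob.model, prob.space, big, cfg)
        assert res.history[0].n_out_of_box == 0
        assert res.history[-1].n_out_of_box > 0
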