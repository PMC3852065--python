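import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clusternewton import (ClusterNewton, Cluster, CNMConfig, ParameterSpace,
                           geometric_summary, parameter_correlations,
                           score_samples, select_best, ss_log,
                           synthetic_observed_profile)
from clusternewton.analysis import ds_sweep
from clusternewton.core import run_cnm
from clusternewton.forward import CallableModel
from clusternewton.space import ObjectiveSpec
from clusternewton.synthetic import make_affine_problem


class TestSsLog:
    def test_perfect_agreement_scores_zero(self):
        obs = np.array([10.0, 20.0, 30.0])
        assert ss_log(obs, obs) == 0.0

    def test_single_point_e_fold_scores_one(self):
        assert ss_log([np.e * 5.0], [5.0]) == pytest.approx(1.0)

    def test_printed_formula_on_known_ratios(self):
        # ratios (2, 0.5, 1): two squared ln-2 terms
        obs = np.array([1.0, 4.0, 9.0])
        sim = obs * np.array([2.0, 0.5, 1.0])
        assert ss_log(sim, obs) == pytest.approx(2 * np.log(2.0) ** 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ss_log([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="positive"):
            ss_log([1.0], [0.0])

    def test_zero_simulated_amount_is_floored_not_infinite(self):
        val = ss_log([0.0], [100.0], floor=1e-12)
        assert np.isfinite(val) and val > 100.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=8),
           st.lists(st.floats(1e-3, 1e3), min_size=8, max_size=8))
    def test_nonnegative_and_zero_iff_equal(self, obs, sim):
        obs = np.asarray(obs)
        sim = np.asarray(sim[:len(obs)])
        v = ss_log(sim, obs)
        assert v >= 0.0
        assert (v == 0.0) == bool(np.all(sim == obs))


class TestSelection:
    def _scores(self, vals):
        return pd.DataFrame({"sample_id": np.arange(len(vals)),
                             "ss_log": vals})

    def test_argmin_and_full_set(self):
        s = self._scores([0.5, 0.1, 0.3])
        assert list(select_best(s, 1)) == [1]
        assert set(select_best(s, 3)) == {0, 1, 2}
        with pytest.raises(ValueError):
            select_best(s, 4)

    def test_ties_break_by_sample_id(self):
        s = self._scores([0.2, 0.2, 0.1])
        assert list(select_best(s, 2)) == [2, 0]

    def test_selection_is_nested_in_k(self):
        rng = np.random.default_rng(0)
        s = self._scores(rng.random(30))
        for k1, k2 in [(1, 5), (5, 12), (12, 30)]:
            assert set(select_best(s, k1)) <= set(select_best(s, k2))


class TestGeometricSummary:
    def _space(self, p):
        return ParameterSpace([f"p{i}" for i in range(p)],
                              lower=np.full(p, 1e-3), upper=np.full(p, 1e3))

    def test_degenerate_cluster(self):
        Z = np.tile(np.log([3.0, 7.0]), (5, 1))
        gs = geometric_summary(Cluster(Z), self._space(2))
        np.testing.assert_allclose(gs["geometric_mean"], [3.0, 7.0])
        np.testing.assert_allclose(gs["log_sd"], 0.0, atol=1e-12)
        np.testing.assert_allclose(gs["geometric_sd"], 1.0, atol=1e-12)

    def test_two_samples_geometric_mean(self):
        Z = np.log([[1.0], [100.0]])
        gs = geometric_summary(Cluster(Z), self._space(1))
        assert gs["geometric_mean"][0] == pytest.approx(10.0)

    def test_lognormal_draws_recover_location(self, rng):
        Z = rng.normal(np.log(5.7), 0.5, size=(20000, 1))
        gs = geometric_summary(Cluster(Z), self._space(1))
        assert gs["geometric_mean"][0] == pytest.approx(5.7, rel=0.02)
        assert gs["geometric_sd"][0] == pytest.approx(np.exp(0.5), rel=0.02)


class TestCorrelations:
    def _space(self, names):
        return ParameterSpace(names, np.full(len(names), 1e-6),
                              np.full(len(names), 1e6))

    def test_proportional_columns_screen_in(self, rng):
        x = rng.standard_normal(200)
        Z = np.column_stack([x, 2.0 * x + 1.0, rng.standard_normal(200)])
        rep = parameter_correlations(Cluster(Z), self._space(["a", "b", "c"]))
        pair = rep.pairs.set_index(["name_i", "name_j"]).loc[("a", "b")]
        assert pair["r2"] == pytest.approx(1.0)
        assert rep.screened_parameters == ["a", "b"]

    def test_anticorrelation_reported_with_sign(self, rng):
        x = rng.standard_normal(500)
        Z = np.column_stack([x, -x + 0.05 * rng.standard_normal(500)])
        rep = parameter_correlations(Cluster(Z), self._space(["a", "b"]))
        pair = rep.pairs.iloc[0]
        assert pair["r2"] > 0.64 and pair["r"] < 0

    def test_independent_columns_screen_out(self, rng):
        Z = rng.standard_normal((2000, 2))
        rep = parameter_correlations(Cluster(Z), self._space(["a", "b"]))
        assert rep.screened.empty

    def test_zero_variance_excluded_not_imputed(self, rng):
        Z = np.column_stack([rng.standard_normal(50), np.full(50, 2.0)])
        rep = parameter_correlations(Cluster(Z), self._space(["a", "b"]))
        assert rep.undefined_parameters == ["b"]
        assert rep.pairs.empty

    def test_invariance_to_relabeling_and_unit_rescaling(self, rng):
        Z = rng.standard_normal((300, 3)) @ rng.standard_normal((3, 3))
        space = self._space(["a", "b", "c"])
        base = parameter_correlations(Cluster(Z), space).pairs
        perm = rng.permutation(300)
        shuffled = parameter_correlations(Cluster(Z[perm]), space).pairs
        # rescaling a parameter's units is an additive shift in ln-space
        rescaled = parameter_correlations(
            Cluster(Z + np.array([np.log(1000.0), 0.0, 0.0])), space).pairs
        pd.testing.assert_frame_equal(base, shuffled)
        np.testing.assert_allclose(base["r"], rescaled["r"], atol=1e-12)


class TestProfileScoring:
    def test_best_samples_track_observed_profiles_more_tightly(self, oc):
        cn = ClusterNewton.from_scenario(oc)
        res = cn.fit(n_samples=60, n_iterations=3, ds=0.5, seed=4)
        times, series = synthetic_observed_profile("OC")
        scores = score_samples(res, series, times)
        assert len(scores) == 60 and np.all(scores["ss_log"] >= 0)
        best = select_best(scores, 10)
        X = res.space.to_original(res.final_cluster.Z)
        terminal_urine = np.array([
            res.model.simulate(x, times=times).urine_total[-1] for x in X])
        sel = np.isin(res.final_cluster.sample_ids, best)
        iqr = lambda v: np.subtract(*np.percentile(v, [75, 25]))
        assert iqr(terminal_urine[sel]) < iqr(terminal_urine)


class TestDsSweep:
    def _toy(self):
        return make_affine_problem(4, 2, rank=2, seed=13)

    def test_sweep_is_deterministic(self):
        prob = self._toy()
        cfg = CNMConfig(n_samples=25, n_iterations=3, seed=8)
        a = ds_sweep(prob.model, prob.space, prob.objectives, cfg, [0.0, 0.5])
        b = ds_sweep(prob.model, prob.space, prob.objectives, cfg, [0.0, 0.5])
        pd.testing.assert_frame_equal(a, b)

    def test_affine_toy_converges_in_one_iteration_at_ds_zero(self):
        prob = self._toy()
        cfg = CNMConfig(n_samples=25, n_iterations=1, seed=8,
                        target_perturbation=0.0)
        rep = ds_sweep(prob.model, prob.space, prob.objectives, cfg, [0.0])
        row = rep.iloc[0]
        assert row["converged"] and row["diverged_at"] is None \
            and row["residual_median"] < 1e-10

    def test_individual_failures_recorded_sweep_continues(self):
        bad = CallableModel(lambda x: np.array([np.nan]), ["p0"], ["y"])
        space = ParameterSpace(["p0"], [0.1], [10.0])
        spec = ObjectiveSpec(["y"], [1.0])
        cfg = CNMConfig(n_samples=10, n_iterations=2, seed=0)
        rep = ds_sweep(bad, space, spec, cfg, [0.0, 0.5])
        assert len(rep) == 2
        assert (~rep["converged"]).all()
        assert rep["error"].notna().all()
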