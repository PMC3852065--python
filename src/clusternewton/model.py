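"""Model-level interface: build an ensemble inverse problem, call ``fit``.

Usage mirrors the estimation-package idiom — a model object is constructed
from the forward map, the parameter space and the observed targets, and
``fit()`` returns a results object carrying the estimates, their spread,
diagnostics and a ``summary()``::

    scen = load_scenario("oc")
    cn = ClusterNewton(IrinotecanPBPK(scen.dosing), scen.space, scen.objectives)
    res = cn.fit(n_samples=3000, n_iterations=9, ds=0.5, seed=1)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace

from .core import CNMConfig, run_cnm
from .forward import ForwardModel
from .results import FitResult
from .space import ObjectiveSpec, ParameterSpace

__all__ = ["ClusterNewton"]


class ClusterNewton:
    """Ensemble (Cluster Newton) solver bound to one inverse problem.

    Parameters
    ----------
    model : ForwardModel
        Forward map from a full original-scale parameter vector to positive
        objective values.
    space : ParameterSpace
        Bounded, partially fixed parameter definition; all internal work is
        done in ln-space.
    objectives : ObjectiveSpec
        Observed target values (strictly positive).
    **config
        Default :class:`~clusternewton.core.CNMConfig` overrides applied to
        every subsequent ``fit``.
    """

    def __init__(self, model: ForwardModel, space: ParameterSpace,
                 objectives: ObjectiveSpec, **config):
        if space.n_free == 0:
            pass   # degenerate but legal: the ensemble is a single point
        self.model = model
        self.space = space
        self.objectives = objectives
        self._config = CNMConfig(**config)

    @classmethod
    def from_scenario(cls, scenario, model=None, **config) -> "ClusterNewton":
        """Build from a :class:`~clusternewton.config.Scenario` (or its
        packaged name), defaulting to the irinotecan PBPK forward model."""
        from .config import Scenario, load_scenario
        if not isinstance(scenario, Scenario):
            scenario = load_scenario(scenario)
        if model is None:
            from .pbpk import IrinotecanPBPK
            model = IrinotecanPBPK(scenario.dosing)
        return cls(model, scenario.space, scenario.objectives, **config)

    @property
    def config(self) -> CNMConfig:
        return self._config

    def fit(self, callback=None, **overrides) -> FitResult:
        """Run the ensemble fit; keyword overrides update the stored config
        (e.g. ``n_samples=3000, n_iterations=9, ds=0.5, seed=1``)."""
        cfg = replace(self._config, **overrides) if overrides else self._config
        return run_cnm(self.model, self.space, self.objectives, cfg,
                       callback=callback)

    def sweep(self, ds_values, **overrides):
        """dS sweep with a shared seed; see :func:`analysis.ds_sweep`."""
        from .analysis import ds_sweep
        cfg = replace(self._config, **overrides) if overrides else self._config
        return ds_sweep(self.model, self.space, self.objectives, cfg,
                        ds_values)
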