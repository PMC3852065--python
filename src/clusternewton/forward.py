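"""Forward-model contract: parameter vector -> objective vector."""

from __future__ import annotations

import numpy as np


class ForwardModel:
    """Base class for forward models consumed by the ensemble solver.

    Subclasses implement :meth:`evaluate`, mapping one full original-scale
    parameter vector to a vector of positive objective values, and set
    ``param_names`` / ``objective_names``.  A failing evaluation should raise
    :class:`clusternewton.core.EvaluationError` (or return non-finite values);
    the solver isolates such rows instead of aborting.
    """

    param_names: list = None
    objective_names: list = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_objectives(self) -> int:
        return len(self.objective_names)

    def evaluate(self, params: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def evaluate_many(self, P: np.ndarray) -> np.ndarray:
        """Row-wise evaluation; order-independent by construction."""
        return np.array([self.evaluate(p) for p in np.atleast_2d(P)])


class CallableModel(ForwardModel):
    """Adapter wrapping a plain function ``f(params) -> objectives``."""

    def __init__(self, func, param_names, objective_names):
        self.func = func
        self.param_names = list(param_names)
        self.objective_names = list(objective_names)

    def evaluate(self, params):
        return np.asarray(self.func(np.asarray(params, dtype=float)),
                          dtype=float)


class LogAffineModel(ForwardModel):
    """Exactly log-log-affine model: ``ln y = A ln x + b``.

    The workhorse of the synthetic test problems: the solver's surrogate is
    exact for it, so solution manifolds are known in closed form.
    """

    def __init__(self, A, b, param_names=None, objective_names=None):
        self.A = np.asarray(A, dtype=float)
        self.b = np.asarray(b, dtype=float)
        m, p = self.A.shape
        self.param_names = list(param_names) if param_names is not None \
            else [f"p{i + 1}" for i in range(p)]
        self.objective_names = list(objective_names) if objective_names is not None \
            else [f"y{j + 1}" for j in range(m)]

    def evaluate(self, params):
        return np.exp(self.A @ np.log(np.asarray(params, dtype=float)) + self.b)

    def null_basis(self, rcond=1e-10):
        """Orthonormal basis of the null space of A (ln-space directions
        along which the objectives are invariant)."""
        from scipy.linalg import null_space
        return null_space(self.A, rcond=rcond)
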