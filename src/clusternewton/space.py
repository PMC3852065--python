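"""Parameter-space and objective definitions for ensemble inverse problems.

All sampling and linear algebra in the solver act on the natural log of the
parameters, so a parameter box ``[lower, upper]`` becomes a log-box
``[ln lower, ln upper]``.  Parameters may be fixed (held at a constant value,
possibly zero); fixed parameters never enter the log-space cluster and are
re-inserted when assembling full vectors for a forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid parameter-space / objective / solver configuration."""


@dataclass
class ParameterSpace:
    """A named, bounded, partially fixed parameter vector definition.

    Parameters
    ----------
    names : list of str
        One identifier per parameter.
    lower, upper : array-like
        Bounds on the original (linear) scale.  For free parameters
        ``0 < lower < upper`` is required; bounds of fixed parameters are
        ignored.
    units : list of str, optional
        Unit string per parameter ("-" for dimensionless).
    fixed_mask : array-like of bool, optional
        True where the parameter is held constant.
    fixed_values : array-like, optional
        Constant values for fixed entries (may be zero); NaN elsewhere.
    """

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    units: list[str] = field(default=None)
    fixed_mask: np.ndarray = field(default=None)
    fixed_values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.names = list(self.names)
        n = len(self.names)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.units is None:
            self.units = ["-"] * n
        self.units = list(self.units)
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(n, dtype=bool)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if self.fixed_values is None:
            self.fixed_values = np.full(n, np.nan)
        self.fixed_values = np.asarray(self.fixed_values, dtype=float)
        for arr, label in [(self.lower, "lower"), (self.upper, "upper"),
                           (self.fixed_mask, "fixed_mask"),
                           (self.fixed_values, "fixed_values")]:
            if arr.shape != (n,):
                raise ConfigurationError(
                    f"{label} has shape {arr.shape}, expected ({n},)")
        if len(self.units) != n:
            raise ConfigurationError("units length mismatch")
        for i in np.flatnonzero(~self.fixed_mask):
            lo, up = self.lower[i], self.upper[i]
            if not (0.0 < lo < up) or not np.isfinite(lo) or not np.isfinite(up):
                raise ConfigurationError(
                    f"parameter {self.names[i]!r}: free parameter requires "
                    f"0 < lower < upper, got [{lo}, {up}]")
        for i in np.flatnonzero(self.fixed_mask):
            if not np.isfinite(self.fixed_values[i]):
                raise ConfigurationError(
                    f"parameter {self.names[i]!r}: fixed but no finite value given")

    # -- geometry -----------------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed_mask)

    @property
    def n_free(self) -> int:
        return int((~self.fixed_mask).sum())

    @property
    def free_names(self) -> list[str]:
        return [self.names[i] for i in self.free_indices]

    @property
    def log_lower(self) -> np.ndarray:
        """ln of the lower bounds of the free parameters."""
        return np.log(self.lower[~self.fixed_mask])

    @property
    def log_upper(self) -> np.ndarray:
        return np.log(self.upper[~self.fixed_mask])

    @property
    def log_center(self) -> np.ndarray:
        return 0.5 * (self.log_lower + self.log_upper)

    # -- assembly -----------------------------------------------------------

    def to_original(self, Z: np.ndarray) -> np.ndarray:
        """Assemble full original-scale parameter matrix from free ln-values.

        Parameters
        ----------
        Z : ndarray, shape (n_samples, n_free) or (n_free,)

        Returns
        -------
        ndarray, shape (n_samples, n_params) or (n_params,)
        """
        Z = np.asarray(Z, dtype=float)
        single = Z.ndim == 1
        Z2 = np.atleast_2d(Z)
        if Z2.shape[1] != self.n_free:
            raise ConfigurationError(
                f"expected {self.n_free} free parameters, got {Z2.shape[1]}")
        X = np.empty((Z2.shape[0], self.n_params))
        X[:, ~self.fixed_mask] = np.exp(Z2)
        X[:, self.fixed_mask] = self.fixed_values[self.fixed_mask]
        return X[0] if single else X

    def to_log_free(self, x: np.ndarray) -> np.ndarray:
        """ln of the free entries of a full original-scale vector/matrix."""
        x = np.asarray(x, dtype=float)
        return np.log(x[..., ~self.fixed_mask])

    def out_of_box(self, Z: np.ndarray) -> np.ndarray:
        """Boolean mask of entries outside the free-parameter log-box."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return (Z < self.log_lower) | (Z > self.log_upper)

    def fix(self, name: str, value: float) -> "ParameterSpace":
        """Return a copy with one parameter fixed at *value*."""
        i = self.names.index(name)
        mask = self.fixed_mask.copy()
        vals = self.fixed_values.copy()
        mask[i] = True
        vals[i] = value
        return ParameterSpace(self.names, self.lower, self.upper,
                              units=self.units, fixed_mask=mask, fixed_values=vals)


@dataclass
class ObjectiveSpec:
    """Observed target values the ensemble is steered toward.

    Targets must be strictly positive: residuals are measured as
    ``ln(simulated / observed)``.
    """

    names: list[str]
    observed: np.ndarray
    weights: np.ndarray = field(default=None)

    def __post_init__(self):
        self.names = list(self.names)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.observed)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.observed.shape != (len(self.names),):
            raise ConfigurationError("observed length must match names")
        if self.weights.shape != self.observed.shape:
            raise ConfigurationError("weights length must match names")
        bad = np.flatnonzero(~(self.observed > 0) | ~np.isfinite(self.observed))
        if bad.size:
            raise ConfigurationError(
                f"objective {self.names[bad[0]]!r}: observed value must be a "
                f"positive finite number (log-residuals undefined otherwise)")

    @property
    def n_objectives(self) -> int:
        return len(self.names)

    @property
    def log_observed(self) -> np.ndarray:
        return np.log(self.observed)
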