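"""Post-fit statistics: goodness of fit, best-sample selection, parameter
summaries, correlation screening and dS-sweep diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Cluster, CNMConfig, run_cnm
from .space import ParameterSpace

__all__ = [
    "ss_log", "score_samples", "select_best", "geometric_summary",
    "parameter_correlations", "CorrelationReport", "ds_sweep",
]


def ss_log(simulated, observed, floor: float = 1e-12) -> float:
    """Sum of squared log residuals between matched cumulative series.

    ``SS = Σ [ln(simulated / observed)]²`` over all time points (and, when
    2-D arrays are given, over all series/routes).  Simulated amounts are
    floored at *floor* before taking the ratio so that a vanishing simulated
    amount yields a large but finite penalty; observed values must be
    positive.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"shape mismatch: simulated {sim.shape} vs "
                         f"observed {obs.shape}")
    if np.any(obs <= 0):
        raise ValueError("observed amounts must be strictly positive")
    return float(np.sum(np.log(np.maximum(sim, floor) / obs) ** 2))


def score_samples(result, observed: dict, times: np.ndarray,
                  per_compound: bool = False) -> pd.DataFrame:
    """SS_log of every final-cluster sample against observed time-profiles.

    Parameters
    ----------
    result : FitResult
        A fit whose forward model exposes ``simulate`` (the PBPK model).
    observed : dict route -> array
        Observed cumulative *total* amounts per route ("urine", "feces" and,
        for BDC, "ttube"), matched to *times*.
    times : array
        Sampling times (min) of the observed series.

    Returns a frame with columns sample_id, ss_log, rank; ranking ties are
    broken deterministically by sample_id.
    """
    times = np.asarray(times, dtype=float)
    X = result.space.to_original(result.final_cluster.Z)
    ids = result.final_cluster.sample_ids
    routes = list(observed)
    scores = np.empty(len(ids))
    for j in range(len(ids)):
        prof = result.model.simulate(X[j], times=times)
        totals = {"urine": prof.urine_total, "feces": prof.feces_total,
                  "ttube": prof.ttube_total}
        scores[j] = sum(ss_log(totals[r], np.asarray(observed[r], dtype=float))
                        for r in routes)
    df = pd.DataFrame({"sample_id": ids, "ss_log": scores})
    df = df.sort_values(["ss_log", "sample_id"], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def select_best(scores: pd.DataFrame, k: int) -> np.ndarray:
    """IDs of the *k* samples with the lowest SS_log (ties by sample_id)."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of scored samples")
    ordered = scores.sort_values(["ss_log", "sample_id"], kind="mergesort")
    return ordered["sample_id"].to_numpy()[:k]


def geometric_summary(cluster: Cluster, space: ParameterSpace) -> pd.DataFrame:
    """Per-parameter geometric mean and spread of the ensemble.

    Reports the geometric mean ``exp(mean(ln p))``, the multiplicative SD
    ``exp(sd(ln p))`` (the ×/÷ factor), and the plain ln-scale mean and SD.
    """
    Z = cluster.Z
    mean_ln = Z.mean(axis=0)
    sd_ln = Z.std(axis=0, ddof=1) if cluster.n_samples > 1 \
        else np.zeros(Z.shape[1])
    free = space.free_indices
    return pd.DataFrame({
        "name": [space.names[i] for i in free],
        "unit": [space.units[i] for i in free],
        "geometric_mean": np.exp(mean_ln),
        "geometric_sd": np.exp(sd_ln),
        "log_mean": mean_ln,
        "log_sd": sd_ln,
        "min": np.exp(Z.min(axis=0)),
        "max": np.exp(Z.max(axis=0)),
    })


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of ln-parameters.

    ``pairs`` lists every defined pair with r and r²; ``screened`` holds the
    subset with r² above the threshold; ``screened_parameters`` are the
    parameters correlated (r² > threshold) with at least one other.
    Zero-variance parameters have undefined r and are excluded (reported in
    ``undefined_parameters``), not imputed.
    """

    pairs: pd.DataFrame
    threshold: float
    undefined_parameters: list

    @property
    def screened(self) -> pd.DataFrame:
        return self.pairs[self.pairs["r2"] > self.threshold]

    @property
    def screened_parameters(self) -> list:
        s = self.screened
        return sorted(set(s["name_i"]) | set(s["name_j"]))


def parameter_correlations(cluster: Cluster, space: ParameterSpace,
                           threshold: float = 0.64) -> CorrelationReport:
    """Pairwise Pearson r on ln-parameters with an r² screen.

    Sign is reported so inverse relationships (negative r with r² above the
    threshold) are distinguishable from proportional ones.
    """
    Z = cluster.Z
    if cluster.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    names = space.free_names
    sd = Z.std(axis=0)
    defined = sd > 0
    undefined = [n for n, d in zip(names, defined) if not d]
    idx = np.flatnonzero(defined)
    C = np.corrcoef(Z[:, idx].T) if idx.size > 1 else np.ones((idx.size,) * 2)
    rows = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            r = float(C[a, b])
            rows.append((names[idx[a]], names[idx[b]], r, r * r))
    pairs = pd.DataFrame(rows, columns=["name_i", "name_j", "r", "r2"])
    return CorrelationReport(pairs=pairs, threshold=threshold,
                             undefined_parameters=undefined)


def plot_correlation_matrix(cluster: Cluster, space: ParameterSpace,
                            threshold: float = 0.64, max_params: int = 12):
    """Scatter-matrix of the ln-parameters screened by the r² threshold.

    Returns a matplotlib Figure (requires the optional plotting dependency).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    report = parameter_correlations(cluster, space, threshold=threshold)
    names = report.screened_parameters[:max_params]
    if not names:
        raise ValueError(f"no parameter pair exceeds r^2 = {threshold}")
    cols = [space.free_names.index(n) for n in names]
    Z = cluster.Z[:, cols]
    k = len(names)
    fig, axes = plt.subplots(k, k, figsize=(1.6 * k, 1.6 * k),
                             squeeze=False, constrained_layout=True)
    for a in range(k):
        for b in range(k):
            ax = axes[a][b]
            if a == b:
                ax.hist(Z[:, a], bins=20, color="steelblue")
            else:
                ax.plot(Z[:, b], Z[:, a], ".", ms=1.5, alpha=0.5)
            if a == k - 1:
                ax.set_xlabel(names[b], fontsize=6)
            if b == 0:
                ax.set_ylabel(names[a], fontsize=6)
            ax.tick_params(labelsize=5)
    return fig


def ds_sweep(model, space, spec, base_config: CNMConfig,
             ds_values) -> pd.DataFrame:
    """Run the full fit once per dS value with a shared seed.

    Machine-readable convergence diagnostics per dS: a convergence flag
    (final median |ln(sim/obs)| within tolerance), the divergence iteration
    if any, final residual quantiles, and the final ensemble diversity
    (median per-parameter log-range).  Individual run failures are recorded
    and the sweep continues.
    """
    rows = []
    for ds in ds_values:
        cfg = replace(base_config, ds=float(ds))
        row = {"ds": float(ds)}
        try:
            res = run_cnm(model, space, spec, cfg)
        except Exception as exc:   # individual failures must not stop the sweep
            row.update(converged=False, diverged_at=getattr(exc, "iteration", None),
                       error=str(exc), residual_median=np.nan,
                       residual_q95=np.nan, diversity=np.nan)
            rows.append(row)
            continue
        d = res.diagnostics
        Z = res.final_cluster.Z
        log_range = Z.max(axis=0) - Z.min(axis=0)
        row.update(converged=d["converged"], diverged_at=d["diverged_at"],
                   error=None,
                   residual_median=d["final_residual_median"],
                   residual_q95=d["final_residual_quantiles"][3],
                   diversity=float(np.median(log_range)))
        rows.append(row)
    return pd.DataFrame(rows)
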