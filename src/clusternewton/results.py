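"""Fit results: final ensemble, history, diagnostics, summaries, export."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FitResult:
    """Outcome of an ensemble fit.

    Attributes
    ----------
    final_cluster : Cluster
        The ensemble after the last iteration (free-parameter ln-values).
    history : list of IterationRecord
        One record per iteration including iteration 0 (length
        ``n_iterations + 1``).
    residuals : ndarray or None
        Per-sample per-objective log-residuals ``ln(sim/obs)`` at the final
        iteration.
    diagnostics : dict
        Divergence flag/iteration, convergence flag, failed-evaluation
        counts, out-of-box counts.
    """

    model: object
    space: object
    objectives: object
    config: object
    final_cluster: object
    history: list
    residuals: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)

    # -- tabular views ------------------------------------------------------

    @property
    def params(self) -> pd.DataFrame:
        """Final ensemble on the original scale, one row per sample
        (free and fixed parameters)."""
        X = self.space.to_original(self.final_cluster.Z)
        return pd.DataFrame(X, columns=self.space.names,
                            index=pd.Index(self.final_cluster.sample_ids,
                                           name="sample_id"))

    @property
    def params_log(self) -> pd.DataFrame:
        """Final ensemble free-parameter ln-values."""
        return pd.DataFrame(self.final_cluster.Z,
                            columns=self.space.free_names,
                            index=pd.Index(self.final_cluster.sample_ids,
                                           name="sample_id"))

    def residual_history(self) -> pd.DataFrame:
        rows = [{
            "iteration": r.iteration,
            "residual_median": r.residual_median,
            "residual_q25": r.residual_q[0],
            "residual_q75": r.residual_q[2],
            "residual_q95": r.residual_q[3],
            "n_failed": r.n_failed,
            "n_out_of_box": r.n_out_of_box,
        } for r in self.history]
        return pd.DataFrame(rows)

    # -- statistics ---------------------------------------------------------

    def geometric_summary(self) -> pd.DataFrame:
        from .analysis import geometric_summary
        return geometric_summary(self.final_cluster, self.space)

    def correlations(self, threshold: float = 0.64):
        from .analysis import parameter_correlations
        return parameter_correlations(self.final_cluster, self.space,
                                      threshold=threshold)

    def summary(self) -> str:
        """Human-readable fit report."""
        gs = self.geometric_summary()
        d = self.diagnostics
        lines = []
        lines.append("Cluster Newton fit")
        lines.append("=" * 66)
        lines.append(f"samples: {self.final_cluster.n_samples}    "
                     f"iterations: {len(self.history) - 1}    "
                     f"dS: {self.config.ds}    seed: {self.config.seed}")
        lines.append(f"objectives: {self.objectives.n_objectives}    "
                     f"free parameters: {self.space.n_free}")
        lines.append(f"converged: {d.get('converged')}    "
                     f"diverged_at: {d.get('diverged_at')}    "
                     f"failed evaluations: {d.get('failed_evaluations')}")
        med = d.get("final_residual_median")
        if med is not None and np.isfinite(med):
            lines.append(f"final median |ln(sim/obs)|: {med:.4f} "
                         f"(x/ {np.exp(med):.3f} fold)")
        lines.append("-" * 66)
        lines.append(f"{'parameter':<22}{'unit':<10}{'geo mean':>10}"
                     f"{'geo SD':>8}{'ln-SD':>8}")
        for _, row in gs.iterrows():
            lines.append(f"{row['name']:<22}{row['unit']:<10}"
                         f"{row['geometric_mean']:>10.4g}"
                         f"{row['geometric_sd']:>8.3f}{row['log_sd']:>8.3f}")
        return "\n".join(lines)

    # -- export -------------------------------------------------------------

    def to_tidy(self, include_history: bool = False) -> pd.DataFrame:
        """Tidy long-format table: iteration, sample_id, name, value
        (original scale, free parameters)."""
        records = []
        snaps = (self.history if include_history
                 else [self.history[-1]]) if self.history else []
        for rec in snaps:
            if rec.cluster is None:
                continue
            X = self.space.to_original(rec.cluster.Z)
            free = self.space.free_indices
            for j, sid in enumerate(rec.cluster.sample_ids):
                for i in free:
                    records.append((rec.iteration, sid, self.space.names[i],
                                    X[j, i]))
        return pd.DataFrame(records,
                            columns=["iteration", "sample_id", "name", "value"])

    def manifest(self) -> dict:
        """JSON-serialisable run manifest (config echo, seed, diagnostics)."""
        from . import __version__
        cfg = {k: v for k, v in vars(self.config).items()}
        diag = {}
        for k, v in self.diagnostics.items():
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            if isinstance(v, tuple):
                v = list(v)
            diag[k] = v
        return {"schema_version": 1, "software_version": __version__,
                "config": cfg, "seed": self.config.seed, "diagnostics": diag,
                "residual_history": self.residual_history()
                                        .to_dict(orient="records")}

    def save(self, outdir, include_history: bool = True):
        """Write tidy parameter CSV + JSON manifest under *outdir*."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_tidy(include_history=include_history).to_csv(
            outdir / "parameters.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)
        return outdir
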