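"""Whole-body PBPK model of irinotecan (CPT-11) and four metabolites.

Irinotecan is metabolised by carboxylesterase-2 (CES2) and CYP3A4:

    CPT-11 --CES2-->  SN-38 --UGT1A--> SN-38G
    CPT-11 --CYP3A4-> APC
    CPT-11 --CYP3A4-> NPC --CES2--> SN-38

Each of the five compounds is tracked (in parent-mass equivalents, so
metabolic conversion moves mass 1:1 between compound pools, matching
total-radioactivity accounting) through:

* a rapid-equilibrium compartment (volume ``V_rapid``) receiving the
  zero-order intravenous infusion (CPT-11 only), exchanging with a late
  (deep) compartment via ``CL_12``/``k_21``, cleared renally (``CL_r``) into
  cumulative urine, and connected to the liver by hepatic blood flow ``Q_H``;
* a well-stirred liver (volume ``V_liver``, partition coefficient
  ``K_p,liver``): elimination and biliary excretion are driven by the
  blood-side concentration ``A_liver / (V_liver K_p)``;
* a chain of biliary transit compartments (biliary clearance ``CL_bile``
  in, first-order ``k_transit`` toward the small intestine) — the biliary
  limb of the enterohepatic circulation;
* small intestine (reabsorption ``k_a`` back into the liver — closing the
  enterohepatic loop — or transit ``k_LI`` onward), large intestine
  (``k_feces`` into cumulative feces);
* for the bile-duct-cancer (BDC) group, a biliary T-tube that diverts bile
  externally with clearance ``r_T * CL_bile`` (the same drainage fraction
  ``r_T`` for all compounds); ``r_T = 0`` for the other-cancer (OC) group.

All transfers are first order and the infusion is piecewise constant, so the
system is linear and time invariant within each phase; the default
integrator propagates the exact solution with matrix exponentials and a
stiff BDF solver is available as an independent route.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .core import EvaluationError
from .forward import ForwardModel

__all__ = [
    "COMPOUNDS", "DosingConfig", "PBPKParams", "AccumulationProfile",
    "pbpk_rhs", "build_rate_matrix", "simulate", "objectives_from_simulation",
    "IrinotecanPBPK", "parameter_names", "objective_names",
]

COMPOUNDS = ("CPT11", "SN38", "SN38G", "NPC", "APC")

# metabolic edges: (source index, product index, clearance attribute)
_MET_EDGES = (
    (0, 1, "cl_ces_cpt11"),    # CPT-11 -> SN-38    (CES2)
    (3, 1, "cl_ces_npc"),      # NPC    -> SN-38    (CES2)
    (0, 4, "cl_cyp3a4_apc"),   # CPT-11 -> APC      (CYP3A4)
    (0, 3, "cl_cyp3a4_npc"),   # CPT-11 -> NPC      (CYP3A4)
    (1, 2, "cl_ugt_sn38"),     # SN-38  -> SN-38G   (UGT1A)
)


@dataclass
class DosingConfig:
    """Dosing and physiological constants (per kg body weight).

    Defaults are the study settings: a 1500 µg/kg intravenous dose infused
    over 90 min, hepatic blood flow 20.7 ml/min/kg, liver volume 24.1 ml/kg.
    """

    dose: float = 1500.0              # µg/kg
    infusion_duration: float = 90.0   # min
    q_liver: float = 20.7             # ml/min/kg
    v_liver: float = 24.1             # ml/kg
    group: str = "OC"                 # {"OC", "BDC"}
    t_end: float = 7200.0             # min (5 days; excreta plateau)
    n_bile_transit: int = 1

    def __post_init__(self):
        if self.group not in ("OC", "BDC"):
            raise ValueError(f"group must be 'OC' or 'BDC', got {self.group!r}")
        if self.n_bile_transit < 1:
            raise ValueError("n_bile_transit must be >= 1")


@dataclass
class PBPKParams:
    """Model parameters; per-compound arrays follow :data:`COMPOUNDS` order.

    Clearances in ml/min/kg (``cl_12`` in ml/min), rate constants in /min,
    ``kp`` and ``r_t`` dimensionless, ``v_rapid`` in ml/kg.
    """

    kp: np.ndarray            # liver:blood partition coefficient
    cl_r: np.ndarray          # renal clearance
    cl_bile: np.ndarray       # biliary clearance into the transit chain
    k_feces: np.ndarray       # large intestine -> feces
    k_a: np.ndarray           # small intestine -> liver (reabsorption)
    k_li: np.ndarray          # small -> large intestine
    k_transit: np.ndarray     # bile transit -> small intestine
    cl_12: np.ndarray         # rapid -> late equilibrium clearance
    k_21: np.ndarray          # late -> rapid rate constant
    v_rapid: np.ndarray       # rapid-compartment volume
    cl_ces_cpt11: float       # CPT-11 -> SN-38 (CES2)
    cl_ces_npc: float         # NPC    -> SN-38 (CES2)
    cl_cyp3a4_apc: float      # CPT-11 -> APC   (CYP3A4)
    cl_cyp3a4_npc: float      # CPT-11 -> NPC   (CYP3A4)
    cl_ugt_sn38: float        # SN-38  -> SN-38G (UGT1A)
    r_t: float = 0.0          # CL_bile,T-tube / CL_bile,transit (0 for OC)

    def __post_init__(self):
        for name in ("kp", "cl_r", "cl_bile", "k_feces", "k_a", "k_li",
                     "k_transit", "cl_12", "k_21", "v_rapid"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (5,):
                raise ValueError(f"{name} must have one value per compound")
            setattr(self, name, arr)

    @classmethod
    def from_vector(cls, x) -> "PBPKParams":
        """Build from the 56-element vector in catalogue order
        (Kp ×5, CL_r ×5, CL_bile ×5, the five metabolic clearances,
        k_feces ×5, k_a ×5, k_LI ×5, k_transit ×5, CL_12 ×5, k_21 ×5,
        V_rapid ×5, r_T)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (56,):
            raise ValueError(f"expected 56 parameters, got {x.shape}")
        return cls(kp=x[0:5], cl_r=x[5:10], cl_bile=x[10:15],
                   cl_ces_cpt11=x[15], cl_ces_npc=x[16],
                   cl_cyp3a4_apc=x[17], cl_cyp3a4_npc=x[18],
                   cl_ugt_sn38=x[19],
                   k_feces=x[20:25], k_a=x[25:30], k_li=x[30:35],
                   k_transit=x[35:40], cl_12=x[40:45], k_21=x[45:50],
                   v_rapid=x[50:55], r_t=x[55])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.kp, self.cl_r, self.cl_bile,
            [self.cl_ces_cpt11, self.cl_ces_npc, self.cl_cyp3a4_apc,
             self.cl_cyp3a4_npc, self.cl_ugt_sn38],
            self.k_feces, self.k_a, self.k_li, self.k_transit,
            self.cl_12, self.k_21, self.v_rapid, [self.r_t]])


def parameter_names() -> list[str]:
    """The 56 parameter identifiers, in vector order."""
    names = []
    names += [f"Kp_liver_{c}" for c in COMPOUNDS]
    names += [f"CLr_{c}" for c in COMPOUNDS]
    names += [f"CLbile_{c}" for c in COMPOUNDS]
    names += ["CL_CES_CPT11", "CL_CES_NPC", "CL_CYP3A4_APC",
              "CL_CYP3A4_NPC", "CL_UGT_SN38"]
    names += [f"kfeces_{c}" for c in COMPOUNDS]
    names += [f"ka_{c}" for c in COMPOUNDS]
    names += [f"kLI_{c}" for c in COMPOUNDS]
    names += [f"ktransit_{c}" for c in COMPOUNDS]
    names += [f"CL12_{c}" for c in COMPOUNDS]
    names += [f"k21_{c}" for c in COMPOUNDS]
    names += [f"Vrapid_{c}" for c in COMPOUNDS]
    names += ["bile_Ttube_ratio"]
    return names


def objective_names(group: str) -> list[str]:
    """Cumulative-accumulation objective identifiers (9 for OC, 14 for BDC)."""
    names = [f"urine_{c}" for c in COMPOUNDS]
    names += ["feces_CPT11", "feces_SN38_SN38G", "feces_NPC", "feces_APC"]
    if group == "BDC":
        names += [f"bile_{c}" for c in COMPOUNDS]
    elif group != "OC":
        raise ValueError(f"group must be 'OC' or 'BDC', got {group!r}")
    return names


# ---------------------------------------------------------------------------
# state layout and rate matrix
# ---------------------------------------------------------------------------

def _n_states_per_compound(nt: int) -> int:
    # rapid, late, liver, nt bile transits, SI, LI, urine, feces, T-tube
    return 8 + nt


def state_index(compound: int, compartment: str, config: DosingConfig,
                transit: int = 0) -> int:
    """Index of a compartment in the flat state vector."""
    nt = config.n_bile_transit
    base = compound * _n_states_per_compound(nt)
    order = {"rapid": 0, "late": 1, "liver": 2}
    if compartment in order:
        return base + order[compartment]
    if compartment == "transit":
        return base + 3 + transit
    tail = {"si": 3 + nt, "li": 4 + nt, "urine": 5 + nt,
            "feces": 6 + nt, "ttube": 7 + nt}
    return base + tail[compartment]


def build_rate_matrix(params: PBPKParams, config: DosingConfig) -> np.ndarray:
    """First-order rate matrix M with dA/dt = M A (+ infusion input).

    M is a compartmental (Metzler) matrix with zero column sums — mass is
    conserved exactly, the excreta being absorbing states.
    """
    nt = config.n_bile_transit
    ns = _n_states_per_compound(nt)
    N = 5 * ns
    M = np.zeros((N, N))
    Q = config.q_liver
    VL = config.v_liver

    def idx(c, comp, transit=0):
        return state_index(c, comp, config, transit)

    for c in range(5):
        vr = params.v_rapid[c]
        kliver = 1.0 / (VL * params.kp[c])   # amount -> blood-side conc
        i_rap, i_lat, i_liv = idx(c, "rapid"), idx(c, "late"), idx(c, "liver")
        i_si, i_li = idx(c, "si"), idx(c, "li")
        i_ur, i_fe, i_tt = idx(c, "urine"), idx(c, "feces"), idx(c, "ttube")

        # rapid equilibrium compartment
        M[i_rap, i_rap] -= (Q + params.cl_r[c] + params.cl_12[c]) / vr
        M[i_rap, i_lat] += params.k_21[c]
        M[i_rap, i_liv] += Q * kliver
        # late equilibrium compartment
        M[i_lat, i_rap] += params.cl_12[c] / vr
        M[i_lat, i_lat] -= params.k_21[c]
        # urine
        M[i_ur, i_rap] += params.cl_r[c] / vr
        # liver: inflow, outflow, biliary excretion, reabsorption
        met_out = sum(getattr(params, attr) for (src, _, attr) in _MET_EDGES
                      if src == c)
        cl_bile_total = params.cl_bile[c] * (1.0 + params.r_t)
        M[i_liv, i_rap] += Q / vr
        M[i_liv, i_liv] -= (Q + cl_bile_total + met_out) * kliver
        M[i_liv, i_si] += params.k_a[c]
        # biliary transit chain
        first = idx(c, "transit", 0)
        M[first, i_liv] += params.cl_bile[c] * kliver
        for t in range(nt):
            it = idx(c, "transit", t)
            M[it, it] -= params.k_transit[c]
            if t + 1 < nt:
                M[idx(c, "transit", t + 1), it] += params.k_transit[c]
        M[i_si, idx(c, "transit", nt - 1)] += params.k_transit[c]
        # intestinal transit and elimination
        M[i_si, i_si] -= params.k_a[c] + params.k_li[c]
        M[i_li, i_si] += params.k_li[c]
        M[i_li, i_li] -= params.k_feces[c]
        M[i_fe, i_li] += params.k_feces[c]
        # biliary T-tube drainage
        M[i_tt, i_liv] += params.r_t * params.cl_bile[c] * kliver

    # metabolic conversion in the liver (parent-mass equivalents, 1:1)
    for (src, dst, attr) in _MET_EDGES:
        cl = getattr(params, attr)
        ksrc = 1.0 / (VL * params.kp[src])
        M[idx(dst, "liver"), idx(src, "liver")] += cl * ksrc
    return M


def infusion_vector(params: PBPKParams, config: DosingConfig) -> np.ndarray:
    """Zero-order input (µg/kg/min) during the infusion: CPT-11 rapid only."""
    u = np.zeros(5 * _n_states_per_compound(config.n_bile_transit))
    u[state_index(0, "rapid", config)] = config.dose / config.infusion_duration
    return u


def pbpk_rhs(t: float, state: np.ndarray, params: PBPKParams,
             config: DosingConfig) -> np.ndarray:
    """Time derivative of the full state (for ODE-solver integration)."""
    M = build_rate_matrix(params, config)
    dy = M @ state
    if 0.0 <= t < config.infusion_duration:
        dy = dy + infusion_vector(params, config)
    return dy


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class AccumulationProfile:
    """Cumulative excreta time-profiles plus full compartment history.

    ``urine``/``feces``/``ttube`` are (n_times, 5) per-compound cumulative
    amounts in µg parent-equivalent per kg; ``states`` holds every
    compartment for mass-balance checks.
    """

    times: np.ndarray
    urine: np.ndarray
    feces: np.ndarray
    ttube: np.ndarray
    states: np.ndarray
    config: DosingConfig
    params: PBPKParams

    @property
    def urine_total(self) -> np.ndarray:
        return self.urine.sum(axis=1)

    @property
    def feces_total(self) -> np.ndarray:
        return self.feces.sum(axis=1)

    @property
    def ttube_total(self) -> np.ndarray:
        return self.ttube.sum(axis=1)

    def infused(self) -> np.ndarray:
        """Cumulative infused amount at each output time."""
        c = self.config
        return c.dose * np.minimum(self.times, c.infusion_duration) \
            / c.infusion_duration

    def mass_balance_error(self) -> np.ndarray:
        """|total in system + excreta − infused| / dose at each time."""
        total = self.states.sum(axis=1)
        return np.abs(total - self.infused()) / self.config.dose

    def to_frame(self):
        """Tidy long-format table (time, compound, route, amount)."""
        import pandas as pd
        rows = []
        for route, arr in (("urine", self.urine), ("feces", self.feces),
                           ("ttube", self.ttube)):
            for ci, cname in enumerate(COMPOUNDS):
                for t, a in zip(self.times, arr[:, ci]):
                    rows.append((t, cname, route, a))
        return pd.DataFrame(rows, columns=["time", "compound", "route",
                                           "amount"])


def _propagate_expm(M: np.ndarray, u: np.ndarray, times: np.ndarray,
                    duration: float) -> np.ndarray:
    """Exact piecewise-LTI propagation; returns states at `times`.

    The constant infusion is handled by augmenting the system with a dummy
    state of constant value 1 feeding the input vector.
    """
    N = M.shape[0]
    Maug = np.zeros((N + 1, N + 1))
    Maug[:N, :N] = M
    Maug[:N, N] = u
    cache: dict[tuple, np.ndarray] = {}

    def step(mat, dt, key):
        k = (key, round(float(dt), 9))
        if k not in cache:
            cache[k] = expm(mat * dt)
        return cache[k]

    # breakpoints: all output times plus the end of infusion
    out = np.zeros((len(times), N))
    x = np.zeros(N)
    t_now = 0.0
    for i, t in enumerate(times):
        seg_targets = []
        if t_now < duration <= t:
            seg_targets.append(duration)
        seg_targets.append(t)
        for t_next in seg_targets:
            dt = t_next - t_now
            if dt > 0:
                if t_next <= duration:
                    xa = np.append(x, 1.0)
                    x = (step(Maug, dt, "inf") @ xa)[:N]
                else:
                    x = step(M, dt, "free") @ x
            t_now = t_next
        out[i] = x
    return out


def simulate(params: PBPKParams, config: DosingConfig,
             times: np.ndarray | None = None, method: str = "expm",
             rtol: float = 1e-8) -> AccumulationProfile:
    """Integrate the model from an all-zero initial state.

    Parameters
    ----------
    times : array-like, optional
        Output grid (min).  Defaults to a grid resolving the infusion and
        the excretion phase up to ``config.t_end``.
    method : {"expm", "bdf"}
        "expm" (default) propagates the exact linear-system solution;
        "bdf" integrates with :func:`scipy.integrate.solve_ivp` (stiff BDF),
        the conventional stiff-ODE route, kept as an independent check.
    """
    if times is None:
        d, te = config.infusion_duration, config.t_end
        times = np.unique(np.concatenate([
            np.linspace(0.0, d, 7), np.linspace(d, te, 61)]))
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("times must be a non-decreasing 1-D grid of t >= 0")
    M = build_rate_matrix(params, config)
    u = infusion_vector(params, config)

    if method == "expm":
        states = _propagate_expm(M, u, times, config.infusion_duration)
    elif method == "bdf":
        from scipy.integrate import solve_ivp

        def rhs(t, y):
            dy = M @ y
            if t < config.infusion_duration:
                dy = dy + u
            return dy

        t0 = float(times[0])
        y0 = np.zeros(M.shape[0])
        if t0 > 0:   # integrate silently up to the first requested time
            pre = solve_ivp(rhs, (0.0, t0), y0, method="BDF", rtol=rtol,
                            atol=1e-10, jac=lambda t, y: M)
            if not pre.success:
                raise EvaluationError(f"stiff solver failed: {pre.message}")
            y0 = pre.y[:, -1]
        sol = solve_ivp(rhs, (t0, float(times[-1]) + 1e-9), y0, method="BDF",
                        t_eval=times, rtol=rtol, atol=1e-10,
                        jac=lambda t, y: M)
        if not sol.success:
            raise EvaluationError(f"stiff solver failed: {sol.message}")
        states = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(states)):
        raise EvaluationError("non-finite amounts (unstable parameter set)")
    if np.min(states) < -1e-6 * config.dose:
        raise EvaluationError("negative amounts beyond tolerance")
    states = np.maximum(states, 0.0)

    def gather(comp):
        return np.column_stack(
            [states[:, state_index(c, comp, config)] for c in range(5)])

    return AccumulationProfile(times=times, urine=gather("urine"),
                               feces=gather("feces"), ttube=gather("ttube"),
                               states=states, config=config, params=params)


def objectives_from_simulation(profile: AccumulationProfile,
                               group: str) -> np.ndarray:
    """Cumulative accumulation objectives at the end of the simulation.

    OC: urinary amounts of the five compounds, then fecal CPT-11,
    SN-38 + SN-38G combined (intestinal deconjugation makes the two
    indistinguishable in feces), NPC and APC — 9 values.  BDC adds the five
    biliary (T-tube) amounts — 14 values.
    """
    u, f, b = profile.urine[-1], profile.feces[-1], profile.ttube[-1]
    vals = list(u) + [f[0], f[1] + f[2], f[3], f[4]]
    if group == "BDC":
        vals += list(b)
    elif group != "OC":
        raise ValueError(f"group must be 'OC' or 'BDC', got {group!r}")
    return np.asarray(vals)


class IrinotecanPBPK(ForwardModel):
    """Forward model: 56 PBPK parameters -> accumulation objectives.

    The solver calls :meth:`evaluate` with full original-scale vectors (the
    OC group's T-tube ratio arrives as the fixed value 0).  Evaluation uses
    the exact matrix-exponential propagator at the terminal time only.
    """

    def __init__(self, dosing: DosingConfig | None = None, group: str | None = None,
                 method: str = "expm"):
        if dosing is None:
            dosing = DosingConfig(group=group or "OC")
        elif group is not None and group != dosing.group:
            dosing = replace(dosing, group=group)
        self.dosing = dosing
        self.method = method
        self.param_names = parameter_names()
        self.objective_names = objective_names(self.dosing.group)

    def evaluate(self, params: np.ndarray) -> np.ndarray:
        p = PBPKParams.from_vector(params)
        profile = simulate(p, self.dosing,
                           times=np.array([0.0, self.dosing.t_end]),
                           method=self.method)
        return objectives_from_simulation(profile, self.dosing.group)

    def simulate(self, params: np.ndarray, times=None,
                 method=None) -> AccumulationProfile:
        """Full accumulation time-profile for one parameter vector."""
        p = params if isinstance(params, PBPKParams) \
            else PBPKParams.from_vector(params)
        return simulate(p, self.dosing, times=times,
                        method=method or self.method)
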