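"""Forward simulation of paced cardiac action potentials.

Two models ship with the package:

* :func:`courtemanche_model` — the Courtemanche–Ramirez–Nattel (1998) human
  atrial ionic model (21 state variables), transcribed from the published
  equations, with every maximal conductance / maximal pump rate exposed as a
  dimensionless multiplier (1.0 reproduces the original parameterization).
* :func:`toy_model` — a fast two-variable phenomenological pulse model whose
  dynamics are linear, so the simulated trace can be checked against a closed
  form.  It is the default fixture for exercising the full inverse pipeline
  in seconds.

Simulation is cycle-by-cycle with a stiff implicit integrator; a configurable
number of pre-pacing cycles brings the model to a permanent regime before the
recorded beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CellModel",
    "PacingProtocol",
    "APTrace",
    "SolverConfig",
    "simulate_ap",
    "interpolate_to_grid",
    "courtemanche_model",
    "toy_model",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellModel:
    """An ODE cell model with scalable conductance multipliers.

    ``rhs(t, y, g, stim)`` returns the state derivative; ``g`` is the vector
    of *effective* conductance values (published value x multiplier) in the
    order of ``nominal_conductances``, and ``stim`` the instantaneous
    stimulus current (model-native units, pA/pF here).
    """

    name: str
    state_dim: int
    nominal_conductances: dict[str, float]
    fixed_parameters: dict[str, float]
    rhs: Callable[[float, np.ndarray, np.ndarray, float], np.ndarray]
    initial_state: np.ndarray
    voltage_index: int = 0

    def conductance_vector(self, multipliers: Mapping[str, float] | None) -> np.ndarray:
        """Effective conductances in canonical order; unnamed entries stay nominal."""
        multipliers = dict(multipliers or {})
        unknown = set(multipliers) - set(self.nominal_conductances)
        if unknown:
            raise KeyError(
                f"unknown conductance(s) {sorted(unknown)} for model {self.name!r}; "
                f"known: {sorted(self.nominal_conductances)}"
            )
        g = np.array(
            [
                self.nominal_conductances[name] * float(multipliers.get(name, 1.0))
                for name in self.nominal_conductances
            ]
        )
        if np.any(g < 0):
            raise ValueError("conductance multipliers must be non-negative")
        return g


@dataclass(frozen=True)
class PacingProtocol:
    """Square-pulse pacing at a fixed frequency."""

    frequency_hz: float = 1.0
    stimulus_duration_ms: float = 2.0
    stimulus_amplitude: float = 20.0
    n_prepace: int = 5

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.stimulus_duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.stimulus_duration_ms >= self.cycle_length_ms:
            raise ValueError("stimulus duration must be shorter than the cycle length")
        if self.n_prepace < 0:
            raise ValueError("n_prepace must be >= 0")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def tag(self) -> str:
        f = self.frequency_hz
        return f"{f:g}Hz"


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances and method of the stiff time integrator."""

    abs_tol: float = 1e-6
    rel_tol: float = 1e-6
    method: str = "LSODA"
    max_step: float = math.inf


@dataclass
class APTrace:
    """One paced AP cycle: times in ms (strictly increasing), voltages in mV."""

    times: np.ndarray
    voltages: np.ndarray
    meta: dict = field(default_factory=dict)
    ok: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must have the same length")
        if self.ok and self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _integrate_cycle(
    model: CellModel,
    y0: np.ndarray,
    g: np.ndarray,
    protocol: PacingProtocol,
    cfg: SolverConfig,
):
    """One paced cycle from t=0 (stimulus onset).  Returns (t, Y) on the
    solver's adaptive grid, stimulus segment included."""
    cl = protocol.cycle_length_ms
    sd = protocol.stimulus_duration_ms
    amp = protocol.stimulus_amplitude
    kw = dict(method=cfg.method, rtol=cfg.rel_tol, atol=cfg.abs_tol, max_step=cfg.max_step)

    sol_on = solve_ivp(lambda t, y: model.rhs(t, y, g, amp), (0.0, sd), y0, **kw)
    if not sol_on.success:
        raise RuntimeError(f"integration failed during stimulus: {sol_on.message}")
    sol_off = solve_ivp(
        lambda t, y: model.rhs(t, y, g, 0.0), (sd, cl), sol_on.y[:, -1], **kw
    )
    if not sol_off.success:
        raise RuntimeError(f"integration failed after stimulus: {sol_off.message}")
    t = np.concatenate([sol_on.t, sol_off.t[1:]])
    y = np.concatenate([sol_on.y, sol_off.y[:, 1:]], axis=1)
    # adaptive solvers may repeat the terminal time point
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], y[:, keep]


def simulate_ap(
    model: CellModel,
    multipliers: Mapping[str, float] | None = None,
    protocol: PacingProtocol | None = None,
    solver_cfg: SolverConfig | None = None,
) -> APTrace:
    """Simulate ``n_prepace`` conditioning cycles and return the next one.

    The returned trace lives on the solver's adaptive grid over one cycle
    (t=0 at stimulus onset).  ``meta['prepace_rel_l2']`` holds the relative L2
    difference between the returned cycle and the last pre-pacing cycle on a
    uniform 1 ms grid; ``meta['cycle_rel_l2']`` the full per-cycle history.

    Integration failures (e.g. at extreme g_Na) are returned as a flagged
    trace with ``ok=False`` rather than raised, so database construction can
    proceed past bad collocation points.
    """
    protocol = protocol or PacingProtocol()
    cfg = solver_cfg or SolverConfig()
    try:
        g = model.conductance_vector(multipliers)
    except (KeyError, ValueError):
        raise
    grid = np.arange(0.0, protocol.cycle_length_ms + 0.5, 1.0)
    grid = grid[grid <= protocol.cycle_length_ms]

    y = model.initial_state.copy()
    prev_v = None
    diffs: list[float] = []
    try:
        for _ in range(protocol.n_prepace + 1):
            t_cyc, y_cyc = _integrate_cycle(model, y, g, protocol, cfg)
            y = y_cyc[:, -1]
            v_grid = np.interp(grid, t_cyc, y_cyc[model.voltage_index])
            if prev_v is not None:
                denom = np.linalg.norm(prev_v)
                diffs.append(float(np.linalg.norm(v_grid - prev_v) / denom) if denom else np.nan)
            prev_v = v_grid
    except (RuntimeError, ArithmeticError, ValueError) as exc:
        return APTrace(
            times=np.array([0.0]),
            voltages=np.array([np.nan]),
            ok=False,
            meta={"error": str(exc), "multipliers": dict(multipliers or {})},
        )

    return APTrace(
        times=t_cyc,
        voltages=y_cyc[model.voltage_index],
        meta={
            "model": model.name,
            "protocol": protocol,
            "multipliers": dict(multipliers or {}),
            "prepace_rel_l2": diffs[-1] if diffs else np.nan,
            "cycle_rel_l2": diffs,
            "final_state": y,
        },
    )


def interpolate_to_grid(trace: APTrace, grid: Sequence[float]) -> APTrace:
    """Linearly interpolate a trace onto a common time grid (deterministic)."""
    grid = np.asarray(grid, dtype=float)
    if not trace.ok:
        return APTrace(grid, np.full(grid.shape, np.nan), ok=False, meta=dict(trace.meta))
    t0, t1 = trace.times[0], trace.times[-1]
    if grid[0] < t0 - 1e-12 or grid[-1] > t1 + 1e-12:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside trace span [{t0}, {t1}]"
        )
    v = np.interp(grid, trace.times, trace.voltages)
    return APTrace(grid, v, meta=dict(trace.meta))


# ---------------------------------------------------------------------------
# Courtemanche–Ramirez–Nattel 1998 human atrial model
# ---------------------------------------------------------------------------

_CRN_CONDUCTANCES = {
    # nS/pF maximal conductances and pA/pF maximal pump/exchanger rates
    "g_Na": 7.8,
    "g_K1": 0.09,
    "g_to": 0.1652,
    "g_Kr": 0.029411765,
    "g_Ks": 0.12941176,
    "g_CaL": 0.12375,
    "g_Kur": 1.0,          # scales the voltage-dependent g_Kur(V) expression
    "g_bNa": 0.0006744375,
    "g_bCa": 0.001131,
    "g_NaK": 0.59933874,   # I_NaK maximum
    "g_NaCa": 1600.0,      # I_NaCa maximum
    "g_pCa": 0.275,        # I_pCa maximum
}

_CRN_FIXED = {
    "R": 8.3143, "T": 310.0, "F": 96.4867,
    "Cm": 100.0,
    "V_i": 13668.0, "V_up": 1109.52, "V_rel": 96.48,
    "K_o": 5.4, "Na_o": 140.0, "Ca_o": 1.8,
    "K_rel": 30.0, "tau_tr": 180.0, "I_up_max": 0.005,
    "K_up": 0.00092, "Ca_up_max": 15.0,
    "CMDN_max": 0.05, "TRPN_max": 0.07, "CSQN_max": 10.0,
    "Km_CMDN": 0.00238, "Km_TRPN": 0.0005, "Km_CSQN": 0.8,
    "Km_Na_i": 10.0, "Km_K_o": 1.5,
    "K_mNa": 87.5, "K_mCa": 1.38, "K_sat": 0.1, "gamma": 0.35,
    "KQ10": 3.0,
}

# state: V m h j oa oi ua ui xr xs d f fca u v w Nai Ki Cai Caup Carel
_CRN_Y0 = np.array([
    -81.18, 2.908e-3, 0.9649, 0.9775, 3.043e-2, 0.9992, 4.966e-3, 0.9986,
    3.296e-5, 1.869e-2, 1.367e-4, 0.9996, 0.7755, 0.0, 1.0, 0.9992,
    11.17, 139.0, 1.013e-4, 1.488, 1.488,
])


def _crn_rhs(t: float, y: np.ndarray, g: np.ndarray, stim: float) -> np.ndarray:
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     Nai, Ki, Cai, Caup, Carel) = y
    (gNa, gK1, gto, gKr, gKs, gCaL, gKur_scale, gbNa, gbCa,
     INaK_max, INaCa_max, IpCa_max) = g
    p = _CRN_FIXED
    R, T, F, Cm = p["R"], p["T"], p["F"], p["Cm"]
    RT_F = R * T / F
    exp = math.exp

    ENa = RT_F * math.log(p["Na_o"] / Nai)
    EK = RT_F * math.log(p["K_o"] / Ki)
    ECa = 0.5 * RT_F * math.log(p["Ca_o"] / max(Cai, 1e-12))

    # fast Na+ current (Luo-Rudy formulation)
    INa = Cm * gNa * m ** 3 * h * j * (V - ENa)
    dv = V + 47.13
    a_m = 3.2 if abs(dv) < 1e-10 else 0.32 * dv / (1.0 - exp(-0.1 * dv))
    b_m = 0.08 * exp(-V / 11.0)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + exp((V + 10.66) / -11.1)))
        a_j = 0.0
        b_j = 0.3 * exp(-2.535e-7 * V) / (1.0 + exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * exp((V + 80.0) / -6.8)
        b_h = 3.56 * exp(0.079 * V) + 3.1e5 * exp(0.35 * V)
        a_j = ((-1.2714e5 * exp(0.2444 * V) - 3.474e-5 * exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + exp(0.311 * (V + 79.23))))
        b_j = 0.1212 * exp(-0.01052 * V) / (1.0 + exp(-0.1378 * (V + 40.14)))

    # inward rectifier
    IK1 = Cm * gK1 * (V - EK) / (1.0 + exp(0.07 * (V + 80.0)))

    # transient outward
    KQ10 = p["KQ10"]
    a_oa = 0.65 / (exp(-(V + 10.0) / 8.5) + exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / ((a_oa + b_oa) * KQ10)
    oa_inf = 1.0 / (1.0 + exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + exp(-(V + 1.26) / 7.44))
    tau_oi = 1.0 / ((a_oi + b_oi) * KQ10)
    oi_inf = 1.0 / (1.0 + exp((V + 43.1) / 5.3))
    Ito = Cm * gto * oa ** 3 * oi * (V - EK)

    # ultrarapid delayed rectifier
    gKur = gKur_scale * (0.005 + 0.05 / (1.0 + exp(-(V - 15.0) / 13.0)))
    a_ua = 0.65 / (exp(-(V + 10.0) / 8.5) + exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / ((a_ua + b_ua) * KQ10)
    ua_inf = 1.0 / (1.0 + exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + exp(-(V - 185.0) / 28.0))
    b_ui = exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / ((a_ui + b_ui) * KQ10)
    ui_inf = 1.0 / (1.0 + exp((V - 99.45) / 27.48))
    IKur = Cm * gKur * ua ** 3 * ui * (V - EK)

    # rapid delayed rectifier
    dv = V + 14.1
    a_xr = 0.0015 if abs(dv) < 1e-10 else 0.0003 * dv / (1.0 - exp(-dv / 5.0))
    dv = V - 3.3328
    b_xr = 3.7836118e-4 if abs(dv) < 1e-10 else 7.3898e-5 * dv / (exp(dv / 5.1237) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    xr_inf = 1.0 / (1.0 + exp(-(V + 14.1) / 6.5))
    IKr = Cm * gKr * xr * (V - EK) / (1.0 + exp((V + 15.0) / 22.4))

    # slow delayed rectifier
    dv = V - 19.9
    a_xs = 6.8e-4 if abs(dv) < 1e-10 else 4e-5 * dv / (1.0 - exp(-dv / 17.0))
    b_xs = 3.15e-4 if abs(dv) < 1e-10 else 3.5e-5 * dv / (exp(dv / 9.0) - 1.0)
    tau_xs = 0.5 / (a_xs + b_xs)
    xs_inf = 1.0 / math.sqrt(1.0 + exp(-(V - 19.9) / 12.7))
    IKs = Cm * gKs * xs ** 2 * (V - EK)

    # L-type Ca2+ current
    dv = V + 10.0
    d_inf = 1.0 / (1.0 + exp(-dv / 8.0))
    if abs(dv) < 1e-10:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e = exp(-dv / 6.24)
        tau_d = (1.0 - e) / (0.035 * dv * (1.0 + e))
    f_inf = 1.0 / (1.0 + exp((V + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    tau_fca = 2.0
    ICaL = Cm * gCaL * d * f * fca * (V - 65.0)

    # pumps and exchangers
    sigma = (exp(p["Na_o"] / 67.3) - 1.0) / 7.0
    f_NaK = 1.0 / (1.0 + 0.1245 * exp(-0.1 * V / RT_F) + 0.0365 * sigma * exp(-V / RT_F))
    INaK = (Cm * INaK_max * f_NaK * p["K_o"] / (p["K_o"] + p["Km_K_o"])
            / (1.0 + (p["Km_Na_i"] / Nai) ** 1.5))
    eg = exp(p["gamma"] * V / RT_F)
    eg1 = exp((p["gamma"] - 1.0) * V / RT_F)
    INaCa = (Cm * INaCa_max * (eg * Nai ** 3 * p["Ca_o"] - eg1 * p["Na_o"] ** 3 * Cai)
             / ((p["K_mNa"] ** 3 + p["Na_o"] ** 3) * (p["K_mCa"] + p["Ca_o"])
                * (1.0 + p["K_sat"] * eg1)))
    IbNa = Cm * gbNa * (V - ENa)
    IbCa = Cm * gbCa * (V - ECa)
    IpCa = Cm * IpCa_max * Cai / (0.0005 + Cai)

    # Ca2+ handling (SR release, uptake, transfer)
    Irel = p["K_rel"] * u ** 2 * v * w * (Carel - Cai)
    Fn = 1e3 * (1e-15 * p["V_rel"] * Irel - 1e-15 / (2.0 * F) * (0.5 * ICaL - 0.2 * INaCa))
    u_inf = 1.0 / (1.0 + exp(-(Fn - 3.4175e-13) / 13.67e-16))
    tau_u = 8.0
    v_inf = 1.0 - 1.0 / (1.0 + exp(-(Fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + exp(-(Fn - 3.4175e-13) / 13.67e-16))
    w_inf = 1.0 - 1.0 / (1.0 + exp(-(V - 40.0) / 17.0))
    dv = V - 7.9
    if abs(dv) < 1e-10:
        tau_w = 6.0 / 6.5
    else:
        e = exp(-dv / 5.0)
        tau_w = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)

    Iup = p["I_up_max"] / (1.0 + p["K_up"] / max(Cai, 1e-12))
    Iup_leak = p["I_up_max"] * Caup / p["Ca_up_max"]
    Itr = (Caup - Carel) / p["tau_tr"]

    Ist = -stim * Cm  # inward square pulse, amplitude in pA/pF
    Iion = (INa + IK1 + Ito + IKur + IKr + IKs + IbNa + IbCa + INaK + IpCa
            + INaCa + ICaL)

    FVi = F * p["V_i"]
    dNai = (-3.0 * INaK - (3.0 * INaCa + IbNa + INa)) / FVi
    dKi = (2.0 * INaK - (IK1 + Ito + IKur + IKr + IKs)) / FVi
    B1 = ((2.0 * INaCa - (IpCa + ICaL + IbCa)) / (2.0 * FVi)
          + (p["V_up"] * (Iup_leak - Iup) + Irel * p["V_rel"]) / p["V_i"])
    B2 = (1.0 + p["TRPN_max"] * p["Km_TRPN"] / (Cai + p["Km_TRPN"]) ** 2
          + p["CMDN_max"] * p["Km_CMDN"] / (Cai + p["Km_CMDN"]) ** 2)

    return np.array([
        -(Iion + Ist) / Cm,
        a_m * (1.0 - m) - b_m * m,
        a_h * (1.0 - h) - b_h * h,
        a_j * (1.0 - j) - b_j * j,
        (oa_inf - oa) / tau_oa,
        (oi_inf - oi) / tau_oi,
        (ua_inf - ua) / tau_ua,
        (ui_inf - ui) / tau_ui,
        (xr_inf - xr) / tau_xr,
        (xs_inf - xs) / tau_xs,
        (d_inf - d) / tau_d,
        (f_inf - f) / tau_f,
        (fca_inf - fca) / tau_fca,
        (u_inf - u) / tau_u,
        (v_inf - v) / tau_v,
        (w_inf - w) / tau_w,
        dNai,
        dKi,
        B1 / B2,
        Iup - Iup_leak - Itr * p["V_rel"] / p["V_up"],
        (Itr - Irel) / (1.0 + p["CSQN_max"] * p["Km_CSQN"] / (Carel + p["Km_CSQN"]) ** 2),
    ])


def courtemanche_model() -> CellModel:
    """Courtemanche et al. 1998 human atrial AP model.

    All multipliers at 1.0 reproduce the published parameterization; the
    stimulus amplitude is interpreted per unit capacitance (pA/pF).
    """
    return CellModel(
        name="courtemanche",
        state_dim=21,
        nominal_conductances=dict(_CRN_CONDUCTANCES),
        fixed_parameters=dict(_CRN_FIXED),
        rhs=_crn_rhs,
        initial_state=_CRN_Y0.copy(),
    )


# ---------------------------------------------------------------------------
# two-variable phenomenological pulse model (test fixture)
# ---------------------------------------------------------------------------

TOY_V_REST = -80.0
TOY_K_DEP = 0.25     # mV/ms per unit of drive w
TOY_TAU_V = 12.0     # ms, voltage relaxation
TOY_TAU_W = 120.0    # ms, drive decay

_TOY_CONDUCTANCES = {"g_dep": 1.0, "g_rep": 1.0, "g_decay": 1.0, "g_sens": 1.0}


def _toy_rhs(t: float, y: np.ndarray, g: np.ndarray, stim: float) -> np.ndarray:
    V, w = y
    g_dep, g_rep, g_decay, g_sens = g
    dV = g_dep * TOY_K_DEP * w - g_rep * (V - TOY_V_REST) / TOY_TAU_V
    dw = stim * g_sens - g_decay * w / TOY_TAU_W
    return np.array([dV, dw])


def toy_model() -> CellModel:
    """Linear two-variable pulse model with four pseudo-conductances.

    The stimulus charges a drive variable ``w`` (gain ``g_sens``); ``w``
    decays at rate ``g_decay / tau_w`` and depolarizes the membrane with
    strength ``g_dep``; the membrane relaxes to rest at rate
    ``g_rep / tau_v``.  The whole system is linear, so the pulse has a closed
    form (sums of two exponentials) usable as an independent oracle.  Note
    the voltage depends on ``g_dep`` and ``g_sens`` only through their
    product — a built-in unidentifiable pair for inverse-problem tests.
    """
    return CellModel(
        name="toy",
        state_dim=2,
        nominal_conductances=dict(_TOY_CONDUCTANCES),
        fixed_parameters={
            "v_rest": TOY_V_REST, "k_dep": TOY_K_DEP,
            "tau_v": TOY_TAU_V, "tau_w": TOY_TAU_W,
        },
        rhs=_toy_rhs,
        initial_state=np.array([TOY_V_REST, 0.0]),
    )


def toy_closed_form(
    times: np.ndarray,
    multipliers: Mapping[str, float] | None = None,
    protocol: PacingProtocol | None = None,
) -> np.ndarray:
    """Exact solution of the toy model's first paced cycle (from rest).

    Piecewise-linear ODE with constant coefficients: during the stimulus the
    drive ramps toward ``a g_sens tau_w / g_decay``; afterwards both V and w
    are sums of decaying exponentials.
    """
    multipliers = dict(multipliers or {})
    protocol = protocol or PacingProtocol()
    g_dep = multipliers.get("g_dep", 1.0)
    g_rep = multipliers.get("g_rep", 1.0)
    g_decay = multipliers.get("g_decay", 1.0)
    g_sens = multipliers.get("g_sens", 1.0)
    lam_w = g_decay / TOY_TAU_W
    lam_v = g_rep / TOY_TAU_V
    k = g_dep * TOY_K_DEP
    a = protocol.stimulus_amplitude * g_sens
    s = protocol.stimulus_duration_ms

    def advance(V0, w0, forcing, t):
        # w' = forcing - lam_w w ; V' = k w - lam_v (V - V_rest)
        w_ss = forcing / lam_w
        w = w_ss + (w0 - w_ss) * np.exp(-lam_w * t)
        # particular + homogeneous solution for V
        c_exp = k * (w0 - w_ss) / (lam_v - lam_w)
        V_ss = TOY_V_REST + k * w_ss / lam_v
        c0 = V0 - V_ss - c_exp
        V = V_ss + c_exp * np.exp(-lam_w * t) + c0 * np.exp(-lam_v * t)
        return V, w

    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    on = times <= s
    V_on, _ = advance(TOY_V_REST, 0.0, a, times[on])
    out[on] = V_on
    V_s, w_s = advance(TOY_V_REST, 0.0, a, np.array([s]))
    V_off, _ = advance(V_s[0], w_s[0], 0.0, times[~on] - s)
    out[~on] = V_off
    return out
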