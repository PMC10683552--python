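"""Modified Morris-Lecar dynamics of the escape circuit and its integrator.

Each cell follows the current-balance equation

    C dv/dt = -ICa - IK - IL - IKCa - Isyn + Iapp(t)

with an instantaneous calcium activation m_inf(v), a delayed-rectifier K gate
n with voltage-dependent time constant, and a calcium pool [Ca] driving the
Ca-gated K current through [Ca]/([Ca]+k1).  Presynaptic cells (E, GA, GL)
carry a first-order activated-channel fraction s; the M-cell carries a slow
retrograde gain gI that scales every synaptic input it receives and decreases
with its own calcium level.

The functions in this module are the readable reference implementation used
for single steps and unit tests; long simulations are dispatched to the
compiled kernel in :mod:`mcellnet._kernel`, which integrates the identical
equations with a fixed-step classical Runge-Kutta scheme (default step
0.01 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .params import CELLS, STATE_VARS, CellParams, NetworkConfig, NetworkState, SynapseKinetics

__all__ = [
    "GatingValues",
    "IonicCurrents",
    "Trace",
    "IntegrationError",
    "gating_functions",
    "ionic_currents",
    "synaptic_currents",
    "derivatives",
    "rk4_step",
    "initial_state",
    "simulate",
    "pack_config",
]

DEFAULT_DT = 0.01  # ms
DEFAULT_SETTLE_MS = 5000.0
DIVERGENCE_MV = 500.0

_IDX = {name: i for i, name in enumerate(STATE_VARS)}


class IntegrationError(RuntimeError):
    """Raised when the state diverges or becomes non-finite during a run."""

    def __init__(self, message: str, t_ms: float):
        super().__init__(f"{message} at t={t_ms:.3f} ms")
        self.t_ms = t_ms


class GatingValues(NamedTuple):
    m_inf: float
    n_inf: float
    tau_n: float
    s_inf: float | None


class IonicCurrents(NamedTuple):
    IK: float
    ICa: float
    IKCa: float
    IL: float


def gating_functions(
    v: float, cell: CellParams, kin: SynapseKinetics | None = None
) -> GatingValues:
    """Steady-state gates and the n time constant at membrane potential ``v``.

    Returns (m_inf, n_inf, tau_n, s_inf); s_inf is None when no synapse
    kinetics are supplied.
    """
    v = float(v)
    if not np.isfinite(v):
        raise ValueError("membrane potential must be finite")
    m_inf = 0.5 * (1.0 + np.tanh((v - cell.v1) / cell.v2))
    n_inf = 0.5 * (1.0 + np.tanh((v - cell.v3) / cell.v4))
    tau_n = 1.0 / np.cosh((v - cell.v3) / (2.0 * cell.v4))
    s_inf = None
    if kin is not None:
        s_inf = 1.0 / (1.0 + np.exp(-(v - kin.theta_s) / kin.sigma_s))
    return GatingValues(m_inf, n_inf, tau_n, s_inf)


def ionic_currents(v: float, n: float, Ca: float, cell: CellParams) -> IonicCurrents:
    """Intrinsic membrane currents (outward positive by driving-force sign)."""
    if Ca < 0:
        raise ValueError(f"calcium concentration must be >= 0, got {Ca}")
    m_inf = 0.5 * (1.0 + np.tanh((v - cell.v1) / cell.v2))
    IK = cell.gK * n * (v - cell.vK)
    ICa = cell.gCa * m_inf * (v - cell.vCa)
    IKCa = cell.gKCa * (Ca / (Ca + cell.k1)) * (v - cell.vK)
    IL = cell.gL * (v - cell.vL)
    return IonicCurrents(IK, ICa, IKCa, IL)


def synaptic_currents(state: NetworkState | np.ndarray, cfg: NetworkConfig) -> dict:
    """Total synaptic current onto each cell, keyed by cell name.

    The E cell receives no synapses.  GA receives E.  GL receives E (scaled
    by the dopaminergic gain 1+D1_GL) and GA.  M receives E (scaled by
    gI*(1+D1_M)), GA and GL (scaled by gI), plus the constant contralateral
    M drive (scaled by gI).
    """
    y = state.to_array() if isinstance(state, NetworkState) else np.asarray(state, float)
    con, mod = cfg.connections, cfg.modulation
    vGA, vGL, vM = y[_IDX["vGA"]], y[_IDX["vGL"]], y[_IDX["vM"]]
    sE, sGA, sGL = y[_IDX["sE"]], y[_IDX["sGA"]], y[_IDX["sGL"]]
    gI = y[_IDX["gI"]]
    isyn_GA = con.gE_GA * (vGA - con.vE_GA) * sE
    isyn_GL = (
        con.gE_GL * (1.0 + mod.D1_GL) * (vGL - con.vE_GL) * sE
        + con.gGA_GL * (vGL - con.vGA_GL) * sGA
    )
    isyn_M = (
        con.gE_M * gI * (1.0 + mod.D1_M) * (vM - con.vE_M) * sE
        + gI * (con.gGA_M * sGA + con.gGL_M * sGL) * (vM - con.vG_M)
        + con.gM_M * gI * (vM - con.vM_M) * con.sM_const
    )
    return {"E": 0.0, "GA": isyn_GA, "GL": isyn_GL, "M": isyn_M}


def derivatives(
    state: NetworkState | np.ndarray,
    cfg: NetworkConfig,
    t: float = 0.0,
    stim: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full state vector.

    ``stim`` is the instantaneous stimulus current WE*I(t) added to the
    E cell's baseline drive IE0.
    """
    y = state.to_array() if isinstance(state, NetworkState) else np.asarray(state, float)
    dy = np.empty_like(y)
    isyn = synaptic_currents(y, cfg)
    iapp = {"E": cfg.IE0 + stim, "GA": cfg.IGA0, "GL": cfg.IGL0, "M": cfg.IM0}
    for c, name in enumerate(CELLS):
        cell = cfg.cell(name)
        v, n, Ca = y[c], y[4 + c], y[8 + c]
        IK, ICa, IKCa, IL = ionic_currents(v, n, Ca, cell)
        dy[c] = (-ICa - IK - IL - IKCa - isyn[name] + iapp[name]) / cell.C
        g = gating_functions(v, cell)
        dy[4 + c] = cell.phi * (g.n_inf - n) / g.tau_n
        dy[8 + c] = cell.eps * (-cell.mu * ICa - cell.kCa * Ca)
    for j, name in enumerate(("E", "GA", "GL")):
        kin = cfg.kinetics(name)
        v, s = y[j], y[12 + j]
        s_inf = 1.0 / (1.0 + np.exp(-(v - kin.theta_s) / kin.sigma_s))
        dy[12 + j] = kin.alpha * s_inf * (1.0 - s) - kin.beta * s
    mod = cfg.modulation
    CaM, gI = y[_IDX["CaM"]], y[_IDX["gI"]]
    drive = mod.gI_max / (CaM + mod.k2)
    if mod.gI_law == "relaxation":
        dy[_IDX["gI"]] = (drive - gI) / mod.rho
    else:
        dy[_IDX["gI"]] = drive - gI / mod.rho
    return dy


def rk4_step(
    state: NetworkState | np.ndarray,
    cfg: NetworkConfig,
    t: float,
    dt: float,
    stim: float | Callable[[float], float] = 0.0,
) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of the full network."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y = state.to_array() if isinstance(state, NetworkState) else np.asarray(state, float)
    s = stim if callable(stim) else (lambda _t: stim)
    k1 = derivatives(y, cfg, t, s(t))
    k2 = derivatives(y + 0.5 * dt * k1, cfg, t + 0.5 * dt, s(t + 0.5 * dt))
    k3 = derivatives(y + 0.5 * dt * k2, cfg, t + 0.5 * dt, s(t + 0.5 * dt))
    k4 = derivatives(y + dt * k3, cfg, t + dt, s(t + dt))
    out = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite state after RK4 step", t + dt)
    return out


def initial_state(cfg: NetworkConfig) -> NetworkState:
    """Canonical start: every cell at its leak reversal with the K gate at
    steady state, empty calcium pools, silent synapses, and gI = 1."""
    values = {}
    for c, name in enumerate(CELLS):
        cell = cfg.cell(name)
        g = gating_functions(cell.vL, cell)
        values[STATE_VARS[c]] = cell.vL
        values[STATE_VARS[4 + c]] = g.n_inf
        values[STATE_VARS[8 + c]] = 0.0
    values.update(sE=0.0, sGA=0.0, sGL=0.0, gI=1.0)
    return NetworkState(**values)


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

_CELL_COLS = (
    "C", "gK", "gL", "gCa", "gKCa", "vK", "vL", "vCa", "k1",
    "v1", "v2", "v3", "v4", "phi", "eps", "mu", "kCa",
)
_KIN_COLS = ("alpha", "beta", "theta_s", "sigma_s")
_CON_COLS = (
    "gE_GA", "vE_GA", "gE_GL", "vE_GL", "gGA_GL", "vGA_GL", "gE_M", "vE_M",
    "gGA_M", "gGL_M", "vG_M", "gM_M", "vM_M", "sM_const",
)


def pack_config(cfg: NetworkConfig):
    """Flatten a NetworkConfig into the dense arrays the kernel consumes."""
    cp = np.array(
        [[getattr(cfg.cell(c), k) for k in _CELL_COLS] for c in CELLS], dtype=np.float64
    )
    kin = np.array(
        [[getattr(cfg.kinetics(c), k) for k in _KIN_COLS] for c in ("E", "GA", "GL")],
        dtype=np.float64,
    )
    con = np.array([getattr(cfg.connections, k) for k in _CON_COLS], dtype=np.float64)
    mod = np.array(
        [
            cfg.modulation.D1_M,
            cfg.modulation.D1_GL,
            cfg.modulation.gI_max,
            cfg.modulation.k2,
            cfg.modulation.rho,
            0.0 if cfg.modulation.gI_law == "relaxation" else 1.0,
        ],
        dtype=np.float64,
    )
    drives = np.array([cfg.IE0, cfg.IGA0, cfg.IGL0, cfg.IM0], dtype=np.float64)
    return cp, kin, con, mod, drives


# ---------------------------------------------------------------------------
# trace container and the high-level simulate() entry point
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Uniformly sampled trajectory of all 16 state variables.

    ``time`` is in ms from the start of integration (settling included);
    ``protocol_start_ms`` marks where the stimulus protocol begins.
    """

    time: np.ndarray
    data: np.ndarray  # shape (n_samples, 16), columns in STATE_VARS order
    dt: float
    protocol_start_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.data = np.asarray(self.data, float)
        if self.data.shape != (self.time.size, len(STATE_VARS)):
            raise ValueError("trace data shape does not match time grid")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time grid must be strictly increasing")

    def var(self, name: str) -> np.ndarray:
        return self.data[:, _IDX[name]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(STATE_VARS))
        df.insert(0, "t_ms", self.time)
        return df

    @property
    def final_state(self) -> NetworkState:
        return NetworkState.from_array(self.data[-1])


def _pulse_onsets(protocol, settle_ms: float) -> np.ndarray:
    return settle_ms + protocol.isi_ms * np.arange(protocol.n_pulses, dtype=np.float64)


def simulate(
    cfg: NetworkConfig,
    protocol=None,
    we: float | None = None,
    dt: float = DEFAULT_DT,
    settle_ms: float = DEFAULT_SETTLE_MS,
    record_stride: int = 10,
) -> Trace:
    """Integrate the network: a stimulus-free settling period from the
    canonical initial state, then the stimulus protocol at strength ``we``.

    ``protocol`` may be None (settling only).  If ``we`` is None the
    protocol's grid must contain exactly one strength.
    """
    from ._kernel import run_batch

    if dt <= 0 or dt > 0.05:
        raise ValueError("dt must lie in (0, 0.05] ms for stability")
    if protocol is None:
        onsets = np.empty(0, dtype=np.float64)
        pulse_ms = 0.0
        total_ms = settle_ms
        we_val = 0.0
    else:
        if we is None:
            if len(protocol.WE_grid) != 1:
                raise ValueError(
                    "simulate() needs a single stimulus strength; pass we= or a "
                    "one-point WE_grid"
                )
            we_val = float(protocol.WE_grid[0])
        else:
            we_val = float(we)
        onsets = _pulse_onsets(protocol, settle_ms)
        pulse_ms = float(protocol.pulse_ms)
        total_ms = settle_ms + protocol.n_pulses * protocol.isi_ms
    n_steps = int(round(total_ms / dt))
    y0 = initial_state(cfg).to_array()[None, :]
    yf, rec, minmax, status = run_batch(
        y0, cfg, np.array([we_val]), onsets, pulse_ms, 0.0, dt, n_steps,
        record_stride, np.arange(len(STATE_VARS)),
    )
    if status[0] >= 0:
        raise IntegrationError("membrane potential diverged", status[0] * dt)
    time = np.arange(rec.shape[1]) * (record_stride * dt)
    return Trace(
        time=time,
        data=rec[0],
        dt=record_stride * dt,
        protocol_start_ms=settle_ms,
        meta={
            "config": cfg.model_dump(),
            "dt_integration": dt,
            "we": we_val,
            "settle_ms": settle_ms,
            "protocol": None if protocol is None else protocol.model_dump(),
        },
    )
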