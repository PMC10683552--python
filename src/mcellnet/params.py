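"""Parameterization of the four-neuron Mauthner-cell escape circuit.

The network contains one excitatory sensory-relay neuron (E), one GABAergic
interneuron (GA), one glycinergic interneuron (GL) and one Mauthner cell (M).
Each cell is a modified Morris-Lecar oscillator (voltage, a delayed-rectifier
K gate, and an intracellular calcium pool feeding a Ca-gated K current).
E excites all other cells, GA inhibits GL and M, GL inhibits M only, and the
contralateral M-cell contributes a fixed small synaptic drive.

All voltages are in mV, time in ms; conductances, currents and calcium use
the dimensionless Morris-Lecar convention.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "CellParams",
    "SynapseKinetics",
    "ConnectionParams",
    "ModulationParams",
    "NetworkConfig",
    "NetworkState",
    "CELLS",
    "STATE_VARS",
    "dominant_preset",
    "subordinate_preset",
    "preset",
]

#: order of the cells everywhere state or parameters are stacked
CELLS = ("E", "GA", "GL", "M")

#: flat state-vector layout: 4 voltages, 4 K-gates, 4 calcium pools,
#: 3 synaptic activation fractions (E, GA, GL), and the M-cell retrograde gain
STATE_VARS = (
    "vE", "vGA", "vGL", "vM",
    "nE", "nGA", "nGL", "nM",
    "CaE", "CaGA", "CaGL", "CaM",
    "sE", "sGA", "sGL",
    "gI",
)


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CellParams(_Frozen):
    """Single-cell Morris-Lecar parameters.

    ``C`` membrane capacitance; ``gK/gL/gCa/gKCa`` maximal conductances of the
    delayed-rectifier K, leak, Ca and Ca-gated K currents; ``vK/vL/vCa``
    reversal potentials (mV); ``k1`` calcium half-saturation of the Ca-gated K
    current; ``v1..v4`` shape parameters of the instantaneous Ca-activation
    (m) and K-gate (n) sigmoids (mV); ``phi`` n-rate scale; ``eps/mu/kCa``
    calcium influx/decay constants.
    """

    C: float = 20.0
    gK: float = 8.0
    gL: float = 2.0
    gCa: float = 4.0
    gKCa: float = 0.25
    vK: float = -84.0
    vL: float = -60.0
    vCa: float = 120.0
    k1: float = 10.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 12.0
    v4: float = 17.0
    phi: float = 0.23
    eps: float = 0.005
    mu: float = 0.19
    kCa: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "CellParams":
        for name in ("gK", "gL", "gCa", "gKCa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.v2 == 0 or self.v4 == 0:
            raise ValueError("v2 and v4 must be nonzero")
        if self.eps <= 0 or self.kCa <= 0:
            raise ValueError("eps and kCa must be > 0")
        return self


class SynapseKinetics(_Frozen):
    """First-order transmitter-release kinetics of a presynaptic cell.

    ``alpha`` is the voltage-gated activation rate, ``beta`` the decay rate of
    the activated-channel fraction s; ``theta_s``/``sigma_s`` set the midpoint
    and steepness (mV) of the steady-state activation sigmoid.
    """

    alpha: float
    beta: float
    theta_s: float = 0.0
    sigma_s: float = 4.0

    @model_validator(mode="after")
    def _check(self) -> "SynapseKinetics":
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.sigma_s == 0:
            raise ValueError("sigma_s must be nonzero")
        return self


class ConnectionParams(_Frozen):
    """Maximal synaptic conductances and reversal potentials per pathway.

    ``sM_const`` is the fixed activation fraction standing in for the
    contralateral Mauthner cell (not simulated explicitly).
    """

    gE_GA: float = 0.3
    vE_GA: float = 40.0
    gE_GL: float = 0.3
    vE_GL: float = 40.0
    gGA_GL: float = 0.2
    vGA_GL: float = -50.0
    gE_M: float = 0.24
    vE_M: float = 40.0
    gGA_M: float = 0.4
    gGL_M: float = 0.2
    vG_M: float = -50.0
    gM_M: float = 0.1
    vM_M: float = -50.0
    sM_const: float = 0.029

    @model_validator(mode="after")
    def _check(self) -> "ConnectionParams":
        for name in ("gE_GA", "gE_GL", "gGA_GL", "gE_M", "gGA_M", "gGL_M", "gM_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.sM_const <= 1.0:
            raise ValueError("sM_const must lie in [0, 1]")
        return self


class ModulationParams(_Frozen):
    """Dopaminergic and retrograde-calcium modulation of synaptic gain.

    ``D1_M`` / ``D1_GL`` are dimensionless D1-receptor gains multiplying the
    excitatory input to the M-cell and glycinergic cell as (1 + D1).
    ``gI_max, k2, rho`` govern the slow retrograde gain gI on all presynaptic
    inputs to the M-cell, which decreases with M-cell calcium.

    ``gI_law`` selects the gI dynamics: ``"relaxation"`` relaxes gI toward
    gI_max/([Ca]+k2) with time constant rho (default); ``"linear_decay"`` uses
    dgI/dt = gI_max/([Ca]+k2) - gI/rho.
    """

    D1_M: float = 0.015
    D1_GL: float = 0.65
    gI_max: float = 15.0
    k2: float = 10.0
    rho: float = 10000.0
    gI_law: Literal["relaxation", "linear_decay"] = "relaxation"

    @model_validator(mode="after")
    def _check(self) -> "ModulationParams":
        if self.D1_M < 0 or self.D1_GL < 0:
            raise ValueError("D1 gains must be >= 0")
        if self.rho <= 0 or self.k2 <= 0:
            raise ValueError("rho and k2 must be > 0")
        return self


def _default_cell(name: str) -> CellParams:
    if name == "M":
        return CellParams(C=1.0, gKCa=0.3, kCa=0.9)
    return CellParams()


def _default_kin(name: str) -> SynapseKinetics:
    if name == "E":
        return SynapseKinetics(alpha=15.0, beta=0.1)
    if name == "GA":
        return SynapseKinetics(alpha=4.0, beta=0.08)
    return SynapseKinetics(alpha=8.0, beta=0.08)  # GL


class NetworkConfig(_Frozen):
    """Complete parameterization of the four-cell circuit."""

    E: CellParams = None  # type: ignore[assignment]
    GA: CellParams = None  # type: ignore[assignment]
    GL: CellParams = None  # type: ignore[assignment]
    M: CellParams = None  # type: ignore[assignment]
    kin_E: SynapseKinetics = None  # type: ignore[assignment]
    kin_GA: SynapseKinetics = None  # type: ignore[assignment]
    kin_GL: SynapseKinetics = None  # type: ignore[assignment]
    connections: ConnectionParams = ConnectionParams()
    modulation: ModulationParams = ModulationParams()
    IE0: float = 43.9
    IGA0: float = 36.0
    IGL0: float = 36.0
    IM0: float = 19.5
    status: Literal["dominant", "subordinate", "custom"] = "custom"

    @model_validator(mode="before")
    @classmethod
    def _fill_defaults(cls, data):
        if isinstance(data, dict):
            for cell in CELLS:
                if data.get(cell) is None:
                    data[cell] = _default_cell(cell)
            for cell in ("E", "GA", "GL"):
                key = f"kin_{cell}"
                if data.get(key) is None:
                    data[key] = _default_kin(cell)
        return data

    @model_validator(mode="after")
    def _check(self) -> "NetworkConfig":
        for name in ("IE0", "IGA0", "IGL0", "IM0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        return self

    def cell(self, name: str) -> CellParams:
        return getattr(self, name)

    def kinetics(self, name: str) -> SynapseKinetics:
        return getattr(self, f"kin_{name}")

    def with_overrides(self, **dotted: float) -> "NetworkConfig":
        """Return a copy with dotted-path overrides, e.g. ``modulation.D1_GL=0``."""
        data = self.model_dump()
        for path, value in dotted.items():
            node = data
            *parents, leaf = path.split(".")
            for p in parents:
                node = node[p]
            if leaf not in node:
                raise KeyError(f"unknown parameter {path!r}")
            node[leaf] = value
        return NetworkConfig.model_validate(data)


class NetworkState(_Frozen):
    """Dynamical state of the circuit (one scalar per state variable)."""

    vE: float
    vGA: float
    vGL: float
    vM: float
    nE: float
    nGA: float
    nGL: float
    nM: float
    CaE: float
    CaGA: float
    CaGL: float
    CaM: float
    sE: float
    sGA: float
    sGL: float
    gI: float

    @model_validator(mode="after")
    def _check(self) -> "NetworkState":
        for name in ("nE", "nGA", "nGL", "nM", "sE", "sGA", "sGL"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} outside [0, 1]")
        for name in ("CaE", "CaGA", "CaGL", "CaM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gI < 0:
            raise ValueError("gI must be >= 0")
        return self

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_VARS], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_VARS),):
            raise ValueError(f"state vector must have shape ({len(STATE_VARS)},)")
        return cls(**dict(zip(STATE_VARS, y.tolist())))


def dominant_preset() -> NetworkConfig:
    """Dominant-like circuit: strong dopaminergic drive onto the glycinergic
    cell (D1_GL=0.65) and weak GABA->glycinergic inhibition (gGA_GL=0.2)."""
    return NetworkConfig(
        connections=ConnectionParams(gGA_GL=0.2),
        modulation=ModulationParams(D1_GL=0.65),
        status="dominant",
    )


def subordinate_preset() -> NetworkConfig:
    """Subordinate-like circuit: weak dopaminergic drive onto the glycinergic
    cell (D1_GL=0.25) and strong GABA->glycinergic inhibition (gGA_GL=0.4)."""
    return NetworkConfig(
        connections=ConnectionParams(gGA_GL=0.4),
        modulation=ModulationParams(D1_GL=0.25),
        status="subordinate",
    )


_PRESETS = {"dominant": dominant_preset, "subordinate": subordinate_preset}


def preset(name: str) -> NetworkConfig:
    """Return a named status preset ('dominant' or 'subordinate')."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}") from None
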