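"""Compiled fixed-step RK4 integration kernel.

The equations here transcribe :func:`mcellnet.model.derivatives` into a form
numba can compile; the two code paths are held equal by the test suite.
State layout (16): v[E,GA,GL,M], n[E,GA,GL,M], Ca[E,GA,GL,M], s[E,GA,GL], gI.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import DIVERGENCE_MV, pack_config

__all__ = ["run_batch"]


@njit(cache=True, error_model="numpy")
def _stim_at(tau, onsets, pulse_ms):
    """Unit square-pulse train: 1.0 inside any [onset, onset+pulse_ms)."""
    for i in range(onsets.shape[0]):
        d = tau - onsets[i]
        if 0.0 <= d < pulse_ms:
            return 1.0
    return 0.0


@njit(cache=True, error_model="numpy")
def _deriv(y, dy, cp, kin, con, mod, drives, stim):
    sE = y[12]
    sGA = y[13]
    sGL = y[14]
    gI = y[15]
    D1_M = mod[0]
    D1_GL = mod[1]

    # synaptic currents per cell (E receives none)
    isyn0 = 0.0
    isyn1 = con[0] * (y[1] - con[1]) * sE
    isyn2 = (
        con[2] * (1.0 + D1_GL) * (y[2] - con[3]) * sE
        + con[4] * (y[2] - con[5]) * sGA
    )
    isyn3 = (
        con[6] * gI * (1.0 + D1_M) * (y[3] - con[7]) * sE
        + gI * (con[8] * sGA + con[9] * sGL) * (y[3] - con[10])
        + con[11] * gI * (y[3] - con[12]) * con[13]
    )

    for c in range(4):
        v = y[c]
        n = y[4 + c]
        Ca = y[8 + c]
        C = cp[c, 0]
        gK = cp[c, 1]
        gL = cp[c, 2]
        gCa = cp[c, 3]
        gKCa = cp[c, 4]
        vK = cp[c, 5]
        vL = cp[c, 6]
        vCa = cp[c, 7]
        k1 = cp[c, 8]
        v1 = cp[c, 9]
        v2 = cp[c, 10]
        v3 = cp[c, 11]
        v4 = cp[c, 12]
        phi = cp[c, 13]
        eps = cp[c, 14]
        mu = cp[c, 15]
        kCa = cp[c, 16]

        m_inf = 0.5 * (1.0 + math.tanh((v - v1) / v2))
        IK = gK * n * (v - vK)
        ICa = gCa * m_inf * (v - vCa)
        IKCa = gKCa * (Ca / (Ca + k1)) * (v - vK)
        IL = gL * (v - vL)
        if c == 0:
            isyn = isyn0
            iapp = drives[0] + stim
        elif c == 1:
            isyn = isyn1
            iapp = drives[1]
        elif c == 2:
            isyn = isyn2
            iapp = drives[2]
        else:
            isyn = isyn3
            iapp = drives[3]
        dy[c] = (-ICa - IK - IL - IKCa - isyn + iapp) / C
        n_inf = 0.5 * (1.0 + math.tanh((v - v3) / v4))
        tau_n = 1.0 / math.cosh((v - v3) / (2.0 * v4))
        dy[4 + c] = phi * (n_inf - n) / tau_n
        dy[8 + c] = eps * (-mu * ICa - kCa * Ca)

    for j in range(3):
        v = y[j]
        s = y[12 + j]
        s_inf = 1.0 / (1.0 + math.exp(-(v - kin[j, 2]) / kin[j, 3]))
        dy[12 + j] = kin[j, 0] * s_inf * (1.0 - s) - kin[j, 1] * s

    drive = mod[2] / (y[11] + mod[3])
    if mod[5] == 0.0:
        dy[15] = (drive - gI) / mod[4]
    else:
        dy[15] = drive - gI / mod[4]


@njit(cache=True, error_model="numpy")
def _integrate(
    y0, cp, kin, con, mod, drives, WE, onsets, pulse_ms,
    t0, dt, n_steps, record_stride, rec_idx,
):
    B = y0.shape[0]
    n_rec = n_steps // record_stride + 1
    R = rec_idx.shape[0]
    out = np.empty((B, n_rec, R), dtype=np.float64)
    yf = np.empty_like(y0)
    # per run: min over n/s/Ca/gI and max over n/s, for bound checks
    minmax = np.empty((B, 6), dtype=np.float64)
    status = np.full(B, -1, dtype=np.int64)

    y = np.empty(16, dtype=np.float64)
    yt = np.empty(16, dtype=np.float64)
    k1 = np.empty(16, dtype=np.float64)
    k2 = np.empty(16, dtype=np.float64)
    k3 = np.empty(16, dtype=np.float64)
    k4 = np.empty(16, dtype=np.float64)

    for b in range(B):
        for i in range(16):
            y[i] = y0[b, i]
        n_min = 1.0e300
        n_max = -1.0e300
        s_min = 1.0e300
        s_max = -1.0e300
        ca_min = 1.0e300
        gi_min = 1.0e300
        for r in range(R):
            out[b, 0, r] = y[rec_idx[r]]
        rec = 1
        for step in range(n_steps):
            t = t0 + step * dt
            w = WE[b]
            st1 = w * _stim_at(t, onsets, pulse_ms)
            st2 = w * _stim_at(t + 0.5 * dt, onsets, pulse_ms)
            st3 = w * _stim_at(t + dt, onsets, pulse_ms)
            _deriv(y, k1, cp, kin, con, mod, drives, st1)
            for i in range(16):
                yt[i] = y[i] + 0.5 * dt * k1[i]
            _deriv(yt, k2, cp, kin, con, mod, drives, st2)
            for i in range(16):
                yt[i] = y[i] + 0.5 * dt * k2[i]
            _deriv(yt, k3, cp, kin, con, mod, drives, st2)
            for i in range(16):
                yt[i] = y[i] + dt * k3[i]
            _deriv(yt, k4, cp, kin, con, mod, drives, st3)
            for i in range(16):
                y[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

            bad = False
            for c in range(4):
                if not (-DIVERGENCE_MV <= y[c] <= DIVERGENCE_MV):
                    bad = True
                nv = y[4 + c]
                if nv < n_min:
                    n_min = nv
                if nv > n_max:
                    n_max = nv
                cv = y[8 + c]
                if cv < ca_min:
                    ca_min = cv
            for j in range(3):
                sv = y[12 + j]
                if sv < s_min:
                    s_min = sv
                if sv > s_max:
                    s_max = sv
            if y[15] < gi_min:
                gi_min = y[15]
            if bad:
                status[b] = step
                break
            if (step + 1) % record_stride == 0:
                for r in range(R):
                    out[b, rec, r] = y[rec_idx[r]]
                rec += 1
        for i in range(16):
            yf[b, i] = y[i]
        minmax[b, 0] = n_min
        minmax[b, 1] = n_max
        minmax[b, 2] = s_min
        minmax[b, 3] = s_max
        minmax[b, 4] = ca_min
        minmax[b, 5] = gi_min
    return yf, out, minmax, status


def run_batch(
    y0: np.ndarray,
    cfg,
    WE: np.ndarray,
    onsets: np.ndarray,
    pulse_ms: float,
    t0: float,
    dt: float,
    n_steps: int,
    record_stride: int,
    rec_idx: np.ndarray,
):
    """Integrate a batch of runs sharing one config but differing in stimulus
    strength.  ``y0`` has shape (B, 16); ``WE`` shape (B,).

    Returns (final states (B,16), recorded series (B, n_rec, len(rec_idx)),
    bound extrema (B, 6: min n, max n, min s, max s, min Ca, min gI),
    status (B,) with -1 for success or the diverging step index).
    """
    cp, kin, con, mod, drives = pack_config(cfg)
    y0 = np.ascontiguousarray(y0, dtype=np.float64)
    if y0.shape[0] == 1 and WE.shape[0] > 1:
        y0 = np.repeat(y0, WE.shape[0], axis=0)
    return _integrate(
        y0, cp, kin, con, mod, drives,
        np.ascontiguousarray(WE, dtype=np.float64),
        np.ascontiguousarray(onsets, dtype=np.float64),
        float(pulse_ms), float(t0), float(dt), int(n_steps),
        int(record_stride), np.ascontiguousarray(rec_idx, dtype=np.int64),
    )
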