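"""Compiled fixed-step RK4 integrator for the four-unit network.

Parameters are packed into flat arrays so the hot loop is free of Python
objects.  Column layout of the per-unit parameter matrix ``P`` (shape 4x14)
matches ``pack_params`` below.  The kernel is the production integrator;
its output is cross-checked in the tests against both the plain-numpy
right-hand side and an adaptive scipy solver.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import NetworkConfig, UnitParams

# column indices into the packed parameter matrix
_C, _GL, _EL, _GNAP, _ENA, _VM, _KM, _VH, _KH, _TAUMAX, _VTAU, _KTAU, _VMIN, _VMAX = range(14)


def pack_params(net: NetworkConfig) -> np.ndarray:
    P = np.empty((4, 14))
    for i, p in enumerate(net.units):
        P[i] = (
            p.C, p.g_L, p.E_L, p.g_NaP, p.E_Na,
            p.V_mNaP, p.k_mNaP, p.V_hNaP, p.k_hNaP,
            p.tau_NaP_max, p.V_tauNaP, p.k_tauNaP, p.V_min, p.V_max,
        )
    return P


@njit(cache=True)
def _deriv(V, h, d, b, P, E_ex, E_inh, dV, dh):
    # firing rates
    f = np.empty(4)
    for j in range(4):
        x = (V[j] - P[j, _VMIN]) / (P[j, _VMAX] - P[j, _VMIN])
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        f[j] = x
    for i in range(4):
        m = 1.0 / (1.0 + np.exp((V[i] - P[i, _VM]) / P[i, _KM]))
        hinf = 1.0 / (1.0 + np.exp((V[i] - P[i, _VH]) / P[i, _KH]))
        tau = P[i, _TAUMAX] / np.cosh((V[i] - P[i, _VTAU]) / P[i, _KTAU])
        I_L = P[i, _GL] * (V[i] - P[i, _EL])
        I_NaP = P[i, _GNAP] * m * h[i] * (V[i] - P[i, _ENA])
        s = d[i] * (V[i] - E_ex)
        acc = 0.0
        for j in range(4):
            acc += b[j, i] * f[j]
        s += acc * (V[i] - E_inh)
        dV[i] = -(I_L + I_NaP + s) / P[i, _C]
        dh[i] = (hinf - h[i]) / tau


@njit(cache=True)
def rk4_integrate(V0, h0, d, b, P, E_ex, E_inh, dt, n_steps, record_every):
    """Integrate n_steps of size dt, recording every record_every steps.

    Returns (V_samples, h_samples) of shape (n_samples, 4) including the
    initial state as sample 0.
    """
    n_samples = n_steps // record_every + 1
    Vs = np.empty((n_samples, 4))
    hs = np.empty((n_samples, 4))
    V = V0.copy()
    h = h0.copy()
    Vs[0] = V
    hs[0] = h

    k1V = np.empty(4); k1h = np.empty(4)
    k2V = np.empty(4); k2h = np.empty(4)
    k3V = np.empty(4); k3h = np.empty(4)
    k4V = np.empty(4); k4h = np.empty(4)
    Vt = np.empty(4); ht = np.empty(4)

    idx = 1
    for step in range(1, n_steps + 1):
        _deriv(V, h, d, b, P, E_ex, E_inh, k1V, k1h)
        for i in range(4):
            Vt[i] = V[i] + 0.5 * dt * k1V[i]
            ht[i] = h[i] + 0.5 * dt * k1h[i]
        _deriv(Vt, ht, d, b, P, E_ex, E_inh, k2V, k2h)
        for i in range(4):
            Vt[i] = V[i] + 0.5 * dt * k2V[i]
            ht[i] = h[i] + 0.5 * dt * k2h[i]
        _deriv(Vt, ht, d, b, P, E_ex, E_inh, k3V, k3h)
        for i in range(4):
            Vt[i] = V[i] + dt * k3V[i]
            ht[i] = h[i] + dt * k3h[i]
        _deriv(Vt, ht, d, b, P, E_ex, E_inh, k4V, k4h)
        for i in range(4):
            V[i] += dt / 6.0 * (k1V[i] + 2.0 * k2V[i] + 2.0 * k3V[i] + k4V[i])
            h[i] += dt / 6.0 * (k1h[i] + 2.0 * k2h[i] + 2.0 * k3h[i] + k4h[i])
        if step % record_every == 0:
            Vs[idx] = V
            hs[idx] = h
            idx += 1
    return Vs, hs
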