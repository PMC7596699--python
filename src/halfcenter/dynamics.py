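"""Right-hand side of the CPG network ODEs, as plain numpy functions.

Each unit obeys the current balance

    C dV/dt = -I_L - I_NaP - I_syn,

with leak current I_L = g_L (V - E_L), persistent sodium current
I_NaP = g_NaP * m_inf(V) * h * (V - E_Na) (instantaneous activation, slow
inactivation gate h), and synaptic current

    I_syn_i = d_i (V_i - E_ex) + sum_j b_ji f(V_j) (V_i - E_inh),

where d_i is the excitatory drive conductance and f is the piecewise-linear
normalized firing rate.  The inactivation gate relaxes as

    dh/dt = (h_inf(V) - h) / tau_h(V),   tau_h = tau_max / cosh((V - V_tau)/k_tau).

These reference implementations are deliberately direct transcriptions of
the equations; the integrator uses a compiled kernel (see ``_kernel``) that
is cross-checked against this module in the test suite.
"""

from __future__ import annotations

import numpy as np

from .params import CurrentBreakdown, DriveConfig, NetworkConfig, NetworkState, UnitParams

__all__ = [
    "m_inf",
    "h_inf",
    "tau_h",
    "rate",
    "synaptic_current",
    "derivatives",
]


def m_inf(V, params: UnitParams):
    """Steady-state persistent-Na activation; rising sigmoid in V."""
    return 1.0 / (1.0 + np.exp((V - params.V_mNaP) / params.k_mNaP))


def h_inf(V, params: UnitParams):
    """Steady-state persistent-Na inactivation; falling sigmoid in V."""
    return 1.0 / (1.0 + np.exp((V - params.V_hNaP) / params.k_hNaP))


def tau_h(V, params: UnitParams):
    """Voltage-dependent inactivation time constant (ms), maximal at V_tauNaP."""
    return params.tau_NaP_max / np.cosh((V - params.V_tauNaP) / params.k_tauNaP)


def rate(V, params: UnitParams):
    """Normalized firing rate: 0 below V_min, linear to 1 at V_max."""
    span = params.V_max - params.V_min
    return np.clip((np.asarray(V, dtype=float) - params.V_min) / span, 0.0, 1.0)


def synaptic_current(
    unit_index: int,
    state: NetworkState,
    net: NetworkConfig,
    effective_drives: np.ndarray,
) -> float:
    """Synaptic current (pA) into one unit for a given network state.

    ``unit_index`` is 0-based (0 left flexor .. 3 right extensor).
    """
    if not 0 <= unit_index < 4:
        raise IndexError(f"unit index must be in 0..3, got {unit_index}")
    i = unit_index
    V_i = state.V[i]
    d_i = effective_drives[i]
    f_j = np.array([rate(state.V[j], net.units[j]) for j in range(4)])
    inhib = float(np.dot(net.b[:, i], f_j)) * (V_i - net.E_inh)
    return float(d_i * (V_i - net.E_ex) + inhib)


def derivatives(
    state: NetworkState,
    net: NetworkConfig,
    drives: DriveConfig,
) -> tuple[np.ndarray, np.ndarray, CurrentBreakdown]:
    """Time derivatives dV/dt (mV/ms) and dh/dt (1/ms), plus the currents.

    Raises ValueError on a non-finite state.
    """
    V, h = state.V, state.h
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(h))):
        raise ValueError("non-finite state")

    d = drives.effective_drives()
    I_L = np.empty(4)
    I_NaP = np.empty(4)
    I_syn = np.empty(4)
    dh = np.empty(4)
    for i, p in enumerate(net.units):
        I_L[i] = p.g_L * (V[i] - p.E_L)
        I_NaP[i] = p.g_NaP * m_inf(V[i], p) * h[i] * (V[i] - p.E_Na)
        I_syn[i] = synaptic_current(i, state, net, d)
        dh[i] = (h_inf(V[i], p) - h[i]) / tau_h(V[i], p)
    C = np.array([p.C for p in net.units])
    dV = -(I_L + I_NaP + I_syn) / C
    return dV, dh, CurrentBreakdown(I_L=I_L, I_NaP=I_NaP, I_syn=I_syn)
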