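"""Numerical integration of the network and the Trace container.

The production solver is a fixed-step classical Runge-Kutta scheme at
dt = 0.05 ms (the system's fastest membrane time scale is C/g ~ 5 ms, so
this step resolves it by two orders of magnitude); traces are stored on a
uniform 1 ms grid regardless of solver internals.  An adaptive LSODA path
is provided for cross-checking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernel
from .dynamics import derivatives, h_inf, rate
from .params import (
    FLEXOR_L,
    FLEXOR_R,
    EXTENSOR_L,
    EXTENSOR_R,
    DriveConfig,
    NetworkConfig,
    NetworkState,
)

__all__ = ["Trace", "integrate", "seed_state", "DEFAULT_DURATION", "DEFAULT_TRANSIENT"]

DEFAULT_DURATION = 40_000.0  # ms; >= 12 cycles at the slowest reported rhythm
DEFAULT_TRANSIENT = 10_000.0  # ms discarded before any measurement
DEFAULT_DT = 0.05  # ms, fixed-step RK4
SAMPLE_DT = 1.0  # ms, storage grid


@dataclass
class Trace:
    """Uniformly sampled solution: V, h and firing rate f for all units.

    Arrays have shape (n_samples, 4), column order left flexor, right
    flexor, left extensor, right extensor.
    """

    t: np.ndarray
    V: np.ndarray
    h: np.ndarray
    f: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def sample_dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def after(self, t0: float) -> "Trace":
        """Sub-trace from time t0 (ms) onward; used to drop transients."""
        k = np.searchsorted(self.t, t0)
        return Trace(self.t[k:], self.V[k:], self.h[k:], self.f[k:], self.meta)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t}
        for name, arr in (("V", self.V), ("h", self.h), ("f", self.f)):
            for i in range(4):
                cols[f"{name}{i + 1}"] = arr[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def seed_state(
    net: NetworkConfig, kind: Literal["anti_phase", "in_phase"] = "anti_phase"
) -> NetworkState:
    """Standard initial conditions for coordination experiments.

    anti_phase: left flexor depolarized (-30 mV), everything else at rest
    (-65 mV) — biases the network toward alternation.  in_phase: both
    flexors depolarized, the right one 2 mV less — biases toward synchrony
    while sitting slightly off the exactly symmetric manifold, which is
    dynamically invariant: a perfectly symmetric start would follow the
    synchronous solution even where it is unstable, masking its stability.
    Gates start at their voltage steady state h_inf(V).
    """
    if kind == "anti_phase":
        V = np.array([-30.0, -65.0, -65.0, -65.0])
    elif kind == "in_phase":
        V = np.array([-30.0, -32.0, -65.0, -65.0])
    else:
        raise ValueError(f"unknown seed kind {kind!r}")
    h = np.array([h_inf(V[i], net.units[i]) for i in range(4)])
    return NetworkState(t=0.0, V=V, h=h)


def _config_hash(net: NetworkConfig, drives: DriveConfig, extra: dict) -> str:
    payload = {
        "b": net.b.tolist(),
        "E_ex": net.E_ex,
        "E_inh": net.E_inh,
        "units": [vars(u) for u in net.units],
        "drives": {
            k: getattr(drives, k)
            for k in (
                "d_F_left",
                "d_F_right",
                "D_E0",
                "coupled",
                "d_E_left_override",
                "d_E_right_override",
            )
        },
        **extra,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def integrate(
    net: NetworkConfig,
    drives: DriveConfig,
    duration: float = DEFAULT_DURATION,
    init: NetworkState | None = None,
    dt: float = DEFAULT_DT,
    sample_dt: float = SAMPLE_DT,
    method: Literal["rk4", "lsoda"] = "rk4",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trace:
    """Integrate the network ODEs and return a uniformly sampled Trace.

    Parameters
    ----------
    duration : simulated time in ms (must be positive).
    init : initial state; defaults to the anti-phase seed.
    dt : RK4 step (ms); must divide sample_dt.
    method : "rk4" (compiled fixed-step, default) or "lsoda" (scipy
        adaptive, used as an independent solver oracle).

    Raises RuntimeError if the state becomes non-finite.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if init is None:
        init = seed_state(net)
    d = drives.effective_drives()
    n_samples = int(round(duration / sample_dt))
    t = np.arange(n_samples + 1) * sample_dt

    if method == "rk4":
        record_every = int(round(sample_dt / dt))
        if abs(record_every * dt - sample_dt) > 1e-12:
            raise ValueError("dt must divide sample_dt")
        P = _kernel.pack_params(net)
        Vs, hs = _kernel.rk4_integrate(
            init.V.astype(float),
            init.h.astype(float),
            d,
            net.b,
            P,
            net.E_ex,
            net.E_inh,
            dt,
            n_samples * record_every,
            record_every,
        )
    elif method == "lsoda":
        def rhs(_t, y):
            state = NetworkState(t=_t, V=y[:4], h=np.clip(y[4:], 0.0, 1.0))
            dV, dh, _ = derivatives(state, net, drives)
            return np.concatenate([dV, dh])

        sol = solve_ivp(
            rhs,
            (0.0, duration),
            np.concatenate([init.V, init.h]),
            method="LSODA",
            t_eval=t,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"solver failed: {sol.message}")
        Vs = sol.y[:4].T.copy()
        hs = sol.y[4:].T.copy()
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(Vs)):
        raise RuntimeError("non-finite state during integration")

    f = np.column_stack(
        [rate(Vs[:, i], net.units[i]) for i in range(4)]
    )
    meta = {
        "method": method,
        "dt": dt,
        "sample_dt": sample_dt,
        "duration": duration,
        "config_hash": _config_hash(
            net, drives, {"method": method, "dt": dt, "duration": duration}
        ),
    }
    return Trace(t=t, V=Vs, h=hs, f=f, meta=meta)
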