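"""Parameter and state containers for the bilateral half-center CPG network.

The network has four activity-based units indexed 1..4 (0..3 internally):

    1 — left flexor, 2 — right flexor, 3 — left extensor, 4 — right extensor.

Each unit is a population model whose membrane potential obeys a
conductance-based current balance with a leak current, a slowly
inactivating persistent sodium current (the burst pacemaker), and synaptic
input.  Units are coupled by inhibitory synapses whose weights live in a
dense 4x4 matrix ``b`` (source row -> target column); excitatory drive is
modelled as an excitatory synaptic conductance.

Units of measure throughout: mV, ms, nS, pF, pA.  With these choices the
current-balance equation is dimensionally consistent without hidden scale
factors (pA / pF = mV / ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UnitParams",
    "NetworkConfig",
    "DriveConfig",
    "NetworkState",
    "CurrentBreakdown",
    "DriveClampWarning",
    "FLEXOR_L",
    "FLEXOR_R",
    "EXTENSOR_L",
    "EXTENSOR_R",
]

# 0-based unit indices (public API uses these names, not raw integers)
FLEXOR_L, FLEXOR_R, EXTENSOR_L, EXTENSOR_R = 0, 1, 2, 3


class DriveClampWarning(UserWarning):
    """Net extensor drive went negative and was clamped to zero."""


@dataclass(frozen=True)
class UnitParams:
    """Biophysical constants of one half-center unit.

    Defaults are the reference parameter set of the model: a 20 pF
    population unit with leak (2.8 nS to -65 mV) and persistent sodium
    (5 nS, reversal +50 mV) currents.  The persistent-Na activation gate is
    instantaneous with a rising sigmoid (half-voltage -40 mV, slope -6 mV);
    the inactivation gate relaxes toward a falling sigmoid (half-voltage
    -50 mV, slope 10 mV) with a sech-shaped voltage-dependent time constant
    peaking at 1500 ms.  The normalized firing rate is piecewise linear
    between V_min = -50 mV and V_max = 0 mV.
    """

    C: float = 20.0          # membrane capacitance, pF
    g_L: float = 2.8         # leak conductance, nS
    E_L: float = -65.0       # leak reversal, mV
    g_NaP: float = 5.0       # persistent-Na maximal conductance, nS
    E_Na: float = 50.0       # sodium reversal, mV
    V_mNaP: float = -40.0    # activation half-voltage, mV
    k_mNaP: float = -6.0     # activation slope, mV (negative: rising sigmoid)
    V_hNaP: float = -50.0    # inactivation half-voltage, mV
    k_hNaP: float = 10.0     # inactivation slope, mV (positive: falling sigmoid)
    tau_NaP_max: float = 1500.0  # inactivation time-constant scale, ms
    V_tauNaP: float = -100.0     # time-constant half-voltage, mV
    k_tauNaP: float = 40.0       # time-constant slope, mV
    V_min: float = -50.0     # rate-function threshold, mV
    V_max: float = 0.0       # rate-function saturation, mV

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.g_L < 0:
            raise ValueError(f"g_L must be non-negative, got {self.g_L}")
        if self.g_NaP < 0:
            raise ValueError(f"g_NaP must be non-negative, got {self.g_NaP}")
        if not self.V_max > self.V_min:
            raise ValueError(
                f"V_max ({self.V_max}) must exceed V_min ({self.V_min})"
            )
        if not self.tau_NaP_max > 0:
            raise ValueError(
                f"tau_NaP_max must be positive, got {self.tau_NaP_max}"
            )
        if not self.k_mNaP < 0:
            raise ValueError(
                f"k_mNaP must be negative (rising activation), got {self.k_mNaP}"
            )
        if not self.k_hNaP > 0:
            raise ValueError(
                f"k_hNaP must be positive (falling inactivation), got {self.k_hNaP}"
            )


# intra-RG reciprocal inhibition, fixed in all experiments (nS)
_B_EXT_TO_FLEX = 0.5   # extensor -> ipsilateral flexor
_B_FLEX_TO_EXT = 1.0   # flexor -> ipsilateral extensor


def _default_units() -> tuple[UnitParams, UnitParams, UnitParams, UnitParams]:
    p = UnitParams()
    return (p, p, p, p)


@dataclass(frozen=True)
class NetworkConfig:
    """Synaptic wiring and reversal potentials of the four-unit network.

    ``b[j, i]`` is the maximal conductance (nS) of the inhibitory synapse
    from unit j onto unit i (0-based indices).  Structurally absent
    connections (flexor->contralateral extensor and extensor->extensor)
    must be zero.
    """

    b: np.ndarray = field(default_factory=lambda: NetworkConfig._default_b())
    E_ex: float = -10.0   # excitatory synaptic reversal, mV
    E_inh: float = -90.0  # inhibitory synaptic reversal, mV
    units: tuple[UnitParams, ...] = field(default_factory=_default_units)

    @staticmethod
    def _default_b() -> np.ndarray:
        b = np.zeros((4, 4))
        b[EXTENSOR_L, FLEXOR_L] = _B_EXT_TO_FLEX
        b[EXTENSOR_R, FLEXOR_R] = _B_EXT_TO_FLEX
        b[FLEXOR_L, EXTENSOR_L] = _B_FLEX_TO_EXT
        b[FLEXOR_R, EXTENSOR_R] = _B_FLEX_TO_EXT
        return b

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if b.shape != (4, 4):
            raise ValueError(f"b must be 4x4, got shape {b.shape}")
        if np.any(b < 0):
            raise ValueError("synaptic weights must be non-negative")
        if np.any(np.diag(b) != 0):
            raise ValueError("self-connections (diagonal of b) must be zero")
        for j, i in [
            (FLEXOR_L, EXTENSOR_R),
            (FLEXOR_R, EXTENSOR_L),
            (EXTENSOR_L, EXTENSOR_R),
            (EXTENSOR_R, EXTENSOR_L),
        ]:
            if b[j, i] != 0:
                raise ValueError(
                    f"structural zero violated: b[{j + 1}{i + 1}] must be 0"
                )
        if len(self.units) != 4:
            raise ValueError("units must contain exactly four UnitParams")
        object.__setattr__(self, "b", b)

    @classmethod
    def bilateral(
        cls,
        ff_inhibition: float = 0.4,
        ef_inhibition: float = 0.2,
        **kwargs,
    ) -> "NetworkConfig":
        """Symmetric left-right wiring from the two commissural strengths.

        Parameters
        ----------
        ff_inhibition : mutual flexor-flexor inhibition b12 = b21 (nS).
        ef_inhibition : crossed extensor-flexor inhibition b41 = b32 (nS).

        The default point (F-F 0.4, E-F 0.2) lies in the monostable
        anti-phase region of the coordination plane at all drives used in
        the bilateral experiments.
        """
        b = cls._default_b()
        b[FLEXOR_L, FLEXOR_R] = ff_inhibition
        b[FLEXOR_R, FLEXOR_L] = ff_inhibition
        b[EXTENSOR_R, FLEXOR_L] = ef_inhibition
        b[EXTENSOR_L, FLEXOR_R] = ef_inhibition
        return cls(b=b, **kwargs)

    @classmethod
    def single_rg(cls, **kwargs) -> "NetworkConfig":
        """One rhythm generator in isolation: commissural weights zero.

        The right-side units remain in the state vector but receive and
        send no commissural input, so the left flexor-extensor pair evolves
        exactly as an isolated RG.
        """
        return cls.bilateral(ff_inhibition=0.0, ef_inhibition=0.0, **kwargs)

    @property
    def ff_inhibition(self) -> float:
        return float(self.b[FLEXOR_L, FLEXOR_R])

    @property
    def ef_inhibition(self) -> float:
        return float(self.b[EXTENSOR_R, FLEXOR_L])

    def mirrored(self) -> "NetworkConfig":
        """Wiring with left and right swapped (1<->2, 3<->4)."""
        perm = np.array([FLEXOR_R, FLEXOR_L, EXTENSOR_R, EXTENSOR_L])
        return replace(
            self,
            b=self.b[np.ix_(perm, perm)],
            units=tuple(self.units[k] for k in perm),
        )


@dataclass(frozen=True)
class DriveConfig:
    """Excitatory drives (nS) to the four units.

    Flexor drives are set directly.  In the default *coupled* mode the net
    drive to each extensor is a constant gross drive ``D_E0`` minus the
    ipsilateral flexor drive — the flexor drive simultaneously excites the
    flexor half-center and (through inhibitory interneurons) suppresses the
    extensor half-center.  With ``coupled=False`` the net extensor drives
    are given explicitly instead (the drive-decoupling control).
    """

    d_F_left: float = 0.5
    d_F_right: float = 0.5
    D_E0: float = 1.4
    coupled: bool = True
    d_E_left_override: float | None = None
    d_E_right_override: float | None = None

    def __post_init__(self) -> None:
        if self.d_F_left < 0 or self.d_F_right < 0:
            raise ValueError("flexor drives must be non-negative")
        if self.D_E0 < 0:
            raise ValueError("D_E0 must be non-negative")
        if not self.coupled:
            if self.d_E_left_override is None or self.d_E_right_override is None:
                raise ValueError(
                    "uncoupled drives require explicit extensor overrides"
                )
            if self.d_E_left_override < 0 or self.d_E_right_override < 0:
                raise ValueError("extensor drive overrides must be non-negative")

    @classmethod
    def symmetric(cls, drive: float, **kwargs) -> "DriveConfig":
        """Equal left and right flexor drives (tied-belt conditions)."""
        return cls(d_F_left=drive, d_F_right=drive, **kwargs)

    @classmethod
    def uncoupled(
        cls, d_F_left: float, d_F_right: float, d_E: float = 0.7
    ) -> "DriveConfig":
        """Fixed net extensor drive regardless of flexor drive."""
        return cls(
            d_F_left=d_F_left,
            d_F_right=d_F_right,
            coupled=False,
            d_E_left_override=d_E,
            d_E_right_override=d_E,
        )

    def net_extensor_drives(self) -> tuple[float, float]:
        """Net drives to the left and right extensors, clamped at zero.

        A warning (:class:`DriveClampWarning`) is issued if the coupled rule
        D_E0 - d_F would go negative; a negative conductance is unphysical.
        """
        if not self.coupled:
            return (float(self.d_E_left_override), float(self.d_E_right_override))
        left = self.D_E0 - self.d_F_left
        right = self.D_E0 - self.d_F_right
        if left < 0 or right < 0:
            warnings.warn(
                "net extensor drive clamped to 0 "
                f"(D_E0={self.D_E0}, flexor drives "
                f"{self.d_F_left}/{self.d_F_right})",
                DriveClampWarning,
                stacklevel=2,
            )
        return (max(left, 0.0), max(right, 0.0))

    def effective_drives(self) -> np.ndarray:
        """4-vector of drives [d1, d2, d3, d4] in unit order."""
        d_e_l, d_e_r = self.net_extensor_drives()
        return np.array([self.d_F_left, self.d_F_right, d_e_l, d_e_r])

    def mirrored(self) -> "DriveConfig":
        return replace(
            self,
            d_F_left=self.d_F_right,
            d_F_right=self.d_F_left,
            d_E_left_override=self.d_E_right_override,
            d_E_right_override=self.d_E_left_override,
        )


@dataclass
class NetworkState:
    """Instantaneous state: time (ms), membrane potentials V (mV) and
    persistent-Na inactivation gates h (dimensionless, in [0, 1])."""

    t: float
    V: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.V.shape != (4,) or self.h.shape != (4,):
            raise ValueError("V and h must be 4-vectors")
        if not np.all(np.isfinite(self.V)):
            raise ValueError("V must be finite")
        if np.any(self.h < 0) or np.any(self.h > 1):
            raise ValueError("h must lie in [0, 1]")

    def mirrored(self) -> "NetworkState":
        perm = np.array([FLEXOR_R, FLEXOR_L, EXTENSOR_R, EXTENSOR_L])
        return NetworkState(t=self.t, V=self.V[perm], h=self.h[perm])


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-unit currents (pA): leak, persistent sodium, synaptic.

    The total equals minus the capacitive term of the current balance, i.e.
    C dV/dt = -(I_L + I_NaP + I_syn).
    """

    I_L: np.ndarray
    I_NaP: np.ndarray
    I_syn: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.I_L + self.I_NaP + self.I_syn
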