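"""Burst detection and cycle metrics from firing-rate traces.

A burst of a unit is an excursion of its normalized firing rate f above an
on-threshold, terminated when f falls below a lower off-threshold
(hysteresis avoids chatter near the rate threshold).  Because f is
normalized to [0, 1], the thresholds are dimensionless and independent of
the biophysical parameters.  Cycle metrics follow locomotor conventions:
the flexor burst is the flexion (swing) phase, the inter-burst interval the
extension (stance) phase, and the period is the onset-to-onset interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean, circstd

from .params import DriveConfig, NetworkConfig, UnitParams, FLEXOR_L
from .simulate import DEFAULT_DURATION, DEFAULT_TRANSIENT, Trace, integrate, seed_state

__all__ = [
    "BurstTrain",
    "CycleMetrics",
    "PhaseStats",
    "NonOscillatoryError",
    "detect_bursts",
    "cycle_metrics",
    "phase_difference",
    "classify_unit_mode",
    "ON_THRESHOLD",
    "OFF_THRESHOLD",
]

ON_THRESHOLD = 0.10
OFF_THRESHOLD = 0.05
# steady-rhythm criterion: CV of the period over the analysed cycles
REGULARITY_CV = 0.02


class NonOscillatoryError(ValueError):
    """Raised when a trace has too few bursts for cycle metrics."""


@dataclass(frozen=True)
class BurstTrain:
    """Ordered, non-overlapping (onset, offset) intervals of one unit, ms."""

    intervals: np.ndarray  # shape (n, 2)
    unit: int = 0

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("burst offsets must follow onsets")
            if np.any(np.diff(iv[:, 0]) <= 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("bursts must be ordered and non-overlapping")
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def onsets(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def offsets(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def to_records(self) -> list[dict]:
        return [
            {"unit": self.unit + 1, "onset_ms": float(a), "offset_ms": float(b)}
            for a, b in self.intervals
        ]


@dataclass(frozen=True)
class CycleMetrics:
    """Averaged rhythm metrics of one unit's burst train."""

    period: float              # ms, mean onset-to-onset
    flexion_duration: float    # ms, mean burst duration
    extension_duration: float  # ms, period minus flexion
    frequency: float           # Hz
    duty_cycle: float          # flexion / period
    n_cycles_used: int
    regularity: float          # coefficient of variation of the period

    @property
    def is_regular(self) -> bool:
        return self.regularity < REGULARITY_CV

    def to_dict(self) -> dict:
        return {
            "period_ms": self.period,
            "flexion_ms": self.flexion_duration,
            "extension_ms": self.extension_duration,
            "frequency_hz": self.frequency,
            "duty_cycle": self.duty_cycle,
            "n_cycles": self.n_cycles_used,
            "period_cv": self.regularity,
        }


def detect_bursts(
    trace: Trace,
    unit: int,
    on_threshold: float = ON_THRESHOLD,
    off_threshold: float = OFF_THRESHOLD,
) -> BurstTrain:
    """Hysteresis burst detection on the firing rate of one unit.

    An onset is an upward crossing of ``on_threshold``; the burst ends at
    the next downward crossing of ``off_threshold``.  Partial bursts at the
    trace edges (activity already above threshold at the start, or an
    unterminated burst at the end) are discarded.  An empty train is a
    valid result.
    """
    if not on_threshold > off_threshold >= 0:
        raise ValueError("need on_threshold > off_threshold >= 0")
    f = trace.f[:, unit]
    t = trace.t
    intervals = []
    in_burst = False
    # skip an initial burst-in-progress: wait until f is below off_threshold
    started = f[0] < on_threshold
    onset = 0.0
    for k in range(1, len(f)):
        if not started:
            if f[k] < off_threshold:
                started = True
            continue
        if not in_burst:
            if f[k] >= on_threshold and f[k - 1] < on_threshold:
                in_burst = True
                onset = t[k]
        else:
            if f[k] < off_threshold and f[k - 1] >= off_threshold:
                intervals.append((onset, t[k]))
                in_burst = False
    return BurstTrain(intervals=np.array(intervals).reshape(-1, 2), unit=unit)


def cycle_metrics(bursts: BurstTrain) -> CycleMetrics:
    """Averaged period/flexion/extension metrics from a burst train.

    Requires at least 3 complete bursts (2 full cycles); otherwise raises
    :class:`NonOscillatoryError`.
    """
    if len(bursts) < 3:
        raise NonOscillatoryError(
            f"need >= 3 bursts for cycle metrics, got {len(bursts)}"
        )
    periods = np.diff(bursts.onsets)
    period = float(np.mean(periods))
    # burst durations for cycles that have a following onset
    flexion = float(np.mean(bursts.durations[:-1]))
    extension = period - flexion
    cv = float(np.std(periods) / period) if period > 0 else np.inf
    return CycleMetrics(
        period=period,
        flexion_duration=flexion,
        extension_duration=extension,
        frequency=1000.0 / period,
        duty_cycle=flexion / period,
        n_cycles_used=len(periods),
        regularity=cv,
    )


@dataclass(frozen=True)
class PhaseStats:
    """Circular summary of left-right flexor phase differences in [0, 1)."""

    mean: float
    sd: float
    values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def phase_difference(left: BurstTrain, right: BurstTrain) -> PhaseStats:
    """Normalized phase of right flexor onsets within the left flexor cycle.

    For each left onset, the fractional position of the nearest following
    right onset within that left cycle; summarized by circular mean and
    circular SD on the unit circle [0, 1).
    """
    if len(left) < 3 or len(right) < 3:
        raise NonOscillatoryError("both trains need >= 3 bursts")
    l_on = left.onsets
    r_on = right.onsets
    if r_on[-1] < l_on[0] or l_on[-1] < r_on[0]:
        raise ValueError("burst trains do not overlap in time")
    phases = []
    for a, b in zip(l_on[:-1], l_on[1:]):
        nxt = r_on[(r_on >= a) & (r_on < b)]
        if nxt.size:
            phases.append((nxt[0] - a) / (b - a))
    if not phases:
        raise ValueError("no right onsets fall within any left cycle")
    ph = np.asarray(phases)
    return PhaseStats(
        mean=float(circmean(ph, high=1.0)),
        sd=float(circstd(ph, high=1.0)),
        values=ph,
    )


def classify_unit_mode(
    params: UnitParams,
    drive: float,
    duration: float = DEFAULT_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> str:
    """Activity mode of one isolated unit under a given drive.

    Simulates the unit with no synaptic inputs other than the excitatory
    drive conductance and classifies the steady firing-rate trace:
    ``quiescent`` (f stays below the burst on-threshold), ``tonic`` (f stays
    above the off-threshold without oscillating), ``bursting`` (sustained
    rhythmic alternation), or ``indeterminate`` (residual oscillation too
    irregular or decaying at the horizon).

    Conditional-burster behaviour is expected: quiescent at low drive,
    bursting in an intermediate window, tonic at high drive.
    """
    net = NetworkConfig(b=np.zeros((4, 4)), units=(params,) * 4)
    drv = DriveConfig.uncoupled(d_F_left=drive, d_F_right=0.0, d_E=0.0)
    init = seed_state(net, "anti_phase")
    trace = integrate(net, drv, duration=duration, init=init).after(transient)
    f = trace.f[:, FLEXOR_L]
    bursts = detect_bursts(trace, FLEXOR_L)
    if len(bursts) >= 3:
        return "bursting"
    if float(f.max()) < ON_THRESHOLD:
        return "quiescent"
    if float(f.min()) > OFF_THRESHOLD:
        # above threshold throughout; tonic only if not visibly oscillating
        if float(f.max() - f.min()) < 0.02:
            return "tonic"
        return "indeterminate"
    return "indeterminate"
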