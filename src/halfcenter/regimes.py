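"""Coordination-regime experiments on the bilateral CPG network.

Four computational experiments are implemented, all brute-force grid
simulations of the deterministic ODE model:

* a single-RG drive sweep (period / flexion / extension vs drive);
* a two-parameter frequency map over independent flexor and net extensor
  drives, with the flexor's intrinsic-rhythmicity boundary;
* a symmetric-drive partition of the commissural-inhibition plane
  (F-F inhibition x E-F inhibition) probed from two initial-condition
  seeds, which exposes bistability between in-phase and anti-phase
  coordination;
* asymmetric-drive experiments: a 1:n burst-ratio map over (slow, fast)
  flexor drives and split-belt-like sweeps with the fast drive increasing
  at fixed slow drive, with and without drive-coupled extensor inhibition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bursts import (
    BurstTrain,
    CycleMetrics,
    NonOscillatoryError,
    REGULARITY_CV,
    classify_unit_mode,
    cycle_metrics,
    detect_bursts,
    phase_difference,
)
from .params import (
    FLEXOR_L,
    FLEXOR_R,
    DriveConfig,
    NetworkConfig,
)
from .simulate import (
    DEFAULT_DURATION,
    DEFAULT_TRANSIENT,
    Trace,
    integrate,
    seed_state,
)

__all__ = [
    "RegimeLabel",
    "RegimeMap",
    "SweepResult",
    "single_rg_sweep",
    "equal_phase_drive",
    "frequency_map",
    "classify_symmetric",
    "symmetric_regime_map",
    "coordination_ratio",
    "asymmetric_ratio_map",
    "split_belt_sweep",
    "validate_reference_point",
    "REFERENCE_FF",
    "REFERENCE_EF",
]

# Reference commissural-inhibition point for asymmetric experiments:
# must lie in the monostable anti-phase region at all drives
# (see validate_reference_point).
REFERENCE_FF = 0.4
REFERENCE_EF = 0.2

# phase-difference classification bins (normalized phase in [0, 1))
IN_PHASE_TOL = 0.05
ANTI_PHASE_TOL = 0.05
SMALL_LAG_MAX = 0.2

# horizon for burst-ratio measurements: long enough for >= 10 slow cycles
# at the slowest rhythms encountered (~0.4 Hz)
RATIO_DURATION = 60_000.0


@dataclass(frozen=True)
class RegimeLabel:
    """Classified coordination regime of one parameter point."""

    cls: str                      # in_phase | anti_phase | asymmetric_alternation
    #                             | small_phase_lag | bistable | one_to_n
    #                             | intermittent | quiescent | tonic
    phase: float | None = None    # measured left-right phase difference
    n: int | None = None          # fast bursts per slow cycle for one_to_n
    per_seed: tuple = ()          # (seed_name, class) pairs behind the label

    def __post_init__(self) -> None:
        if self.cls == "one_to_n" and (self.n is None or self.n < 1):
            raise ValueError("one_to_n label requires integer n >= 1")

    def __str__(self) -> str:
        if self.cls == "one_to_n":
            return f"1:{self.n}"
        return self.cls


@dataclass
class RegimeMap:
    """Labeled rectangular grid over a 2-D parameter plane."""

    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    labels: np.ndarray            # object array (ny, nx) of RegimeLabel/None
    values: np.ndarray | None = None  # optional numeric field, e.g. frequency
    provenance: dict = field(default_factory=dict)

    def label_at(self, x: float, y: float) -> RegimeLabel:
        ix = int(np.argmin(np.abs(self.x_values - x)))
        iy = int(np.argmin(np.abs(self.y_values - y)))
        return self.labels[iy, ix]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, y in enumerate(self.y_values):
            for ix, x in enumerate(self.x_values):
                lab = self.labels[iy, ix]
                rows.append(
                    {
                        self.x_name: x,
                        self.y_name: y,
                        "label": str(lab) if lab is not None else "indeterminate",
                        "phase": getattr(lab, "phase", None),
                        "value": None
                        if self.values is None
                        else self.values[iy, ix],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "x_name": self.x_name,
            "x_values": self.x_values.tolist(),
            "y_name": self.y_name,
            "y_values": self.y_values.tolist(),
            "labels": [
                [str(l) if l is not None else None for l in row]
                for row in self.labels
            ],
            "values": None if self.values is None else self.values.tolist(),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class SweepResult:
    """Per-parameter-value cycle metrics along a 1-D sweep."""

    param_name: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path=None) -> str:
        payload = {
            "param_name": self.param_name,
            "records": json.loads(self.data.to_json(orient="records")),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _metrics_or_none(trace: Trace, unit: int) -> CycleMetrics | None:
    try:
        return cycle_metrics(detect_bursts(trace, unit))
    except NonOscillatoryError:
        return None


def single_rg_sweep(
    drive_grid: Sequence[float] | None = None,
    coupled: bool = True,
    fixed_extensor_drive: float = 0.7,
    duration: float = DEFAULT_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> SweepResult:
    """Drive sweep of the isolated RG (commissural weights zero).

    With ``coupled=True`` (default) the net extensor drive follows the
    drive-coupling rule D_E0 - d_F; with ``coupled=False`` it is held at
    ``fixed_extensor_drive`` (the decoupling control).
    Returns period, flexion, extension, frequency and duty cycle per drive.
    """
    if drive_grid is None:
        drive_grid = np.round(np.arange(0.2, 0.8 + 1e-9, 0.01), 10)
    net = NetworkConfig.single_rg()
    rows = []
    for d in drive_grid:
        if coupled:
            drv = DriveConfig.symmetric(float(d))
        else:
            drv = DriveConfig.uncoupled(float(d), float(d), fixed_extensor_drive)
        trace = integrate(net, drv, duration=duration).after(transient)
        cm = _metrics_or_none(trace, FLEXOR_L)
        row = {"drive": float(d)}
        row.update(
            cm.to_dict()
            if cm is not None
            else {k: np.nan for k in CycleMetrics(1, 1, 0, 1, 1, 0, 0).to_dict()}
        )
        rows.append(row)
    return SweepResult(
        param_name="drive",
        data=pd.DataFrame(rows),
        provenance={"coupled": coupled, "duration": duration},
    )


def equal_phase_drive(sweep: SweepResult | None = None, **sweep_kwargs) -> float:
    """Drive at which flexion and extension durations are equal.

    Locates the sign change of flexion - extension along the sweep and
    interpolates linearly between the bracketing grid points.  Raises
    ValueError if no sign change exists on the grid.
    """
    if sweep is None:
        sweep = single_rg_sweep(**sweep_kwargs)
    df = sweep.data.dropna(subset=["flexion_ms", "extension_ms"])
    d = df["drive"].to_numpy()
    diff = (df["flexion_ms"] - df["extension_ms"]).to_numpy()
    if np.all(np.abs(diff) < 1e-9):
        # degenerate symmetric case: any drive qualifies
        return float(d[0])
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("no flexion-extension crossover on the sweep grid")
    k = int(sign_change[0])
    frac = -diff[k] / (diff[k + 1] - diff[k])
    return float(d[k] + frac * (d[k + 1] - d[k]))


def frequency_map(
    flexor_grid: Sequence[float],
    extensor_grid: Sequence[float],
    duration: float = DEFAULT_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> RegimeMap:
    """Two-parameter map of RG bursting frequency over independent drives.

    The isolated RG is simulated with the flexor drive on the x axis and
    the net extensor drive on the y axis (drive coupling disabled).  Cell
    values are the flexor bursting frequency (0 for non-oscillatory cells).
    The provenance records the flexor-drive interval over which the flexor
    half-center is intrinsically rhythmic (the flexor-driven /
    half-center-mechanism boundary).
    """
    net = NetworkConfig.single_rg()
    fx = np.asarray(flexor_grid, dtype=float)
    ex = np.asarray(extensor_grid, dtype=float)
    values = np.zeros((len(ex), len(fx)))
    labels = np.empty((len(ex), len(fx)), dtype=object)
    for iy, de in enumerate(ex):
        for ix, df_ in enumerate(fx):
            drv = DriveConfig.uncoupled(float(df_), float(df_), float(de))
            trace = integrate(net, drv, duration=duration).after(transient)
            cm = _metrics_or_none(trace, FLEXOR_L)
            if cm is None:
                fmax = float(trace.f[:, FLEXOR_L].max())
                cls = "quiescent" if fmax < 0.10 else "tonic"
                labels[iy, ix] = RegimeLabel(cls=cls)
            else:
                values[iy, ix] = cm.frequency
                labels[iy, ix] = RegimeLabel(cls="one_to_n", n=1)
    unit = net.units[FLEXOR_L]
    modes = [classify_unit_mode(unit, float(d)) for d in fx]
    rhythmic = [d for d, m in zip(fx, modes) if m == "bursting"]
    prov = {
        "flexor_intrinsic_modes": dict(zip(map(float, fx), modes)),
        "flexor_rhythmic_max_drive": max(rhythmic) if rhythmic else None,
    }
    return RegimeMap(
        x_name="flexor_drive",
        x_values=fx,
        y_name="extensor_drive",
        y_values=ex,
        labels=labels,
        values=values,
        provenance=prov,
    )


def _classify_phase(phase: float, regular: bool) -> str:
    lag = min(phase, 1.0 - phase)
    if not regular:
        return "intermittent"
    if lag < IN_PHASE_TOL:
        return "in_phase"
    if abs(phase - 0.5) < ANTI_PHASE_TOL:
        return "anti_phase"
    if lag < SMALL_LAG_MAX:
        return "small_phase_lag"
    return "asymmetric_alternation"


def _classify_one_seed(
    net: NetworkConfig,
    drives: DriveConfig,
    seed: str,
    duration: float,
    transient: float,
) -> tuple[str, float | None]:
    trace = integrate(net, drives, duration=duration, init=seed_state(net, seed))
    trace = trace.after(transient)
    left = detect_bursts(trace, FLEXOR_L)
    right = detect_bursts(trace, FLEXOR_R)
    if len(left) < 3 or len(right) < 3:
        fmax = max(float(trace.f[:, FLEXOR_L].max()), float(trace.f[:, FLEXOR_R].max()))
        return ("quiescent" if fmax < 0.10 else "tonic"), None
    ph = phase_difference(left, right)
    cv = cycle_metrics(left).regularity
    # a dispersed phase distribution also marks an unsettled rhythm
    regular = cv < REGULARITY_CV and ph.sd < 0.05
    return _classify_phase(ph.mean, regular), ph.mean


def classify_symmetric(
    drive: float,
    ff_inhibition: float,
    ef_inhibition: float,
    seeds: Iterable[str] = ("anti_phase", "in_phase"),
    duration: float = DEFAULT_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> RegimeLabel:
    """Coordination regime at one point of the symmetric-drive plane.

    The bilateral network is run from each initial-condition seed; each
    outcome is classified by the steady left-right flexor phase
    difference.  If the seeds settle into distinct classes the point is
    bistable.
    """
    net = NetworkConfig.bilateral(ff_inhibition, ef_inhibition)
    drv = DriveConfig.symmetric(drive)
    outcomes = []
    phases = {}
    for seed in seeds:
        cls, ph = _classify_one_seed(net, drv, seed, duration, transient)
        outcomes.append((seed, cls))
        phases[seed] = ph
    classes = {cls for _, cls in outcomes}
    if len(classes) == 1:
        cls = outcomes[0][1]
        ph = phases[outcomes[0][0]]
        return RegimeLabel(cls=cls, phase=ph, per_seed=tuple(outcomes))
    return RegimeLabel(
        cls="bistable",
        phase=phases.get("anti_phase"),
        per_seed=tuple(outcomes),
    )


def symmetric_regime_map(
    drive: float,
    ff_grid: Sequence[float],
    ef_grid: Sequence[float],
    **kwargs,
) -> RegimeMap:
    """Full partition of the F-F x E-F inhibition plane at one drive."""
    ff = np.asarray(ff_grid, dtype=float)
    ef = np.asarray(ef_grid, dtype=float)
    labels = np.empty((len(ff), len(ef)), dtype=object)
    for iy, w_ff in enumerate(ff):
        for ix, w_ef in enumerate(ef):
            labels[iy, ix] = classify_symmetric(drive, float(w_ff), float(w_ef), **kwargs)
    return RegimeMap(
        x_name="ef_inhibition",
        x_values=ef,
        y_name="ff_inhibition",
        y_values=ff,
        labels=labels,
        provenance={"drive": drive, "seeds": ["anti_phase", "in_phase"]},
    )


def coordination_ratio(
    slow: BurstTrain,
    fast: BurstTrain,
    min_cycles: int = 10,
    agreement: float = 0.9,
) -> RegimeLabel:
    """Fast-per-slow burst-count ratio: 1:n or intermittent.

    Counts fast flexor bursts whose onsets fall strictly within each slow
    cycle (onset-to-onset).  If at least ``agreement`` of the cycles carry
    the same integer count n >= 1, the label is 1:n; otherwise the
    coordination is intermittent.
    """
    if len(slow) < min_cycles + 1:
        raise NonOscillatoryError(
            f"need >= {min_cycles} slow cycles, got {max(len(slow) - 1, 0)}"
        )
    s_on = slow.onsets
    f_on = fast.onsets
    counts = [
        int(np.sum((f_on > a) & (f_on <= b)))
        for a, b in zip(s_on[:-1], s_on[1:])
    ]
    counts = np.asarray(counts)
    vals, freq = np.unique(counts, return_counts=True)
    best = int(vals[np.argmax(freq)])
    if best >= 1 and freq.max() / len(counts) >= agreement:
        return RegimeLabel(cls="one_to_n", n=best)
    return RegimeLabel(cls="intermittent")


def _ratio_at(
    slow_drive: float,
    fast_drive: float,
    net: NetworkConfig,
    duration: float,
    transient: float,
) -> RegimeLabel:
    drv = DriveConfig(d_F_left=slow_drive, d_F_right=fast_drive)
    trace = integrate(net, drv, duration=duration).after(transient)
    slow = detect_bursts(trace, FLEXOR_L)
    fast = detect_bursts(trace, FLEXOR_R)
    if len(fast) < 3:
        # saturated fast flexor shows as tonic here and, through sustained
        # F-F inhibition, as a quiescent slow flexor
        fmin = float(trace.f[:, FLEXOR_R].min())
        return RegimeLabel(cls="tonic" if fmin > 0.05 else "quiescent")
    if len(slow) < 3:
        fmax = float(trace.f[:, FLEXOR_L].max())
        return RegimeLabel(cls="quiescent" if fmax < 0.10 else "tonic")
    try:
        return coordination_ratio(slow, fast)
    except NonOscillatoryError:
        return RegimeLabel(cls="intermittent")


def asymmetric_ratio_map(
    slow_grid: Sequence[float],
    fast_grid: Sequence[float],
    ff_inhibition: float = REFERENCE_FF,
    ef_inhibition: float = REFERENCE_EF,
    duration: float = RATIO_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> RegimeMap:
    """1:n coordination map over (slow, fast) flexor drives.

    Cells with fast drive below the slow drive are left unlabeled (the
    slow side is unit 1 by convention).  Bisector cells (equal drives)
    are expected anti-phase 1:1 at the reference inhibition point.
    """
    slow = np.asarray(slow_grid, dtype=float)
    fast = np.asarray(fast_grid, dtype=float)
    net = NetworkConfig.bilateral(ff_inhibition, ef_inhibition)
    labels = np.empty((len(slow), len(fast)), dtype=object)
    labels[:] = None
    for iy, ds in enumerate(slow):
        for ix, df_ in enumerate(fast):
            if df_ < ds - 1e-12:
                continue
            labels[iy, ix] = _ratio_at(
                float(ds), float(df_), net, duration, transient
            )
    return RegimeMap(
        x_name="fast_drive",
        x_values=fast,
        y_name="slow_drive",
        y_values=slow,
        labels=labels,
        provenance={
            "ff_inhibition": ff_inhibition,
            "ef_inhibition": ef_inhibition,
            "duration": duration,
        },
    )


def max_ratio_over_fast_sweep(
    slow_drive: float,
    fast_step: float = 0.02,
    fast_max: float = 1.3,
    ff_inhibition: float = REFERENCE_FF,
    ef_inhibition: float = REFERENCE_EF,
    duration: float = RATIO_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> tuple[int, list[tuple[float, str]]]:
    """Highest 1:n order reached while sweeping the fast drive upward.

    Sweeps from the slow drive until the fast flexor goes tonic or the
    drive reaches ``fast_max``.  Returns (max n, per-drive labels).
    """
    net = NetworkConfig.bilateral(ff_inhibition, ef_inhibition)
    fast_values = np.round(
        np.arange(slow_drive, fast_max + 1e-9, fast_step), 10
    )
    history: list[tuple[float, str]] = []
    best = 0
    for df_ in fast_values:
        lab = _ratio_at(slow_drive, float(df_), net, duration, transient)
        history.append((float(df_), str(lab)))
        if lab.cls == "one_to_n":
            best = max(best, lab.n)
        if lab.cls == "tonic":
            break
    return best, history


def split_belt_sweep(
    slow_drive: float = 0.5,
    fast_grid: Sequence[float] | None = None,
    coupled: bool = True,
    fixed_extensor_drive: float = 0.7,
    ff_inhibition: float = REFERENCE_FF,
    ef_inhibition: float = REFERENCE_EF,
    duration: float = RATIO_DURATION,
    transient: float = DEFAULT_TRANSIENT,
) -> SweepResult:
    """Split-belt-like sweep: fixed slow drive, increasing fast drive.

    Returns per-value cycle metrics for both RGs plus the coordination
    ratio.  With ``coupled=False`` both net extensor drives are fixed at
    ``fixed_extensor_drive`` (the drive-decoupling control).
    """
    if fast_grid is None:
        fast_grid = np.round(np.arange(0.5, 0.8 + 1e-9, 0.05), 10)
    net = NetworkConfig.bilateral(ff_inhibition, ef_inhibition)
    rows = []
    for df_ in fast_grid:
        if coupled:
            drv = DriveConfig(d_F_left=slow_drive, d_F_right=float(df_))
        else:
            drv = DriveConfig(
                d_F_left=slow_drive,
                d_F_right=float(df_),
                coupled=False,
                d_E_left_override=fixed_extensor_drive,
                d_E_right_override=fixed_extensor_drive,
            )
        trace = integrate(net, drv, duration=duration).after(transient)
        slow_train = detect_bursts(trace, FLEXOR_L)
        fast_train = detect_bursts(trace, FLEXOR_R)
        row = {"fast_drive": float(df_)}
        for tag, train in (("slow", slow_train), ("fast", fast_train)):
            try:
                cm = cycle_metrics(train)
                for k, v in cm.to_dict().items():
                    row[f"{tag}_{k}"] = v
            except NonOscillatoryError:
                for k in ("period_ms", "flexion_ms", "extension_ms",
                          "frequency_hz", "duty_cycle", "n_cycles", "period_cv"):
                    row[f"{tag}_{k}"] = np.nan
        try:
            row["ratio"] = str(coordination_ratio(slow_train, fast_train))
        except NonOscillatoryError:
            row["ratio"] = "indeterminate"
        rows.append(row)
    return SweepResult(
        param_name="fast_drive",
        data=pd.DataFrame(rows),
        provenance={
            "slow_drive": slow_drive,
            "coupled": coupled,
            "ff_inhibition": ff_inhibition,
            "ef_inhibition": ef_inhibition,
        },
    )


def validate_reference_point(
    ff_inhibition: float = REFERENCE_FF,
    ef_inhibition: float = REFERENCE_EF,
    drives: Sequence[float] = (0.3, 0.4, 0.5, 0.65),
    **kwargs,
) -> bool:
    """Check the reference inhibition point is monostable anti-phase.

    The asymmetric experiments assume a commissural point producing robust
    anti-phase alternations at all locomotor frequencies.  Returns True if
    both seeds settle to anti-phase at every drive; warns and returns
    False otherwise (e.g. if the axis order of the point was swapped).
    """
    import warnings

    ok = True
    for d in drives:
        lab = classify_symmetric(d, ff_inhibition, ef_inhibition, **kwargs)
        if lab.cls != "anti_phase":
            warnings.warn(
                f"reference point (F-F={ff_inhibition}, E-F={ef_inhibition}) "
                f"is {lab.cls} at drive {d}; expected monostable anti-phase",
                stacklevel=2,
            )
            ok = False
    return ok
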