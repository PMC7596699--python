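"""Synthetic traces with planted bursts, for exercising the measurement layer.

The generator writes a firing-rate series that is zero outside the planted
intervals and at a plateau inside them, optionally corrupted by Gaussian
noise (clipped back to [0, 1]); membrane potential is set so that the
Trace invariant f = rate(V) holds exactly.  At zero noise the planted
schedule is recovered exactly by burst detection, which is what the
round-trip tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import UnitParams
from .simulate import Trace

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Planted burst schedule for up to four units.

    ``schedule`` maps unit index (0..3) to a list of (onset, offset)
    intervals in ms; intervals must be ordered, non-overlapping and lie
    strictly inside (0, duration) so no partial bursts touch the edges.
    """

    schedule: dict[int, tuple[tuple[float, float], ...]]
    duration: float = 10_000.0
    sample_dt: float = 1.0
    noise: float = 0.0
    plateau: float = 0.8
    params: UnitParams = field(default_factory=UnitParams)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_dt <= 0:
            raise ValueError("duration and sample_dt must be positive")
        if not 0 < self.plateau <= 1:
            raise ValueError("plateau must be in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise amplitude must be non-negative")
        for unit, intervals in self.schedule.items():
            if unit not in (0, 1, 2, 3):
                raise ValueError(f"unit index out of range: {unit}")
            prev_end = 0.0
            for onset, offset in intervals:
                if not 0 < onset < offset < self.duration:
                    raise ValueError(
                        f"interval ({onset}, {offset}) outside (0, {self.duration})"
                    )
                if onset <= prev_end:
                    raise ValueError("intervals must be ordered and disjoint")
                prev_end = offset


def generate_fixture(spec: FixtureSpec, seed: int = 0) -> Trace:
    """Deterministic synthetic Trace realizing a planted burst schedule."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration / spec.sample_dt))
    t = np.arange(n + 1) * spec.sample_dt
    f = np.zeros((n + 1, 4))
    for unit, intervals in spec.schedule.items():
        for onset, offset in intervals:
            # half-open [onset, offset): the offset sample is already off
            f[(t >= onset) & (t < offset), unit] = spec.plateau
    if spec.noise > 0:
        f = np.clip(f + rng.normal(0.0, spec.noise, size=f.shape), 0.0, 1.0)
    p = spec.params
    V = p.V_min + f * (p.V_max - p.V_min)  # inverts rate() on [0, 1]
    h = 1.0 / (1.0 + np.exp((V - p.V_hNaP) / p.k_hNaP))
    return Trace(
        t=t,
        V=V,
        h=h,
        f=f,
        meta={"fixture": True, "seed": seed, "noise": spec.noise},
    )
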