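"""Regime-analysis layer: ratio labeling, sweeps, map consistency."""

import numpy as np
import pandas as pd
import pytest

from halfcenter.bursts import BurstTrain, NonOscillatoryError
from halfcenter.params import NetworkConfig
from halfcenter.regimes import (
    RegimeLabel,
    SweepResult,
    _ratio_at,
    classify_symmetric,
    coordination_ratio,
    equal_phase_drive,
    frequency_map,
    single_rg_sweep,
    split_belt_sweep,
)


def _train(onsets, width=150.0):
    return BurstTrain(intervals=np.array([[a, a + width] for a in onsets]))


class TestCoordinationRatio:
    def test_equal_trains_are_one_to_one(self):
        onsets = np.arange(0.0, 24_000.0, 2000.0)
        lab = coordination_ratio(_train(onsets), _train(onsets + 1000.0))
        assert lab.cls == "one_to_n" and lab.n == 1

    def test_two_fast_bursts_per_slow_cycle(self):
        slow = _train(np.arange(0.0, 24_000.0, 2000.0))
        fast = _train(np.arange(500.0, 24_000.0, 1000.0), width=100.0)
        lab = coordination_ratio(slow, fast)
        assert lab.cls == "one_to_n" and lab.n == 2

    def test_alternating_counts_are_intermittent(self):
        slow = _train(np.arange(0.0, 26_000.0, 2000.0))
        # alternate one and two fast onsets per slow cycle
        fast_onsets = []
        for k, a in enumerate(slow.onsets[:-1]):
            fast_onsets.append(a + 500.0)
            if k % 2:
                fast_onsets.append(a + 1200.0)
        lab = coordination_ratio(slow, _train(np.array(fast_onsets), width=100.0))
        assert lab.cls == "intermittent"

    def test_too_few_cycles_rejected(self):
        slow = _train(np.arange(0.0, 8000.0, 2000.0))
        with pytest.raises(NonOscillatoryError):
            coordination_ratio(slow, slow)

    def test_one_to_n_label_requires_positive_n(self):
        with pytest.raises(ValueError):
            RegimeLabel(cls="one_to_n", n=0)


class TestEqualPhaseDrive:
    def _sweep(self, drives, flexion, extension):
        df = pd.DataFrame(
            {
                "drive": drives,
                "flexion_ms": flexion,
                "extension_ms": extension,
            }
        )
        return SweepResult(param_name="drive", data=df)

    def test_interpolated_crossover(self):
        sw = self._sweep([0.2, 0.3, 0.4], [300.0, 300.0, 300.0], [500.0, 320.0, 200.0])
        # sign change between 0.3 and 0.4: -20 -> +100
        assert equal_phase_drive(sw) == pytest.approx(0.3 + 0.1 * 20 / 120)

    def test_no_crossover_raises(self):
        sw = self._sweep([0.2, 0.3], [300.0, 300.0], [600.0, 500.0])
        with pytest.raises(ValueError, match="no flexion-extension crossover"):
            equal_phase_drive(sw)

    def test_degenerate_identical_durations_returns_grid_point(self):
        sw = self._sweep([0.2, 0.3], [300.0, 300.0], [300.0, 300.0])
        assert equal_phase_drive(sw) == 0.2


class TestSingleRgSweep:
    def test_extension_shortens_while_flexion_stays_flat(self):
        sw = single_rg_sweep([0.2, 0.5, 0.8])
        ext = sw.data["extension_ms"].to_numpy()
        flex = sw.data["flexion_ms"].to_numpy()
        assert np.all(np.diff(ext) < 0)
        assert ext[0] / ext[-1] > 3  # extension collapses with drive
        assert flex.max() / flex.min() < 1.6  # flexion comparatively flat

    def test_uncoupled_control_keeps_flexion_flat(self):
        sw = single_rg_sweep([0.3, 0.5, 0.7], coupled=False)
        flex = sw.data["flexion_ms"].to_numpy()
        assert flex.max() / flex.min() < 1.15


class TestFrequencyMap:
    def test_quiescent_and_oscillatory_cells(self):
        rmap = frequency_map([0.0, 0.3], [0.0, 1.1])
        # no excitation at all: silent cell with zero frequency
        assert rmap.labels[0, 0].cls == "quiescent"
        assert rmap.values[0, 0] == 0.0
        # flexor-driven cell: intrinsically rhythmic flexor, tonic extensor
        assert rmap.labels[1, 1].cls == "one_to_n"
        assert rmap.values[1, 1] > 0.2
        modes = rmap.provenance["flexor_intrinsic_modes"]
        assert modes[0.0] in ("quiescent", "tonic")
        assert modes[0.3] == "bursting"


class TestBilateralConsistency:
    def test_equal_drives_give_symmetric_metrics(self):
        sw = split_belt_sweep(slow_drive=0.5, fast_grid=[0.5])
        row = sw.data.iloc[0]
        assert row["ratio"] == "1:1"
        assert row["slow_period_ms"] == pytest.approx(row["fast_period_ms"], rel=0.02)
        assert row["slow_flexion_ms"] == pytest.approx(row["fast_flexion_ms"], rel=0.02)

    def test_bisector_matches_symmetric_classification(self):
        """Equal-drive ratio-map cells agree with the symmetric experiment."""
        net = NetworkConfig.bilateral(0.4, 0.2)
        lab = _ratio_at(0.5, 0.5, net, 60_000.0, 10_000.0)
        assert str(lab) == "1:1"
        sym = classify_symmetric(0.5, 0.4, 0.2)
        assert sym.cls == "anti_phase"

    def test_seed_role_exchange_equivariance(self):
        """Swapping which side hosts each seed leaves the label unchanged."""
        a = classify_symmetric(0.3, 0.4, 0.3)
        b = classify_symmetric(0.3, 0.4, 0.3, seeds=("in_phase", "anti_phase"))
        assert a.cls == b.cls == "anti_phase"
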