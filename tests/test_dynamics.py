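"""Unit tests of the model equations against hand and symbolic oracles."""

import math

import numpy as np
import pytest

from halfcenter import (
    DriveClampWarning,
    DriveConfig,
    NetworkConfig,
    NetworkState,
    UnitParams,
    derivatives,
    h_inf,
    m_inf,
    rate,
    synaptic_current,
    tau_h,
)

E = math.e


class TestGateFunctions:
    @pytest.mark.parametrize(
        "V, expected",
        [
            (-40.0, 0.5),              # half-activation voltage
            (-46.0, 1 / (1 + E)),      # one slope-width below
            (500.0, 1.0),              # saturation
            (-500.0, 0.0),             # closed
        ],
    )
    def test_m_inf(self, unit, V, expected):
        assert m_inf(V, unit) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "V, expected",
        [
            (-50.0, 0.5),              # half-inactivation voltage
            (-40.0, 1 / (1 + E)),      # one slope-width above
            (-500.0, 1.0),             # fully de-inactivated
        ],
    )
    def test_h_inf(self, unit, V, expected):
        assert h_inf(V, unit) == pytest.approx(expected, abs=1e-12)

    def test_tau_h_peak_and_value(self, unit):
        assert tau_h(-100.0, unit) == pytest.approx(1500.0)
        assert tau_h(-60.0, unit) == pytest.approx(1500.0 / math.cosh(1.0), rel=1e-12)

    def test_tau_h_even_around_peak(self, unit):
        for x in (5.0, 17.3, 40.0, 80.0):
            assert tau_h(-100.0 + x, unit) == pytest.approx(
                tau_h(-100.0 - x, unit), rel=1e-12
            )

    @pytest.mark.parametrize(
        "V, expected",
        [(-50.0, 0.0), (0.0, 1.0), (-25.0, 0.5), (-60.0, 0.0), (10.0, 1.0)],
    )
    def test_rate(self, unit, V, expected):
        assert rate(V, unit) == pytest.approx(expected)

    def test_monotonicity_on_grid(self, unit):
        V = np.linspace(-120.0, 60.0, 721)
        assert np.all(np.diff(m_inf(V, unit)) > 0)
        assert np.all(np.diff(h_inf(V, unit)) < 0)
        assert np.all(np.diff(rate(V, unit)) >= 0)


class TestSynapticCurrent:
    def _state(self, V):
        return NetworkState(t=0.0, V=np.asarray(V, float), h=np.full(4, 0.5))

    def test_empty_network_zero_current(self):
        net = NetworkConfig(b=np.zeros((4, 4)))
        s = self._state([-40.0, -65.0, -65.0, -65.0])
        assert synaptic_current(0, s, net, np.zeros(4)) == 0.0

    def test_drive_term(self):
        # d (V - E_ex) = 0.5 * (-40 + 10) = -15 pA
        net = NetworkConfig(b=np.zeros((4, 4)))
        s = self._state([-40.0, -65.0, -65.0, -65.0])
        d = np.array([0.5, 0.0, 0.0, 0.0])
        assert synaptic_current(0, s, net, d) == pytest.approx(-15.0)

    def test_inhibitory_input_term(self):
        # one input at f = 0.5, weight 1: -15 + 0.5 * (-40 + 90) = +10 pA
        b = np.zeros((4, 4))
        b[2, 0] = 1.0  # left extensor -> left flexor
        net = NetworkConfig(b=b)
        s = self._state([-40.0, -65.0, -25.0, -65.0])  # f(-25) = 0.5
        d = np.array([0.5, 0.0, 0.0, 0.0])
        assert synaptic_current(0, s, net, d) == pytest.approx(10.0)

    def test_index_out_of_range(self):
        net = NetworkConfig()
        s = self._state([-65.0] * 4)
        with pytest.raises(IndexError):
            synaptic_current(4, s, net, np.zeros(4))


class TestDerivatives:
    def test_leak_equilibrium(self):
        p = UnitParams(g_NaP=0.0)
        net = NetworkConfig(b=np.zeros((4, 4)), units=(p,) * 4)
        drv = DriveConfig.uncoupled(0.0, 0.0, 0.0)
        s = NetworkState(t=0.0, V=np.full(4, -65.0), h=np.full(4, 0.5))
        dV, _, _ = derivatives(s, net, drv)
        assert np.allclose(dV, 0.0, atol=1e-14)

    def test_gate_steady_state(self, bilateral):
        V = np.array([-30.0, -55.0, -70.0, -42.0])
        h = np.array([h_inf(v, bilateral.units[i]) for i, v in enumerate(V)])
        s = NetworkState(t=0.0, V=V, h=h)
        _, dh, _ = derivatives(s, bilateral, DriveConfig.symmetric(0.5))
        assert np.allclose(dh, 0.0, atol=1e-15)

    def test_current_breakdown_consistent(self, bilateral):
        s = NetworkState(
            t=0.0, V=np.array([-30.0, -65.0, -50.0, -45.0]), h=np.full(4, 0.4)
        )
        dV, _, cur = derivatives(s, bilateral, DriveConfig.symmetric(0.4))
        C = np.array([u.C for u in bilateral.units])
        assert np.allclose(cur.total, -dV * C, rtol=0, atol=1e-10)

    def test_against_symbolic_oracle(self, bilateral, rng):
        """Agreement with an independent sympy evaluation to 12 digits."""
        import sympy as sp

        V1, h1, d1, bsum = sp.symbols("V h d s")
        p = bilateral.units[0]
        m = 1 / (1 + sp.exp((V1 - p.V_mNaP) / p.k_mNaP))
        hinf = 1 / (1 + sp.exp((V1 - p.V_hNaP) / p.k_hNaP))
        tau = p.tau_NaP_max / sp.cosh((V1 - p.V_tauNaP) / p.k_tauNaP)
        I_L = p.g_L * (V1 - p.E_L)
        I_NaP = p.g_NaP * m * h1 * (V1 - p.E_Na)
        I_syn = d1 * (V1 - bilateral.E_ex) + bsum * (V1 - bilateral.E_inh)
        dV_expr = -(I_L + I_NaP + I_syn) / p.C
        dh_expr = (hinf - h1) / tau

        drv = DriveConfig.symmetric(0.45)
        d = drv.effective_drives()
        for _ in range(20):
            V = rng.uniform(-80, 10, size=4)
            h = rng.uniform(0, 1, size=4)
            s = NetworkState(t=0.0, V=V, h=h)
            dV, dh, _ = derivatives(s, bilateral, drv)
            f = np.array([rate(V[j], bilateral.units[j]) for j in range(4)])
            for i in range(4):
                subs = {
                    V1: V[i],
                    h1: h[i],
                    d1: d[i],
                    bsum: float(np.dot(bilateral.b[:, i], f)),
                }
                exp_dV = float(sp.N(dV_expr.subs(subs), 30))
                exp_dh = float(sp.N(dh_expr.subs(subs), 30))
                assert dV[i] == pytest.approx(exp_dV, rel=1e-12)
                assert dh[i] == pytest.approx(exp_dh, rel=1e-12)

    def test_non_finite_state_rejected(self, bilateral):
        s = NetworkState(t=0.0, V=np.full(4, -65.0), h=np.full(4, 0.5))
        s.V[0] = np.nan
        with pytest.raises(ValueError):
            derivatives(s, bilateral, DriveConfig.symmetric(0.3))


class TestFlowInvariants:
    def test_h_flow_stays_in_unit_interval(self, bilateral):
        drv = DriveConfig.symmetric(0.5)
        for V0 in np.linspace(-100.0, 40.0, 29):
            V = np.full(4, V0)
            s0 = NetworkState(t=0.0, V=V, h=np.zeros(4))
            s1 = NetworkState(t=0.0, V=V, h=np.ones(4))
            _, dh0, _ = derivatives(s0, bilateral, drv)
            _, dh1, _ = derivatives(s1, bilateral, drv)
            assert np.all(dh0 >= 0)
            assert np.all(dh1 <= 0)

    def test_voltage_flow_points_inward(self, bilateral):
        lo = min(bilateral.E_inh, bilateral.units[0].E_L)   # -90
        hi = max(bilateral.units[0].E_Na, bilateral.E_ex)   # +50
        drv = DriveConfig.symmetric(0.6)
        for other_V in (-80.0, -40.0, 0.0):
            for h0 in (0.0, 0.5, 1.0):
                V = np.full(4, other_V)
                V[0] = lo
                s = NetworkState(t=0.0, V=V, h=np.full(4, h0))
                dV, _, _ = derivatives(s, bilateral, drv)
                assert dV[0] > 0
                V[0] = hi
                s = NetworkState(t=0.0, V=V, h=np.full(4, h0))
                dV, _, _ = derivatives(s, bilateral, drv)
                assert dV[0] < 0

    def test_left_right_equivariance(self, bilateral, rng):
        """Mirroring state, wiring and drives commutes with the flow."""
        perm = np.array([1, 0, 3, 2])
        drv = DriveConfig(d_F_left=0.3, d_F_right=0.6)
        for _ in range(10):
            s = NetworkState(
                t=0.0, V=rng.uniform(-80, 0, 4), h=rng.uniform(0, 1, 4)
            )
            dV, dh, _ = derivatives(s, bilateral, drv)
            dV_m, dh_m, _ = derivatives(
                s.mirrored(), bilateral.mirrored(), drv.mirrored()
            )
            assert np.allclose(dV_m, dV[perm], rtol=0, atol=1e-12)
            assert np.allclose(dh_m, dh[perm], rtol=0, atol=1e-12)


class TestDriveCoupling:
    def test_coupled_rule(self):
        drv = DriveConfig.symmetric(0.7, D_E0=1.4)
        assert drv.net_extensor_drives() == (pytest.approx(0.7), pytest.approx(0.7))

    def test_zero_flexor_drive_full_extensor(self):
        drv = DriveConfig.symmetric(0.0, D_E0=1.4)
        assert drv.net_extensor_drives() == (1.4, 1.4)

    def test_uncoupled_override(self):
        drv = DriveConfig.uncoupled(1.0, 1.0, 0.7)
        assert drv.net_extensor_drives() == (0.7, 0.7)

    def test_clamp_warns_and_floors(self):
        drv = DriveConfig.symmetric(1.6, D_E0=1.4)
        with pytest.warns(DriveClampWarning):
            left, right = drv.net_extensor_drives()
        assert left == 0.0 and right == 0.0

    def test_effective_drive_vector_order(self):
        drv = DriveConfig(d_F_left=0.2, d_F_right=0.5)
        assert np.allclose(drv.effective_drives(), [0.2, 0.5, 1.2, 0.9])


class TestValidation:
    def test_unit_invariants(self):
        with pytest.raises(ValueError, match="C must be positive"):
            UnitParams(C=0.0)
        with pytest.raises(ValueError, match="k_mNaP"):
            UnitParams(k_mNaP=6.0)
        with pytest.raises(ValueError, match="V_max"):
            UnitParams(V_min=0.0, V_max=-50.0)

    def test_structural_zeros_enforced(self):
        b = NetworkConfig._default_b()
        b[0, 3] = 0.1  # flexor -> contralateral extensor is absent
        with pytest.raises(ValueError, match="structural zero"):
            NetworkConfig(b=b)

    def test_negative_weight_rejected(self):
        b = NetworkConfig._default_b()
        b[0, 1] = -0.2
        with pytest.raises(ValueError, match="non-negative"):
            NetworkConfig(b=b)
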