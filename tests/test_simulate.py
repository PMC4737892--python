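"""Simulators: continuous delay-ODE reference, discrete recursions, and
their mutual consistency."""

import numpy as np
import pytest

from co2exchange import (
    DivergenceError,
    VentilationRecord,
    build_regressor_m3,
    omega_from_theta,
    second_difference,
    simulate_continuous_m3,
    simulate_discrete,
    steady_state_petco2,
    theta_from_physio,
)
from co2exchange.cohort import ProtocolSpec, generate_protocol


def make_record(u, ts_s=5.0, x1=None):
    u = np.asarray(u, dtype=float)
    n = len(u)
    if x1 is None:
        x1 = np.full(n, 40.0)
    return VentilationRecord(
        ts_s=ts_s, t_s=np.arange(n) * ts_s, petco2=x1, vdot=u, subject_id="t"
    )


class TestVentilationRecord:
    def test_nonuniform_sampling_rejected(self):
        t = np.arange(12) * 5.0
        t[6] += 0.5
        with pytest.raises(ValueError, match="uniform"):
            VentilationRecord(5.0, t, np.full(12, 40.0), np.full(12, 2.0))

    def test_negative_ventilation_rejected(self):
        u = np.full(12, 2.0)
        u[3] = -0.1
        with pytest.raises(ValueError):
            make_record(u)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            make_record(np.full(5, 2.0))


class TestContinuousSimulator:
    def test_steady_state_hyperbola(self, median_physio):
        """At constant ventilation the alveolar tension settles on
        x1 = lam*VCO2/u regardless of volumes, flow, and delays."""
        out = simulate_continuous_m3(
            median_physio, u_fn=lambda t: 2.24, x1_0=40.0,
            duration_s=7200.0, dt_s=0.1,
        )
        target = steady_state_petco2(0.12, 2.24)
        assert target == pytest.approx(46.23, abs=0.01)
        assert abs(out.x1[-1] - target) / target < 1e-3
        # venous offset theta4/theta3 at equilibrium
        th = theta_from_physio(median_physio)
        assert abs(out.x2[-1] - (out.x1[-1] + th.theta4 / th.theta3)) < 0.05

    def test_fixed_point_initial_condition(self, median_physio):
        u = 2.24
        x1_ss = steady_state_petco2(0.12, u)
        out = simulate_continuous_m3(
            median_physio, u_fn=lambda t: u, x1_0=x1_ss,
            duration_s=600.0, dt_s=0.1,
        )
        assert np.max(np.abs(out.x1 - x1_ss)) < 1e-6

    def test_apnea_accumulates_co2(self, median_physio):
        """With u = 0 there is no elimination pathway: x1 rises steadily."""
        out = simulate_continuous_m3(
            median_physio, u_fn=lambda t: 0.0, x1_0=40.0,
            duration_s=1800.0, dt_s=0.1,
        )
        tail = out.x1[len(out.x1) // 2:]
        assert np.all(np.diff(tail) > 0)
        assert out.x1[-1] > 60.0

    def test_steady_state_decreasing_in_ventilation(self, median_physio):
        finals = []
        for u in (1.5, 2.5, 3.5):
            out = simulate_continuous_m3(
                median_physio, u_fn=lambda t, u=u: u, x1_0=45.0,
                duration_s=3600.0, dt_s=0.2,
            )
            finals.append(out.x1[-1])
        assert finals[0] > finals[1] > finals[2]

    def test_invalid_steps_rejected(self, median_physio):
        with pytest.raises(ValueError):
            simulate_continuous_m3(median_physio, duration_s=0.0)


class TestSecondDifference:
    def test_annihilates_affine(self):
        x = 3.0 + 2.0 * np.arange(10)
        for k in range(8):
            assert second_difference(x, k, ts=1.0) == 0.0

    def test_exact_for_quadratic(self):
        ts = 0.5
        x = (np.arange(10) * ts) ** 2
        assert second_difference(x, 3, ts) == pytest.approx(2.0)

    def test_hand_value(self):
        assert second_difference(np.array([1.0, 4.0, 9.0]), 0, 1.0) == pytest.approx(2.0)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            second_difference(np.array([1.0, 2.0, 3.0]), 1, 1.0)


class TestRegressor:
    def test_constant_series_zero_input(self):
        x1 = np.full(10, 5.0)
        u = np.zeros(10)
        psi = build_regressor_m3(x1, u, 4, 2, ts=1.0)
        assert psi == pytest.approx([0, 0, 0, 0, 1])

    def test_linear_ramp_zero_input(self):
        ts = 1.0
        x1 = np.arange(1, 11) * ts
        u = np.zeros(10)
        psi = build_regressor_m3(x1, u, 4, 0, ts)
        assert psi == pytest.approx([0.0, -1.0, 0.0, 0.0, 1.0])

    def test_constant_series_constant_input(self):
        psi = build_regressor_m3(np.full(10, 3.0), np.full(10, 2.0), 4, 1, ts=1.0)
        assert psi == pytest.approx([0, 0, -6.0, 0, 1])

    def test_history_rule_holds_first_sample(self):
        x1 = np.arange(1.0, 11.0)
        psi = build_regressor_m3(x1, np.zeros(10), 2, 5, ts=1.0)
        # k - tau < 0 -> delayed sample held at x1[0]
        assert psi[3] == x1[0] - x1[2]

    def test_index_guard(self):
        with pytest.raises(IndexError):
            build_regressor_m3(np.arange(5.0), np.zeros(5), 4, 0, 1.0)


class TestDiscreteSimulator:
    def test_self_consistency_bit_identical(self, median_theta):
        """A record produced by the recursion is reproduced exactly when
        simulated again from the same parameters and seeds."""
        prot = generate_protocol(ProtocolSpec(seed=5))
        rec0 = make_record(prot.vdot, x1=np.full(len(prot.vdot), 46.0))
        x = simulate_discrete("M3", median_theta, rec0, init=(46.0, 46.0))
        rec = make_record(prot.vdot, x1=x)
        x2 = simulate_discrete("M3", median_theta, rec)
        np.testing.assert_array_equal(x, x2)

    def test_steady_state_constant_output(self, median_theta):
        u = 2.24
        x_ss = steady_state_petco2(0.12, u)
        rec = make_record(np.full(60, u), x1=np.full(60, x_ss))
        x = simulate_discrete("M3", median_theta, rec)
        assert np.max(np.abs(x - x_ss)) < 1e-9

    def test_m1_steady_state(self, median_physio, constants):
        from co2exchange import omega_m1_from_physio

        w = omega_m1_from_physio(median_physio, constants)
        u = 2.24
        x_ss = steady_state_petco2(0.12, u)
        rec = make_record(np.full(60, u), x1=np.full(60, x_ss))
        x = simulate_discrete("M1", w, rec)
        assert np.max(np.abs(x - x_ss)) < 1e-9

    def test_divergence_raises_with_index(self):
        # unstable coefficients: enormous rate constants at 5-s sampling
        from co2exchange import ThetaParams

        th = ThetaParams(50.0, 90.0, 40.0, 400.0, tau=1)
        rec = make_record(np.full(30, 3.0), x1=np.full(30, 40.0))
        with pytest.raises(DivergenceError) as err:
            simulate_discrete("M3", th, rec)
        assert err.value.sample_index is not None

    def test_m3_requires_tau(self, median_theta):
        rec = make_record(np.full(20, 2.0))
        w = omega_from_theta(median_theta, "M3")
        with pytest.raises(ValueError, match="tau"):
            simulate_discrete("M3", w, rec)

    def test_model_params_mismatch(self, median_theta):
        rec = make_record(np.full(20, 2.0))
        w = omega_from_theta(median_theta, "M2")
        with pytest.raises(ValueError):
            simulate_discrete("M3", w, rec, tau=2)


class TestDiscreteContinuousConsistency:
    def test_first_order_convergence(self, median_physio):
        """The forward-difference recursion converges to the delay-ODE
        solution with observed order ~1 as the sampling step is halved."""
        prot = generate_protocol(ProtocolSpec(seed=3, n_segments=3, duration_min=20.0))
        dur = prot.t_s[-1]
        ref = simulate_continuous_m3(
            median_physio, u_fn=prot.u_fn, x1_0=46.0, duration_s=dur, dt_s=0.05
        )
        errs = []
        for ts in (5.0, 2.5, 1.25):
            n = int(dur / ts) + 1
            t = np.arange(n) * ts
            u = np.array([prot.u_fn(ti) for ti in t])
            th = theta_from_physio(median_physio, ts_s=ts)
            stride = int(round(ts / 0.05))
            x1c = ref.x1[::stride][:n]
            rec = VentilationRecord(ts, t, np.full(n, 46.0), u)
            xh = simulate_discrete(
                "M3", th, rec, init=(x1c[0], x1c[1]), tau=th.tau
            )
            errs.append(np.max(np.abs(xh - x1c)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 0.9)

    def test_cohort_range_stability_smoke(self):
        """24-min discrete simulations stay in (0, 200) mmHg across the
        reported interquartile parameter boxes."""
        from co2exchange.cohort import draw_physio_from_iqr, PETCO2_TARGET
        from co2exchange.core import RespiratoryConstants

        c = RespiratoryConstants()
        rng = np.random.default_rng(0)
        prot = generate_protocol(ProtocolSpec(seed=1))
        for _ in range(10):
            p = draw_physio_from_iqr(rng)
            th = theta_from_physio(p, ts_s=5.0)
            scale = (c.lam * p.VCO2 / PETCO2_TARGET) / prot.vdot.mean()
            x0 = steady_state_petco2(p.VCO2, prot.u_fn(0.0) * scale, c)
            rec = make_record(prot.vdot * scale, x1=np.full(len(prot.vdot), x0))
            x = simulate_discrete("M3", th, rec, init=(x0, x0))
            assert np.all((x > 0) & (x < 200))
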