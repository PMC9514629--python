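"""Rate scaling, maturity integration and marker mapping."""

import numpy as np
import pytest

from osteofuzz.controller import CellInputs, ControllerParams
from osteofuzz.dynamics import (
    DynamicsParams,
    Schedule,
    integrate_maturity,
    marker_value,
    maturity_closed_form,
    physical_rates,
    scale_rate,
    simulate_study,
)
from osteofuzz.errors import DesignError, InputError
from osteofuzz.params import ModelParameters


class TestScaleRate:
    @pytest.mark.parametrize(
        "x, alpha_s, alpha_i, expected",
        [
            (0.5, 0.3, 0.9, 1.0),  # both branches meet at 1
            (1.0, 0.4, 0.0, 1.4),
            (0.0, 0.0, 0.6, 0.4),
            (0.0, 0.0, 1.0, 0.0),  # exact lower edge
        ],
    )
    def test_values(self, x, alpha_s, alpha_i, expected):
        assert scale_rate(x, alpha_s, alpha_i) == pytest.approx(expected)

    def test_clamped_below_zero(self):
        assert scale_rate(0.0, 0.0, 1.5) == 0.0

    def test_continuous_at_physiological_rate(self):
        eps = 1e-9
        lo = scale_rate(0.5 - eps, 0.9, 0.1)
        hi = scale_rate(0.5 + eps, 0.9, 0.1)
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_branch_flag_swaps_coefficients(self):
        assert scale_rate(1.0, 0.4, 0.2) == pytest.approx(1.4)
        assert scale_rate(
            1.0, 0.4, 0.2, stimulatory_branch_high=False
        ) == pytest.approx(1.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            scale_rate(1.5, 0.5, 0.5)


class TestPhysicalRates:
    def test_physiological_rate_is_one_over_td(self):
        dp = DynamicsParams(t_d=21.0)
        r_e, r_l = physical_rates(0.5, 0.5, dp)
        assert r_e == pytest.approx(1 / 21)
        assert r_l == pytest.approx(1 / 21)

    def test_stimulated_and_clamped_rates(self):
        dp = DynamicsParams(t_d=20.0, alpha_es=1.0, alpha_li=1.0)
        r_e, r_l = physical_rates(1.0, 0.0, dp)
        assert r_e == pytest.approx(0.1)  # S(1) = 2 at alpha_es = 1
        assert r_l == 0.0


class TestMaturity:
    def test_closed_form_worked_example(self):
        """M_t=0.4, T_d=20, r_e=2 r0, r_l=r0/2: 0.8 at day 8, 0.9 at day 12."""
        r0 = 1 / 20
        args = dict(r_e=2 * r0, r_l=r0 / 2, m_t=0.4, t_d=20.0)
        assert maturity_closed_form(0.0, **args) == 0.0
        assert maturity_closed_form(8.0, **args) == pytest.approx(0.8)
        assert maturity_closed_form(12.0, **args) == pytest.approx(0.9)

    def test_physiological_rates_reach_one_at_td(self):
        r0 = 1 / 21
        assert maturity_closed_form(21.0, r0, r0, 0.4, 21.0) == pytest.approx(1.0)

    def test_continuity_at_phase_switch(self):
        r0 = 1 / 20
        args = dict(r_e=2 * r0, r_l=r0 / 2, m_t=0.4, t_d=20.0)
        t_e = 8.0
        eps = 1e-9
        assert maturity_closed_form(t_e - eps, **args) == pytest.approx(
            maturity_closed_form(t_e + eps, **args), abs=1e-6
        )

    def test_euler_matches_closed_form_constant_inputs(self, cparams):
        """Constant stimulatory inputs: discrete trajectory equals the
        closed form within the first-order Euler bound."""
        from osteofuzz.controller import infer_rates

        dp = DynamicsParams(m_t=0.4, t_d=20.0, alpha_es=0.8, alpha_li=0.7)
        inputs = CellInputs(mg=8.0)
        schedule = Schedule.constant(inputs, horizon_h=20 * 24.0)
        times, traj = integrate_maturity(schedule, cparams, dp, dt=1.0)
        f = infer_rates(inputs, cparams)
        r_e, r_l = physical_rates(f.f_e, f.f_l, dp)
        bound = max(r_e, r_l) * 1.0 / 24.0  # dt * max rate
        for t_h, m in zip(times[:: 48], traj[:: 48]):
            expected = maturity_closed_form(t_h / 24.0, r_e, r_l, 0.4, 20.0)
            assert m == pytest.approx(expected, abs=bound + 1e-12)

    def test_trajectory_monotone_and_bounded(self, cparams):
        dp = DynamicsParams(m_t=0.3, t_d=10.0, alpha_es=1.0)
        schedule = Schedule.pulse(
            CellInputs(il8=100.0), duration_h=48.0, horizon_h=21 * 24.0
        )
        _, traj = integrate_maturity(schedule, cparams, dp, dt=1.0)
        assert np.all(np.diff(traj) >= -1e-15)
        assert traj[0] == 0.0
        assert np.all((traj >= 0.0) & (traj <= 1.0))

    def test_higher_alpha_es_speeds_maturation(self, cparams):
        schedule = Schedule.constant(CellInputs(mg=8.0), horizon_h=7 * 24.0)
        final = []
        for a in (0.2, 0.8):
            dp = DynamicsParams(m_t=0.5, t_d=21.0, alpha_es=a)
            _, traj = integrate_maturity(schedule, cparams, dp, dt=1.0)
            final.append(traj[-1])
        assert final[1] > final[0]

    def test_maturity_based_switching_variant(self, cparams):
        """With maturity-based switching the late phase starts when the
        state reaches M_t; at stimulated early rates this happens before
        T_e, so the final maturity differs from the time-based default
        whenever r_l != r_e, and the two variants agree at physiological
        rates where T_e and M = M_t coincide."""
        base = dict(m_t=0.4, t_d=20.0, alpha_es=1.0, alpha_li=1.0)
        schedule = Schedule.constant(CellInputs(mg=8.0), horizon_h=12 * 24.0)
        _, by_time = integrate_maturity(
            schedule, cparams, DynamicsParams(**base), dt=1.0
        )
        _, by_maturity = integrate_maturity(
            schedule, cparams, DynamicsParams(**base, phase_switch="maturity"), dt=1.0
        )
        # stimulated early rate reaches M_t before T_e, so the slow late
        # phase starts earlier under maturity-based switching
        assert by_maturity[-1] < by_time[-1]

        physio = Schedule.constant(CellInputs.physiological(), 20 * 24.0)
        for variant in ("time", "maturity"):
            _, traj = integrate_maturity(
                physio, cparams, DynamicsParams(m_t=0.4, t_d=20.0, phase_switch=variant)
            )
            assert traj[-1] == pytest.approx(1.0)

    def test_dt_larger_than_segment_rejected(self, cparams):
        schedule = Schedule.pulse(
            CellInputs(tnf=1.0), duration_h=48.0, horizon_h=168.0
        )
        with pytest.raises(DesignError):
            integrate_maturity(schedule, cparams, DynamicsParams(), dt=96.0)

    def test_schedule_must_be_contiguous(self):
        from osteofuzz.dynamics import Segment

        with pytest.raises(DesignError):
            Schedule(
                (
                    Segment(0.0, 48.0, CellInputs()),
                    Segment(72.0, 168.0, CellInputs()),
                )
            )


class TestMarkers:
    def test_baseline_detectable_at_zero_maturity(self, theta):
        t = theta.replace(beta_alp=0.5, n_alp=1.0, k_alp_1=1.0)
        assert marker_value(0.0, "ALP", 1, t) == pytest.approx(0.5)

    def test_nonlinearity_and_correction(self, theta):
        t = theta.replace(beta_oc=0.5, n_oc=2.0, k_oc_2=2.0)
        assert marker_value(0.5, "OC", 2, t) == pytest.approx(2.0)

    def test_alp_plateaus_above_threshold(self, theta):
        t = theta.replace(m_t=0.4)
        assert marker_value(0.6, "ALP", 1, t) == marker_value(0.9, "ALP", 1, t)

    def test_late_markers_strictly_increasing(self, theta):
        values = [marker_value(m, "ARS", 3, theta) for m in (0.2, 0.5, 0.9)]
        assert values[0] < values[1] < values[2]

    def test_unknown_marker_rejected(self, theta):
        with pytest.raises(InputError):
            marker_value(0.5, "BMP", 1, theta)

    def test_unknown_study_correction_rejected(self, theta):
        from osteofuzz.errors import ParameterError

        with pytest.raises(ParameterError):
            marker_value(0.5, "OC", 5, theta)  # no OC factor for study 5


class TestSimulateStudy:
    def test_study_1_item_count(self, designs, theta):
        items = simulate_study(designs[1], theta)
        assert len(items) == 6  # 3 Mg conditions x ALP x 2 days

    def test_relative_control_is_unity(self, designs, theta):
        items = simulate_study(designs[4], theta)
        ctr = [i for i in items if i.condition == "ctr"]
        assert ctr and all(i.value == pytest.approx(1.0) for i in ctr)

    def test_all_builtin_designs_simulable(self, designs, theta):
        for design in designs.values():
            items = simulate_study(design, theta)
            assert len(items) == len(design.conditions) * len(design.measurements)
            assert all(i.value > 0 for i in items)
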