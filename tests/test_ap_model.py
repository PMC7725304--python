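"""Unit and property tests for the mechanistic AP/turgor model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmhapto.ap_model import (
    APEvent,
    CellState,
    ModelParams,
    StimulusProtocol,
    dropout_pattern,
    efflux_rate,
    influx_rate,
    initial_state,
    operating_range,
    potassium_equilibrium_voltage,
    recovery_time,
    resting_pressure,
    simulate,
    single_ap_summary,
    step,
    whole_cell_current,
)
from dmhapto.exceptions import IntegrationError


class TestNernstVoltage:
    @pytest.mark.parametrize(
        "k_apo, k_cell, rtf, expected",
        [
            (1.0, 100.0, 25.0, 25.0 * math.log(0.01)),  # -115.13 mV
            (50.0, 50.0, 25.0, 0.0),
            (0.3, 0.3, 71.0, 0.0),
        ],
    )
    def test_closed_form(self, k_apo, k_cell, rtf, expected):
        assert potassium_equilibrium_voltage(k_apo, k_cell, rtf) == pytest.approx(
            expected, abs=1e-12
        )

    def test_ten_fold_shift_is_ln10(self):
        shift = potassium_equilibrium_voltage(10, 100, 25) - potassium_equilibrium_voltage(
            1, 100, 25
        )
        assert shift == pytest.approx(25 * math.log(10), abs=1e-10)  # 57.56 mV

    def test_antisymmetric(self):
        assert potassium_equilibrium_voltage(3, 80, 25) == pytest.approx(
            -potassium_equilibrium_voltage(80, 3, 25)
        )

    @pytest.mark.parametrize("bad", [(0, 100), (100, 0), (-1, 5)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            potassium_equilibrium_voltage(bad[0], bad[1], 25)


class TestFluxes:
    def test_efflux_at_rest_composition(self, default_params):
        state = initial_state(default_params)
        state.trigger = 1
        # k * (V_excited - E_K0) = 1 * (-60 + 115.13) mV -> 55.13 mM/s
        expected = default_params.k * (-60.0 - 25.0 * math.log(0.01))
        assert efflux_rate(state, default_params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(55.13, abs=0.01)

    def test_efflux_zero_when_not_triggered(self, default_params):
        state = initial_state(default_params)
        assert efflux_rate(state, default_params) == 0.0

    def test_efflux_zero_at_zero_driving_force(self, default_params):
        # Composition where E_K equals V_excited: K_apo/K_cell = exp(-60/25)
        k_cell = 50.0
        k_apo = k_cell * math.exp(-60.0 / 25.0)
        state = CellState(0.0, k_cell, k_apo, k_cell, k_apo, 1.0, trigger=1)
        assert efflux_rate(state, default_params) == pytest.approx(0.0, abs=1e-12)

    def test_influx_zero_at_exact_rest(self, default_params):
        # v0 resolves so that rest is a fixed point of the uptake drive.
        state = initial_state(default_params)
        assert influx_rate(state, default_params) == 0.0

    def test_influx_depleted_state(self, nominal_v0_params):
        state = CellState(0.0, 68.0, 3.13, 68.0, 3.13, 1.0)
        e_k = 25.0 * math.log(3.13 / 68.0)
        expected = 0.01 * (-170.0 - e_k + 55.0)  # ~ -0.38 mM/s
        got = influx_rate(state, nominal_v0_params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-0.38, abs=0.01)

    def test_influx_zero_when_triggered(self, default_params):
        state = CellState(0.0, 68.0, 3.13, 68.0, 3.13, 1.0, trigger=1,
                          excited_until=1.0)
        assert influx_rate(state, default_params) == 0.0

    def test_influx_clamped_past_equilibrium(self, default_params):
        # Overshoot composition: gradient steeper than rest -> drive positive
        # -> clamp keeps the uptake pathway from running as an efflux.
        state = CellState(0.0, 110.0, 0.2, 110.0, 0.2, 1.0)
        assert influx_rate(state, default_params) == 0.0


class TestStep:
    def test_hand_euler_one_step(self, default_params):
        state = initial_state(default_params)
        state.trigger = 1
        state.excited_until = 1.0
        nxt = step(state, default_params)
        j = default_params.k * (-60.0 - 25.0 * math.log(0.01))
        assert nxt.k_cell == pytest.approx(100.0 - j * 0.05, rel=1e-14)   # 97.24
        assert nxt.k_apo == pytest.approx(1.0 + j * 0.05 / 15.0, rel=1e-14)  # 1.184
        assert nxt.a_cell == nxt.k_cell and nxt.a_apo == nxt.k_apo

    def test_zero_flux_leaves_state_unchanged(self, default_params):
        state = initial_state(default_params)
        nxt = step(state, default_params)
        assert nxt.t == pytest.approx(0.05)
        assert (nxt.k_cell, nxt.k_apo, nxt.dp) == (state.k_cell, state.k_apo, state.dp)

    def test_conservation_single_step(self, default_params):
        state = CellState(0.0, 73.0, 2.5, 73.0, 2.5, 1.0, trigger=1,
                          excited_until=10.0)
        nxt = step(state, default_params)
        before = state.k_cell + 15.0 * state.k_apo
        after = nxt.k_cell + 15.0 * nxt.k_apo
        assert after == pytest.approx(before, rel=1e-14)

    def test_negative_concentration_raises(self):
        params = ModelParams(dt=50.0)  # absurdly large Euler step
        state = initial_state(params)
        state.trigger = 1
        state.excited_until = 100.0
        with pytest.raises(IntegrationError):
            step(state, params)


class TestRestingPressure:
    def test_default_composition_is_about_five_bar(self, default_params):
        dp0 = resting_pressure(default_params)
        assert dp0 == pytest.approx(4.776, abs=0.001)
        assert dp0 == pytest.approx(5.0, rel=0.1)

    def test_equal_compositions_give_zero(self):
        p = ModelParams(k_cell0=1.0, k_apo0=1.0, a_cell0=1.0, a_apo0=1.0)
        assert resting_pressure(p) == 0.0


class TestWholeCellCurrent:
    def test_fifty_femtoliter_cell(self):
        i = whole_cell_current(1.0, 50e-15, 50.0)
        assert i == pytest.approx(2.412e-10, rel=1e-3)  # 241 pA ~ 250 pA
        assert i * 1e12 == pytest.approx(250.0, rel=0.1)

    def test_zero_driving_force(self):
        assert whole_cell_current(1.0, 50e-15, 0.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            whole_cell_current(1.0, 0.0, 50.0)


class TestProtocolAndEvents:
    def test_protocol_requires_increasing_times(self):
        with pytest.raises(ValueError):
            StimulusProtocol((0.0, 0.0))
        with pytest.raises(ValueError):
            StimulusProtocol((2.0, 1.0))
        with pytest.raises(ValueError):
            StimulusProtocol((-1.0,))

    def test_periodic_expansion(self):
        p = StimulusProtocol.periodic(0.05, 3)
        assert p.stimulus_times == (0.0, 20.0, 40.0)

    def test_event_dropout_classification(self):
        assert APEvent(0.0, False, 0.4).dropout
        assert not APEvent(0.0, False, 0.9, skipped=True).dropout
        assert not APEvent(0.0, True, 0.9).dropout


class TestSimulate:
    def test_single_ap_headline_changes(self, default_params):
        s = single_ap_summary(default_params)
        # ~30% cytosolic K+ loss, apoplastic K+ to ~3x initial, ~33% turgor loss
        assert s["k_cell_decrease_pct"] == pytest.approx(30.0, rel=0.15)
        assert s["k_apo_final_pct_of_initial"] == pytest.approx(300.0, rel=0.15)
        assert s["dp_decrease_pct"] == pytest.approx(33.0, rel=0.15)
        assert s["k_apo_increment_pct"] == pytest.approx(
            s["k_apo_final_pct_of_initial"] - 100.0
        )

    def test_no_stimuli_stays_at_rest(self, default_params):
        traj = simulate(default_params, None, t_end=5.0)
        assert np.allclose(traj.k_cell, 100.0)
        assert np.allclose(traj.rel_dp, 1.0)
        assert traj.events == []

    def test_sub_threshold_stimulus_is_dropout(self, default_params):
        params = default_params.with_(turgor_threshold=0.7)
        traj = simulate(params, StimulusProtocol((0.0, 1.1)), t_end=3.0)
        assert traj.events[0].fired
        assert traj.events[1].dropout
        assert traj.events[1].rel_dp_at_stimulus < 0.7

    def test_stimulus_during_excited_phase_is_skipped(self, default_params):
        traj = simulate(default_params, StimulusProtocol((0.0, 0.5)), t_end=2.0)
        assert traj.events[0].fired
        assert traj.events[1].skipped and not traj.events[1].dropout

    def test_stimulus_at_t_end_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, StimulusProtocol((5.0,)), t_end=5.0)

    def test_monotone_during_excited_phase(self, default_params):
        traj = simulate(default_params, StimulusProtocol((0.0,)), t_end=1.0)
        assert np.all(np.diff(traj.k_cell) < 0)
        assert np.all(np.diff(traj.k_apo) > 0)
        assert np.all(np.diff(traj.dp) < 0)

    def test_anion_mirrors_potassium(self, default_params):
        traj = simulate(default_params, StimulusProtocol((0.0, 30.0)), t_end=60.0)
        assert np.array_equal(traj.k_cell, traj.a_cell)
        assert np.array_equal(traj.k_apo, traj.a_apo)

    def test_euler_oracle_three_steps(self, default_params):
        """simulate matches an independently hand-coded Euler recurrence."""
        p = default_params
        traj = simulate(p, StimulusProtocol((0.0,)), t_end=3 * p.dt)
        kc, ka = p.k_cell0, p.k_apo0
        rt_j = p.rt_over_f * 1e-3 * 96485.33212
        dp = rt_j * 2 * (kc - ka) / 1e5
        for _ in range(3):
            j = p.k * (p.v_excited - p.rt_over_f * math.log(ka / kc))
            kc, ka = kc - j * p.dt, ka + j * p.dt / p.alpha
            dp -= 2 * rt_j * (1 + 1 / p.alpha) * j * p.dt / 1e5
        assert traj.k_cell[-1] == pytest.approx(kc, rel=1e-12)
        assert traj.k_apo[-1] == pytest.approx(ka, rel=1e-12)
        assert traj.dp[-1] == pytest.approx(dp, rel=1e-12)

    def test_step_halving_first_order_convergence(self, default_params):
        k1 = 100.0 - single_ap_summary(default_params)["k_cell_decrease_pct"]
        k2 = 100.0 - single_ap_summary(default_params.with_(dt=0.025))[
            "k_cell_decrease_pct"
        ]
        assert abs(k1 - k2) / k2 < 0.01

    @given(
        beta=st.floats(0.002, 0.05),
        alpha=st.floats(2.0, 30.0),
        n_stim=st.integers(1, 3),
    )
    @settings(max_examples=20, deadline=None)
    def test_conservation_and_pressure_consistency(self, beta, alpha, n_stim):
        """Mass conservation and incremental-vs-direct pressure agreement."""
        params = ModelParams(beta=beta, alpha=alpha)
        protocol = StimulusProtocol.periodic(0.2, n_stim)
        traj = simulate(params, protocol, t_end=n_stim * 5.0 + 5.0)
        total_k = traj.k_cell + alpha * traj.k_apo
        assert np.max(np.abs(total_k / total_k[0] - 1.0)) <= 1e-9
        rt_j = params.rt_joule
        direct = rt_j * (traj.k_cell + traj.a_cell - traj.k_apo - traj.a_apo) / 1e5
        assert np.max(np.abs(traj.dp - direct) / np.abs(direct)) <= 1e-6


class TestRecovery:
    def test_beta_time_rescaling(self, default_params):
        """Recovery flux scales with beta: halving beta doubles recovery."""
        t1 = recovery_time(default_params)
        t2 = recovery_time(default_params.with_(beta=0.005))
        assert t2 / t1 == pytest.approx(2.0, rel=0.02)

    def test_five_fold_beta_reduction_five_fold_slower(self, default_params):
        t1 = recovery_time(default_params)
        t5 = recovery_time(default_params.with_(beta=0.002))
        assert t5 / t1 == pytest.approx(5.0, rel=0.02)

    def test_looser_tolerance_recovers_sooner(self, default_params):
        assert recovery_time(default_params, tol=0.2) < recovery_time(
            default_params, tol=0.01
        )

    def test_deterministic(self, default_params):
        assert recovery_time(default_params) == recovery_time(default_params)

    def test_time_cap_raises(self, default_params):
        with pytest.raises(IntegrationError):
            recovery_time(default_params, tol=1e-6, time_cap=10.0)

    def test_bad_tolerance_rejected(self, default_params):
        with pytest.raises(ValueError):
            recovery_time(default_params, tol=0.0)


class TestOperatingRange:
    def test_low_frequency_band(self, default_params):
        """0.05 Hz stimulation settles into the 51-61% turgor band."""
        res = operating_range(default_params, frequency=0.05, n_stimuli=60)
        assert res["converged"] and not res["dropout_in_final_cycle"]
        assert res["min_pct"] == pytest.approx(51.0, abs=3.0)
        assert res["max_pct"] == pytest.approx(61.0, abs=3.0)
        assert res["min_pct"] < res["max_pct"]

    def test_very_low_frequency_fully_recovers(self, default_params):
        rt = recovery_time(default_params)
        res = operating_range(default_params, frequency=1.0 / (3.0 * rt),
                              n_stimuli=12)
        assert res["max_pct"] == pytest.approx(100.0, abs=0.1)

    def test_too_few_stimuli_rejected(self, default_params):
        with pytest.raises(ValueError):
            operating_range(default_params, frequency=0.05, n_stimuli=5)


class TestDropoutPattern:
    def test_all_fired_at_low_frequency(self, default_params):
        res = dropout_pattern(default_params, frequency=0.05, n_stimuli=30)
        assert res["fraction_fired"] == 1.0
        assert res["longest_failure_run"] == 0

    def test_reduced_uptake_lengthens_dropout_runs(self, default_params):
        """Blocked K+ uptake (smaller beta) gives longer failure runs."""
        ctrl = dropout_pattern(default_params, frequency=0.2, n_stimuli=60)
        blocked = dropout_pattern(default_params.with_(beta=0.002),
                                  frequency=0.2, n_stimuli=60)
        assert blocked["longest_failure_run"] > ctrl["longest_failure_run"]
        assert blocked["fraction_fired"] < ctrl["fraction_fired"]

    def test_tiny_threshold_never_drops_out(self, default_params):
        res = dropout_pattern(default_params.with_(turgor_threshold=1e-6),
                              frequency=0.2, n_stimuli=40)
        assert res["fraction_fired"] == 1.0


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta": 0.0},
            {"beta": 1.5},
            {"alpha": -1.0},
            {"dt": 0.0},
            {"turgor_threshold": 1.0},
            {"v_excited": -200.0},
            {"k_cell0": 0.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_v0_resolves_to_exact_fixed_point(self, default_params):
        e_k0 = 25.0 * math.log(0.01)
        assert default_params.v0 == pytest.approx(e_k0 + 170.0)  # 54.87 mV
        assert default_params.v0 == pytest.approx(55.0, abs=0.2)

    def test_explicit_v0_kept(self, nominal_v0_params):
        assert nominal_v0_params.v0 == 55.0
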