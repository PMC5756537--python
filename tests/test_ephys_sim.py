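import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iclvol.ephys_sim import (
    CellModel,
    ChannelModel,
    CurrentTrace,
    boltzmann_conductance,
    make_ramp_protocol,
    make_step_protocol,
    read_trace,
    simulate_trace,
    write_trace,
)

EREV = -19.0


class TestStepProtocol:
    def test_nineteen_levels_from_plus80_to_minus100(self, step_protocol):
        levels = step_protocol.test_levels_mV
        assert len(levels) == 19
        assert levels[0] == 80.0 and levels[-1] == -100.0
        assert np.allclose(np.diff(levels), -10.0)

    def test_every_sweep_starts_and_ends_at_holding(self, step_protocol):
        for sweep in step_protocol.sweeps:
            assert sweep[0].v0_mV == -30.0
            assert sweep[-1].v1_mV == -30.0

    def test_test_segment_is_200_ms(self, step_protocol):
        for sweep in step_protocol.sweeps:
            assert sweep[step_protocol.test_segment_index].duration_ms == 200.0

    def test_json_round_trip(self, tmp_path, step_protocol):
        from iclvol.ephys_sim import VoltageProtocol

        step_protocol.to_json(tmp_path / "p.json")
        back = VoltageProtocol.from_json(tmp_path / "p.json")
        assert back.sweeps == step_protocol.sweeps
        assert back.test_segment_index == step_protocol.test_segment_index


class TestRampProtocol:
    def test_ramp_spanning_180_mV_lasts_720_ms(self):
        proto = make_ramp_protocol(n_repeats=1)
        up = [s for s in proto.sweeps[0] if s.kind == "ramp" and s.v1_mV > s.v0_mV][0]
        assert up.v1_mV - up.v0_mV == 180.0
        assert up.duration_ms == pytest.approx(720.0)

    def test_single_repeat_spans_at_least_six_seconds(self):
        proto = make_ramp_protocol(n_repeats=1)
        assert proto.sweep_duration_ms(0) >= 6000.0

    def test_consecutive_onsets_are_6000_ms_apart(self):
        proto = make_ramp_protocol(n_repeats=3)
        segs = proto.sweeps[0]
        onsets, t = [], 0.0
        for s in segs:
            if s.kind == "ramp" and s.v1_mV < s.v0_mV and s.v0_mV == -30.0:
                onsets.append(t)
            t += s.duration_ms
        assert np.allclose(np.diff(onsets), 6000.0)


class TestBoltzmannConductance:
    def test_half_activation_at_midpoint(self):
        m = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV)
        assert boltzmann_conductance(m, -2.0) == pytest.approx(675.0)

    def test_saturates_to_gmax(self):
        m = ChannelModel(1000.0, 0.0, 25.0, erev_mV=EREV)
        assert boltzmann_conductance(m, 0.0 + 10 * 25.0) == pytest.approx(
            1000.0, rel=5e-5
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        vh=st.floats(-60, 60),
        k=st.floats(5, 80),
        v1=st.floats(-120, 120),
        dv=st.floats(0.1, 50),
    )
    def test_monotone_nondecreasing_in_voltage_for_positive_k(self, vh, k, v1, dv):
        m = ChannelModel(1000.0, vh, k, erev_mV=EREV)
        assert boltzmann_conductance(m, v1 + dv) >= boltzmann_conductance(m, v1)


class TestSimulateTrace:
    def test_ohmic_limit_current_linear_in_driving_force(self, step_protocol):
        # k very large -> g ~ gmax/2 at every voltage -> pure resistor
        m = ChannelModel(800.0, 0.0, 1e9, erev_mV=EREV)
        cell = CellModel(iso=m, hypo=m, noise_sd_pA=0.0)
        tr = simulate_trace(cell, step_protocol, "iso")
        expected = cell.capacitance_pF * 400.0 * (tr.v_mV - EREV) * 1e-3
        assert np.allclose(tr.i_pA, expected, rtol=1e-6)

    def test_zero_current_at_reversal(self, step_protocol):
        m = ChannelModel(1350.0, -2.0, 31.0, erev_mV=-30.0)  # Erev at holding
        cell = CellModel(iso=m, hypo=m, noise_sd_pA=0.0)
        tr = simulate_trace(cell, step_protocol, "iso")
        assert np.all(tr.i_pA[tr.v_mV == -30.0] == 0.0)

    def test_same_seed_bit_identical(self, step_protocol):
        m = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV)
        cell = CellModel(iso=m, hypo=m, noise_sd_pA=5.0, seed=42)
        a = simulate_trace(cell, step_protocol, "hypo")
        b = simulate_trace(cell, step_protocol, "hypo")
        assert np.array_equal(a.i_pA, b.i_pA)

    def test_unknown_condition_rejected(self, step_protocol):
        m = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV)
        cell = CellModel(iso=m, hypo=m)
        with pytest.raises(ValueError, match="condition"):
            simulate_trace(cell, step_protocol, "hypertonic")

    def test_switch_condition_moves_iso_toward_hypo(self, step_protocol):
        iso = ChannelModel(300.0, 40.0, 62.0, erev_mV=EREV)
        hypo = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV)
        cell = CellModel(iso=iso, hypo=hypo, noise_sd_pA=0.0,
                         osmotic_transition_tau_s=1.0)
        tr = simulate_trace(cell, step_protocol, "switch")
        ref_iso = simulate_trace(cell, step_protocol, "iso")
        ref_hypo = simulate_trace(cell, step_protocol, "hypo")
        # late in the record the blended current is essentially hypotonic
        assert abs(tr.i_pA[-1] - ref_hypo.i_pA[-1]) < abs(tr.i_pA[-1] - ref_iso.i_pA[-1])

    def test_gating_relaxation_reaches_steady_state_by_window(self, step_protocol):
        fast = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV)
        slow = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV, activation_tau_ms=10.0)
        c_fast = CellModel(iso=fast, hypo=fast, noise_sd_pA=0.0)
        c_slow = CellModel(iso=slow, hypo=slow, noise_sd_pA=0.0)
        a = simulate_trace(c_fast, step_protocol, "iso")
        b = simulate_trace(c_slow, step_protocol, "iso")
        # after >10 tau within the step the relaxing trace matches the instantaneous one
        from iclvol.ephys_fit import step_iv

        iv_a = step_iv(a, step_protocol)
        iv_b = step_iv(b, step_protocol)
        assert np.allclose(iv_a.density_pA_per_pF, iv_b.density_pA_per_pF, rtol=1e-4, atol=1e-6)


def test_trace_csv_round_trip(tmp_path, step_protocol):
    m = ChannelModel(1350.0, -2.0, 31.0, erev_mV=EREV)
    cell = CellModel(iso=m, hypo=m, noise_sd_pA=5.0, seed=7)
    tr = simulate_trace(cell, step_protocol, "hypo")
    write_trace(tr, tmp_path / "t.csv")
    back = read_trace(tmp_path / "t.csv")
    assert np.allclose(back.i_pA, tr.i_pA)
    assert back.capacitance_pF == tr.capacitance_pF
    assert back.condition == "hypo"
    assert back.meta["seed"] == 7


def test_trace_requires_increasing_time():
    with pytest.raises(ValueError, match="increasing"):
        CurrentTrace(
            time_ms=np.array([0.0, 0.0, 1.0]),
            v_mV=np.zeros(3),
            i_pA=np.zeros(3),
            capacitance_pF=10.0,
            condition="iso",
        )
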