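import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iclvol.ephys_sim import (
    CellModel,
    ChannelModel,
    boltzmann_conductance,
    simulate_trace,
)
from iclvol.ephys_fit import (
    IVCurve,
    benjamini_hochberg,
    conductance_transform,
    difference_current,
    estimate_reversal,
    fit_boltzmann,
    fit_difference_boltzmann,
    step_iv,
)
from conftest import EREV, noise_free_iv, rel_err


class TestStepIV:
    def test_noise_free_density_matches_model_conductance_times_driving_force(
        self, step_protocol
    ):
        gmax, vh, k = 1350.0, -2.0, 31.0
        iv = noise_free_iv(gmax, vh, k, step_protocol)
        m = ChannelModel(gmax, vh, k, erev_mV=EREV)
        expected = boltzmann_conductance(m, iv.vm_mV) * (iv.vm_mV - EREV) * 1e-3
        assert np.allclose(iv.density_pA_per_pF, expected, rtol=1e-9)

    def test_zero_conductance_gives_all_zero_curve(self, step_protocol):
        iv = noise_free_iv(0.0, 0.0, 25.0, step_protocol)
        assert np.all(iv.density_pA_per_pF == 0.0)

    def test_19_level_protocol_gives_19_points(self, step_protocol):
        iv = noise_free_iv(1000.0, 0.0, 25.0, step_protocol)
        assert iv.vm_mV.size == 19

    def test_window_outside_test_segment_rejected(self, step_protocol):
        m = ChannelModel(1000.0, 0.0, 25.0, erev_mV=EREV)
        cell = CellModel(iso=m, hypo=m, noise_sd_pA=0.0)
        tr = simulate_trace(cell, step_protocol, "iso")
        with pytest.raises(ValueError, match="window"):
            step_iv(tr, step_protocol, window_ms=(150.0, 250.0))


class TestDifferenceCurrent:
    def test_identical_curves_give_zero(self, step_protocol):
        iv = noise_free_iv(1000.0, 0.0, 25.0, step_protocol, cell_id="c1")
        diff = difference_current(iv, iv)
        assert np.all(diff.density_pA_per_pF == 0.0)
        assert diff.condition == "difference"

    def test_shared_leak_cancels_exactly(self, step_protocol):
        leak = dict(leak=250.0, leak_erev=-10.0)
        iso = noise_free_iv(364.0, 40.0, 62.0, step_protocol, cell_id="c", **leak)
        hypo = noise_free_iv(1350.0, -2.0, 31.0, step_protocol, cell_id="c", **leak)
        iso0 = noise_free_iv(364.0, 40.0, 62.0, step_protocol, cell_id="c")
        hypo0 = noise_free_iv(1350.0, -2.0, 31.0, step_protocol, cell_id="c")
        with_leak = difference_current(hypo, iso)
        without = difference_current(hypo0, iso0)
        assert np.allclose(
            with_leak.density_pA_per_pF, without.density_pA_per_pF, atol=1e-12
        )

    def test_grid_mismatch_is_an_error_not_interpolation(self):
        a = IVCurve(np.array([-10.0, 0.0, 10.0]), np.zeros(3), cell_id="c")
        b = IVCurve(np.array([-10.0, 5.0, 10.0]), np.zeros(3), cell_id="c")
        with pytest.raises(ValueError, match="grid"):
            difference_current(a, b)

    def test_cross_cell_differences_rejected(self, step_protocol):
        a = noise_free_iv(1000.0, 0.0, 25.0, step_protocol, cell_id="c1")
        b = noise_free_iv(1000.0, 0.0, 25.0, step_protocol, cell_id="c2")
        with pytest.raises(ValueError, match="cell"):
            difference_current(a, b)


class TestEstimateReversal:
    def test_exact_for_linear_current(self):
        v = np.arange(-100.0, 81.0, 10.0)
        e_true = -13.7
        iv = IVCurve(v, 0.02 * (v - e_true))
        assert estimate_reversal(iv) == pytest.approx(e_true, abs=1e-12)

    def test_noise_free_difference_reverses_at_model_erev(self, step_protocol):
        iso = noise_free_iv(364.0, 40.0, 62.0, step_protocol, cell_id="c")
        hypo = noise_free_iv(1350.0, -2.0, 31.0, step_protocol, cell_id="c")
        diff = difference_current(hypo, iso)
        assert estimate_reversal(diff, expected_mV=EREV) == pytest.approx(EREV, abs=1.0)

    def test_monotone_positive_curve_has_no_reversal(self):
        v = np.arange(-100.0, 81.0, 10.0)
        iv = IVCurve(v, np.full(v.size, 5.0))
        with pytest.raises(ValueError, match="reverse"):
            estimate_reversal(iv)


class TestConductanceTransform:
    def test_ohmic_curve_gives_constant_conductance(self):
        v = np.arange(-100.0, 81.0, 10.0)
        iv = IVCurve(v, 0.5 * (v - EREV) * 1e-3)  # 0.5 pS/pF resistor
        curve = conductance_transform(iv, EREV)
        assert np.allclose(curve.g_pS_per_pF, 0.5, rtol=1e-12)

    def test_recovers_model_conductance_at_retained_voltages(self, step_protocol):
        gmax, vh, k = 2290.0, 10.0, 25.0
        iv = noise_free_iv(gmax, vh, k, step_protocol)
        curve = conductance_transform(iv, EREV)
        m = ChannelModel(gmax, vh, k, erev_mV=EREV)
        assert np.allclose(
            curve.g_pS_per_pF, boltzmann_conductance(m, curve.vm_mV), rtol=1e-9
        )

    def test_point_at_reversal_is_excluded_not_infinite(self):
        v = np.array([-40.0, EREV, 20.0, 60.0])
        iv = IVCurve(v, np.array([-0.1, 0.0, 0.5, 1.0]))
        curve = conductance_transform(iv, EREV)
        assert EREV not in curve.vm_mV
        assert EREV in curve.excluded_vm_mV
        assert np.all(np.isfinite(curve.g_pS_per_pF))

    def test_all_points_excluded_is_an_error(self):
        iv = IVCurve(np.array([-20.0, -19.0, -18.0]), np.zeros(3))
        with pytest.raises(ValueError, match="exclusion"):
            conductance_transform(iv, EREV, exclusion_half_width_mV=10.0)


class TestFitBoltzmann:
    def test_exact_round_trip_on_model_data(self, step_protocol):
        iv = noise_free_iv(1000.0, 0.0, 25.0, step_protocol)
        fit = fit_boltzmann(conductance_transform(iv, EREV), ci_method="asymptotic")
        assert rel_err(fit.gmax_pS_per_pF, 1000.0) < 1e-6
        assert rel_err(fit.vh_mV, 0.0) < 1e-6
        assert rel_err(fit.k_mV, 25.0) < 1e-6

    def test_too_few_points_rejected(self):
        from iclvol.ephys_fit import ConductanceCurve

        curve = ConductanceCurve(
            np.array([0.0, 20.0, 40.0, 60.0]), np.ones(4), np.array([]), EREV
        )
        with pytest.raises(ValueError, match="at least 5"):
            fit_boltzmann(curve)

    def test_ci_bounds_bracket_estimates(self, step_protocol):
        gmax, vh, k = 1350.0, -2.0, 31.0
        ch = ChannelModel(gmax, vh, k, erev_mV=EREV)
        cell = CellModel(iso=ch, hypo=ch, noise_sd_pA=5.0, seed=11)
        tr = simulate_trace(cell, step_protocol, "hypo")
        iv = step_iv(tr, step_protocol)
        fit = fit_boltzmann(conductance_transform(iv, EREV), n_boot=200, seed=1)
        for name, est in (
            ("gmax_pS_per_pF", fit.gmax_pS_per_pF),
            ("vh_mV", fit.vh_mV),
            ("k_mV", fit.k_mV),
        ):
            lo, hi = fit.ci95[name]
            assert lo <= est <= hi

    def test_parameter_bias_under_noise_below_5_percent(self, step_protocol):
        """200 noisy replicates at 5 pA: mean recovered parameters near truth."""
        gmax, vh, k = 1350.0, -2.0, 31.0
        ch = ChannelModel(gmax, vh, k, erev_mV=EREV)
        fits = []
        for r in range(200):
            cell = CellModel(iso=ch, hypo=ch, noise_sd_pA=5.0, seed=7_000 + r)
            iv = step_iv(simulate_trace(cell, step_protocol, "hypo"), step_protocol)
            f = fit_boltzmann(conductance_transform(iv, EREV), ci_method="asymptotic")
            fits.append((f.gmax_pS_per_pF, f.vh_mV, f.k_mV))
        mean = np.mean(fits, axis=0)
        for est, truth in zip(mean, (gmax, vh, k)):
            assert rel_err(est, truth) < 0.05


class TestFitDifferenceBoltzmann:
    def test_identical_conditions_are_degenerate(self, step_protocol):
        iv = noise_free_iv(1000.0, 0.0, 25.0, step_protocol, cell_id="c")
        with pytest.raises(ValueError, match="degenerate"):
            fit_difference_boltzmann(iv, iv, EREV)

    def test_shared_leak_leaves_fit_unchanged(self, step_protocol):
        kwargs = dict(ci_method="asymptotic")
        leak = dict(leak=300.0, leak_erev=-40.0)
        iso = noise_free_iv(364.0, 40.0, 62.0, step_protocol, cell_id="c", **leak)
        hypo = noise_free_iv(1350.0, -2.0, 31.0, step_protocol, cell_id="c", **leak)
        iso0 = noise_free_iv(364.0, 40.0, 62.0, step_protocol, cell_id="c")
        hypo0 = noise_free_iv(1350.0, -2.0, 31.0, step_protocol, cell_id="c")
        fit_leak = fit_difference_boltzmann(hypo, iso, EREV, **kwargs)
        fit_clean = fit_difference_boltzmann(hypo0, iso0, EREV, **kwargs)
        assert fit_leak.gmax_pS_per_pF == pytest.approx(fit_clean.gmax_pS_per_pF)
        assert fit_leak.vh_mV == pytest.approx(fit_clean.vh_mV)
        assert fit_leak.k_mV == pytest.approx(fit_clean.k_mV)


class TestBenjaminiHochberg:
    def test_hand_computed_three_value_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_ps_stay_equal(self):
        adj = benjamini_hochberg([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    gmax=st.floats(200.0, 3000.0),
    vh=st.floats(-40.0, 60.0),
    k=st.floats(12.0, 60.0),
)
def test_end_to_end_noise_free_identity(step_protocol, gmax, vh, k):
    """simulate -> I-V -> conductance -> fit returns the generating triple."""
    iv = noise_free_iv(gmax, vh, k, step_protocol)
    fit = fit_boltzmann(conductance_transform(iv, EREV), ci_method="asymptotic")
    assert rel_err(fit.gmax_pS_per_pF, gmax) < 1e-6
    assert rel_err(fit.vh_mV, vh) < 1e-6
    assert rel_err(fit.k_mV, k) < 1e-6
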