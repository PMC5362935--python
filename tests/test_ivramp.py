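import warnings

import numpy as np
import pytest

import clhomeo as c
from clhomeo.ivramp import IVCurve, LeakModel


def ramp_sweep(cell, holding=-74.0, duration=2.0, seed=0, **protocol_kw):
    proto = c.RampProtocol([c.Segment(holding, duration, 1.6, 20.0)],
                           protocol_kw.pop("windows", []), 1e-4)
    return c.simulate_sweep(cell, proto, seed=seed, **protocol_kw)


def ohmic_cell(slope=1.0, reversal=0.0, rs=0.0, noise=0.0):
    return c.GroundTruthCell(slope_nS=slope, leak_reversal_mV=reversal,
                             g_cl_rest_pS=0.0, rs_Mohm=rs, noise_sd_pA=noise)


class TestSeriesResistanceCorrection:
    def test_20_mohm_costs_20_mV_per_nA(self):
        sw = c.Sweep(np.arange(3) * 1e-4, np.full(3, -14.0), np.full(3, 1000.0))
        assert np.allclose(c.correct_series_resistance(sw, 20.0), -34.0)

    def test_zero_rs_is_identity(self):
        sw = c.Sweep(np.arange(3) * 1e-4, np.full(3, -50.0), np.full(3, 500.0))
        assert np.allclose(c.correct_series_resistance(sw, 0.0), -50.0)

    def test_recovers_generator_membrane_voltage(self):
        sw = ramp_sweep(ohmic_cell(slope=2.0, reversal=-20.0, rs=25.0))
        v = c.correct_series_resistance(sw, 25.0)
        assert np.max(np.abs(v - sw.truth_v_m_mV)) < 1e-6

    def test_negative_rs_rejected(self):
        sw = c.Sweep(np.arange(3) * 1e-4, np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            c.correct_series_resistance(sw, -1.0)


class TestBuildIV:
    def test_ohmic_sweep_lies_on_unit_line(self):
        sw = ramp_sweep(ohmic_cell())
        v = c.correct_series_resistance(sw, 0.0)
        iv = c.build_iv_from_ramp(sw, v, 0.0, 2.0)
        assert np.allclose(iv.i_pA, iv.v_mV, atol=1e-9)

    def test_sample_count_per_ramp(self):
        # 80 mV of ramp at 1.6 V/s and 10 kHz -> >= 500 samples per half-cycle
        cell = ohmic_cell()
        proto = c.RampProtocol([c.Segment(-40.0, 0.6, 1.6, 10.0)], [], 1e-4)
        sw = c.simulate_sweep(cell, proto, seed=0)
        v = c.correct_series_resistance(sw, 0.0)
        # one monotone 80 mV limb runs between turning points at 75 and 125 ms
        iv = c.build_iv_from_ramp(sw, v, 0.075, 0.125, blank_ms=0.0)
        # 500 samples on the limb; the turning sample itself is excluded
        assert int(np.sum(iv.n_per_bin)) >= 499

    def test_up_down_average_cancels_symmetric_offsets(self):
        # equal and opposite capacitive offsets on the two limbs
        t = np.arange(0, 1.0, 1e-4)
        phase = (t * 20.0) % 1.0
        vcmd = -74.0 + 40.0 * (np.abs(phase - 0.5) * 4 - 1) / 2
        dv = np.gradient(vcmd)
        i = vcmd + 5.0 * np.sign(dv)
        sw = c.Sweep(t, vcmd, i)
        both = c.build_iv_from_ramp(sw, vcmd, 0.0, 1.0, blank_ms=1.0)
        core = (both.v_mV > -90) & (both.v_mV < -58)  # away from ramp extremes
        assert np.allclose(both.i_pA[core], both.v_mV[core], atol=0.15)
        up = c.build_iv_from_ramp(sw, vcmd, 0.0, 1.0, blank_ms=1.0, direction="up")
        assert np.mean(up.i_pA - up.v_mV) == pytest.approx(5.0, abs=0.2)

    def test_too_short_segment_rejected(self):
        sw = ramp_sweep(ohmic_cell())
        v = c.correct_series_resistance(sw, 0.0)
        with pytest.raises(ValueError):
            c.build_iv_from_ramp(sw, v, 0.0, 1e-4)


class TestLeakModel:
    def test_exponential_round_trip(self):
        v = np.linspace(-114.0, -14.0, 101)
        i = -10.0 + 2.0 * np.exp(v / 20.0)
        fit = c.fit_leak_model(IVCurve(v, i), form="exponential")
        assert fit.a_pA == pytest.approx(-10.0, rel=0.01)
        assert fit.b_pA == pytest.approx(2.0, rel=0.01)
        assert fit.c_mV == pytest.approx(20.0, rel=0.01)

    def test_linear_fit_on_unit_line(self):
        v = np.linspace(-50.0, 50.0, 51)
        fit = c.fit_leak_model(IVCurve(v, v.copy()), form="linear")
        assert fit.slope_nS == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept_pA == pytest.approx(0.0, abs=1e-9)

    def test_exponential_form_degenerates_to_line(self):
        v = np.linspace(-94.0, -54.0, 41)
        i = 0.5 * v + 3.0
        fit = c.fit_leak_model(IVCurve(v, i), form="exponential")
        # residual bounded by the curvature a |C| <= 200 mV exponential
        # must carry over a 40 mV span: ~2% of the 20 pA current range
        assert np.max(np.abs(fit.predict(v) - i)) < 0.4

    def test_requires_enough_points_and_unsubtracted_curve(self):
        v = np.linspace(-80, -70, 5)
        with pytest.raises(ValueError):
            c.fit_leak_model(IVCurve(v, v.copy()))
        iv = IVCurve(np.linspace(-80, -60, 21), np.zeros(21), leak_subtracted=True)
        with pytest.raises(ValueError):
            c.fit_leak_model(iv)


class TestSubtractLeak:
    def test_identical_curves_cancel(self):
        v = np.linspace(-94.0, -54.0, 41)
        leak = LeakModel("linear", slope_nS=0.5, intercept_pA=10.0,
                         v_min_mV=-94, v_max_mV=-54)
        iv = IVCurve(v, leak.predict(v))
        out = c.subtract_leak(iv, leak)
        assert np.allclose(out.i_pA, 0.0, atol=1e-12)
        assert out.leak_subtracted

    def test_zero_leak_model_is_identity(self):
        v = np.linspace(-94.0, -54.0, 41)
        zero = LeakModel("linear", slope_nS=0.0, intercept_pA=0.0,
                         v_min_mV=-94, v_max_mV=-54)
        iv = IVCurve(v, np.sin(v / 10.0))
        out = c.subtract_leak(iv, zero)
        assert np.array_equal(out.i_pA, iv.i_pA)

    def test_recovers_agonist_conductance_from_generator(self):
        cell = c.GroundTruthCell(noise_sd_pA=0.0)
        win = c.AgonistWindow(2.2, 4.0, tau_exchange_s=0.05)
        proto = c.RampProtocol([c.Segment(-74.0, 4.0, 1.6, 20.0)], [win], 1e-4)
        sw = c.simulate_sweep(cell, proto, seed=0)
        v = c.correct_series_resistance(sw, cell.rs_Mohm)
        leak_iv = c.build_iv_from_ramp(sw, v, 0.1, 2.1)
        leak = c.fit_leak_model(leak_iv, form="linear")
        ag_iv = c.build_iv_from_ramp(sw, v, 2.7, 4.0)  # ~10 tau after onset
        diff = c.subtract_leak(ag_iv, leak)
        e_cl = cell.cell.e_cl_mV()
        expect = cell.g_ag_max_nS * (diff.v_mV - e_cl)
        assert np.max(np.abs(diff.i_pA - expect)) < 0.12  # residual exchange tail

    def test_model_evaluation_beats_pointwise_trace_subtraction(self):
        # with Rs, the leak and agonist ramps sit at different true voltages;
        # subtracting traces pointwise biases the difference current
        cell = c.GroundTruthCell(slope_nS=2.0, leak_reversal_mV=-60.0,
                                 g_cl_rest_pS=0.0, rs_Mohm=20.0, noise_sd_pA=0.0,
                                 g_ag_max_nS=5.0,
                                 cell=c.CellState(cl_i_mM=30.0))
        win = c.AgonistWindow(2.2, 4.2, tau_exchange_s=1e-3)
        proto = c.RampProtocol([c.Segment(-40.0, 4.2, 1.6, 20.0)], [win], 1e-4)
        sw = c.simulate_sweep(cell, proto, seed=0)
        v = c.correct_series_resistance(sw, cell.rs_Mohm)
        leak_iv = c.build_iv_from_ramp(sw, v, 0.1, 2.1)
        leak = c.fit_leak_model(leak_iv, form="linear")
        ag_iv = c.build_iv_from_ramp(sw, v, 2.4, 4.2)
        e_cl_true = cell.cell.e_cl_mV()
        model_e_rev = c.estimate_reversal_potential(c.subtract_leak(ag_iv, leak))
        # naive: subtract the leak-phase current trace sample-by-sample
        n = int(2.1 / 1e-4)
        naive_i = sw.i_pA[n + int(0.3 / 1e-4):2 * n] - sw.i_pA[int(0.3 / 1e-4):n]
        naive_v = v[n + int(0.3 / 1e-4):2 * n]
        order = np.argsort(naive_v)
        naive_e_rev = float(np.interp(0.0, naive_i[order], naive_v[order]))
        assert abs(model_e_rev - e_cl_true) < 0.2
        assert abs(naive_e_rev - e_cl_true) > 5 * abs(model_e_rev - e_cl_true)


class TestReversalPotential:
    def test_unit_line_reverses_at_zero(self):
        v = np.linspace(-40, 40, 81)
        assert c.estimate_reversal_potential(IVCurve(v, v.copy())) == \
            pytest.approx(0.0, abs=1e-12)

    def test_constructed_root(self):
        v = np.linspace(-60.0, 0.0, 61)
        iv = IVCurve(v, 1.0 * (v + 22.7))
        assert c.estimate_reversal_potential(iv) == pytest.approx(-22.7, abs=1e-9)

    def test_no_crossing_raises(self):
        v = np.linspace(-40, 40, 81)
        with pytest.raises(ValueError):
            c.estimate_reversal_potential(IVCurve(v, v + 100.0))

    def test_multiple_crossings_fall_back_to_local_regression(self):
        rng = np.random.default_rng(0)
        v = np.linspace(-40.0, -5.0, 71)
        i = 0.2 * (v + 22.7) + rng.normal(0, 1.0, len(v))
        with pytest.warns(UserWarning, match="zero crossings"):
            e = c.estimate_reversal_potential(IVCurve(v, i))
        assert e == pytest.approx(-22.7, abs=3.0)

    def test_noisy_probe_sweeps_within_one_mV(self):
        # full probe pipeline at 5 pA noise: E_rev lands within 1 mV of E_Cl
        errors = []
        for seed in range(15):
            cell = c.GroundTruthCell(slope_nS=0.426, leak_reversal_mV=-74.0,
                                     g_cl_rest_pS=0.0, rs_Mohm=0.0,
                                     noise_sd_pA=5.0, g_ag_max_nS=4.0,
                                     cell=c.CellState(cl_i_mM=60.0))
            win = c.AgonistWindow(1.0, 3.0, tau_exchange_s=0.05)
            proto = c.RampProtocol([c.Segment(-23.0, 3.0, 1.6, 20.0)], [win], 1e-4)
            sw = c.simulate_sweep(cell, proto, seed=seed)
            v = c.correct_series_resistance(sw, 0.0)
            leak = c.fit_leak_model(c.build_iv_from_ramp(sw, v, 0.05, 0.95),
                                    form="linear")
            ag = c.build_iv_from_ramp(sw, v, 1.4, 3.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e = c.estimate_reversal_potential(c.subtract_leak(ag, leak))
            errors.append(e - cell.cell.e_cl_mV())
        assert np.max(np.abs(errors)) < 1.0


class TestSlopeConductance:
    def test_unit_line_any_window(self):
        v = np.linspace(-60, 60, 121)
        iv = IVCurve(v, v.copy())
        for center, width in [(0.0, 10.0), (-30.0, 20.0), (25.0, 8.0)]:
            assert c.estimate_slope_conductance(iv, center, width) == \
                pytest.approx(1.0, abs=1e-12)

    def test_exponential_leak_local_slope(self):
        a, b, cc = -10.0, 2.0, 20.0
        v = np.linspace(-94.0, -54.0, 401)
        iv = IVCurve(v, a + b * np.exp(v / cc))
        g = c.estimate_slope_conductance(iv, center_mV=-74.0, half_width_mV=5.0)
        assert g == pytest.approx(b / cc * np.exp(-74.0 / cc), rel=0.02)

    def test_synthetic_resting_conductance(self, noiseless_gcl_sweep,
                                           noiseless_cell):
        sw = noiseless_gcl_sweep
        v = c.correct_series_resistance(sw, noiseless_cell.rs_Mohm)
        iv = c.build_iv_from_ramp(sw, v, 0.3, 3.9)
        g = c.estimate_slope_conductance(iv, center_mV=-74.0, half_width_mV=15.0)
        assert g == pytest.approx(0.48, rel=0.05)

    def test_window_needs_five_points(self):
        v = np.linspace(-60, 60, 13)
        with pytest.raises(ValueError):
            c.estimate_slope_conductance(IVCurve(v, v.copy()), 0.0, 10.0)
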