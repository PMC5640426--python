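"""EPSC metric correctness: closed-form oracles, worked examples, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfspill import epsc, synth
from cfspill.containers import Trace, UndefinedMetricError
from cfspill.synth import PAIRED_50MS, make_epsc_sweep, preset_with


def _trace(samples, dt=0.1, t0=-50.0):
    return Trace(np.asarray(samples, dtype=float), dt=dt, t0=t0)


@pytest.fixture(scope="module")
def cf_paired(cf_noiseless):
    return make_epsc_sweep(cf_noiseless, PAIRED_50MS, dt=0.02)


class TestMeasurePeak:
    def test_flat_trace_zero(self):
        tr = _trace(np.zeros(2000))
        assert epsc.measure_peak(tr, (-50, 0), (0, 40)) == 0.0

    def test_square_step_magnitude(self):
        y = np.zeros(2000)
        y[600:] = -10.0  # step at t=10 ms
        tr = _trace(y)
        assert epsc.measure_peak(tr, (-50, 0), (0, 40)) == 10.0

    def test_window_outside_trace_errors(self):
        tr = _trace(np.zeros(100))
        with pytest.raises(ValueError):
            epsc.measure_peak(tr, (-500, -400), (0, 5))

    def test_cf_preset_amplitude(self, cf_paired):
        assert epsc.measure_peak(cf_paired, (-50, 0), (0, 40)) == pytest.approx(
            34.3, rel=1e-3
        )


class TestRiseTime:
    def test_linear_ramp_10_90(self):
        """A 1-ms linear ramp to peak has a 10-90% rise time of 0.8 ms."""
        t = np.arange(-50, 50, 0.1)
        y = np.where(t < 0, 0.0, np.where(t < 1.0, -10.0 * t, -10.0))
        tr = _trace(y)
        assert epsc.rise_time(tr, (-50, 0), (0, 40)) == pytest.approx(0.8, abs=1e-6)

    def test_analytic_dexp_crossings(self):
        """Rise time matches root-finding on the analytic waveform."""
        tau_r, tau_d = 0.8, 6.0
        t = np.arange(-20, 60, 0.02)
        tr = _trace(-synth.dexp_waveform(t, tau_r, tau_d), dt=0.02, t0=-20.0)
        expect = synth._analytic_rise_10_90(tau_r, tau_d)
        assert epsc.rise_time(tr, (-20, 0), (0, 50)) == pytest.approx(
            expect, rel=5e-3
        )

    def test_no_peak_above_noise_undefined(self):
        rng = np.random.default_rng(0)
        tr = _trace(rng.normal(0, 5, 2000))
        with pytest.raises(UndefinedMetricError):
            epsc.rise_time(tr, (-50, 0), (0, 40))


class TestDecayTau:
    def test_pure_exponential_exact(self):
        t = np.arange(-20, 60, 0.02)
        y = np.where(t < 0, 0.0, -np.exp(-t / 5.0))
        tr = _trace(y, dt=0.02, t0=-20.0)
        assert epsc.decay_tau(tr, (-20, 0), (0, 59)) == pytest.approx(5.0, rel=1e-4)

    def test_noisy_parameter_recovery(self):
        """Mean fitted tau over noisy sweeps within 2% of the generating tau."""
        p = preset_with("cf_ctrl", noise_sd=2.0)
        taus = [
            epsc.decay_tau(
                make_epsc_sweep(p, dt=0.02, seed=s), (-50, 0), (0, 60)
            )
            for s in range(200)
        ]
        assert np.mean(taus) == pytest.approx(7.9, rel=0.02)


class TestPairedPulseRatio:
    def test_two_identical_epscs_unity(self):
        t = np.arange(-50, 120, 0.02)
        y = -(synth.dexp_waveform(t, 0.5, 5.0) + synth.dexp_waveform(t - 50, 0.5, 5.0))
        tr = _trace(y, dt=0.02)
        assert epsc.paired_pulse_ratio(tr) == pytest.approx(1.0, rel=1e-3)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.2, 2.5))
    def test_linear_sum_scale_recovered(self, scale):
        """PPR of linearly summed identical EPSCs with scale s equals s."""
        t = np.arange(-50, 120, 0.02)
        y = -(
            synth.dexp_waveform(t, 0.5, 5.0)
            + scale * synth.dexp_waveform(t - 50, 0.5, 5.0)
        )
        tr = _trace(y, dt=0.02)
        assert epsc.paired_pulse_ratio(tr) == pytest.approx(scale, rel=1e-2)

    def test_first_pulse_absent_undefined(self):
        tr = _trace(np.zeros(9000), dt=0.02)
        with pytest.raises(UndefinedMetricError):
            epsc.paired_pulse_ratio(tr)


class TestCharge:
    def test_rectangle(self):
        t = np.arange(-50, 200, 0.1)
        y = np.where((t >= 0) & (t < 100), -10.0, 0.0)
        tr = _trace(y)
        assert epsc.charge(tr, (0, 150), (-50, 0)) == pytest.approx(1000.0, rel=1e-3)

    def test_zero_trace(self):
        tr = _trace(np.zeros(1000))
        assert epsc.charge(tr, (0, 40), (-50, 0)) == 0.0

    def test_exponential_closed_form(self):
        """Integral of A exp(-t/tau) over many taus approaches A*tau."""
        t = np.arange(-20, 100, 0.02)
        y = np.where(t < -1e-9, 0.0, -8.0 * np.exp(-np.clip(t, 0, None) / 5.0))
        tr = _trace(y, dt=0.02, t0=-20.0)
        assert epsc.charge(tr, (0, 99), (-20, 0)) == pytest.approx(
            8.0 * 5.0, rel=1e-3
        )


class TestDrugEffects:
    def test_percent_of_control_identity(self):
        assert epsc.percent_of_control(3.0, 3.0) == 100.0

    def test_percent_of_control_rejects_nonpositive_control(self):
        with pytest.raises(ValueError):
            epsc.percent_of_control(1.0, 0.0)

    def test_uptake_block_amplitude_and_decay_percent(self):
        """TBOA/control preset pair reproduces the 177% / 257% population effects."""
        ctrl = preset_with("cf_ctrl", noise_sd=0.0)
        tboa = preset_with("cf_tboa", noise_sd=0.0)
        assert epsc.percent_of_control(
            tboa.epsc_peak, ctrl.epsc_peak
        ) == pytest.approx(177.0)
        tr_c = make_epsc_sweep(ctrl, dt=0.02)
        tr_t = make_epsc_sweep(tboa, dt=0.02)
        d_c = epsc.decay_tau(tr_c, (-50, 0), (0, 60))
        d_t = epsc.decay_tau(tr_t, (-50, 0), (0, 160))
        assert epsc.percent_of_control(d_t, d_c) == pytest.approx(257.0, rel=0.01)

    def test_ly_sensitive_charge_identical_traces_zero(self):
        tr = _trace(np.zeros(2000))
        assert epsc.ly_sensitive_charge(tr, tr, (0, 100)) == 0.0

    def test_ly_sensitive_charge_rectangle_difference(self):
        """26.5 pA x 200 ms rectangular difference = 5.3 pA*s."""
        t = np.arange(-50, 500, 0.1)
        base = np.zeros_like(t)
        extra = np.where((t >= 50) & (t < 250), -26.5, 0.0)
        tboa = _trace(base + extra)
        ly = _trace(base)
        assert epsc.ly_sensitive_charge(tboa, ly, (0, 500)) == pytest.approx(
            5.3, rel=1e-3
        )

    def test_mismatched_sampling_rejected(self):
        a = _trace(np.zeros(1000), dt=0.1)
        b = _trace(np.zeros(1000), dt=0.2)
        with pytest.raises(ValueError):
            epsc.ly_sensitive_charge(a, b, (0, 50))

    def test_holding_current_shift_step(self):
        t = np.arange(0, 310, 0.1)
        y = np.where(t > 150, 40.0, 0.0)
        tr = Trace(y, dt=0.1, t0=0.0)
        assert epsc.holding_current_shift(tr, (0, 100), (200, 300)) == pytest.approx(
            40.0
        )

    def test_holding_current_drift_sensitivity(self):
        """1 pA/s linear drift with 100 s between window centers reads 100 pA."""
        t = np.arange(0, 200_000, 10.0)  # ms
        tr = Trace(t / 1000.0, dt=10.0, t0=0.0)  # 1 pA per s
        shift = epsc.holding_current_shift(tr, (0, 20_000), (100_000, 120_000))
        assert shift == pytest.approx(100.0, rel=1e-3)


class TestInputOutput:
    def test_all_or_none_series(self, cf_noiseless):
        p = preset_with("cf_ctrl", noise_sd=0.5)
        sw = synth.make_epsc_intensity_series(
            p, np.arange(1, 9), "all_or_none", thresholds=[3.0], seed=2
        )
        inten, norm, cls = epsc.input_output_curve(sw, (-50, 0), (0, 40))
        assert cls == "all_or_none"
        assert np.allclose(norm, 1.0, atol=0.2)

    def test_graded_series_classified_graded(self):
        p = preset_with("cf_ctrl", noise_sd=0.5)
        sw = synth.make_epsc_intensity_series(
            p, np.arange(1, 9), "graded", seed=3
        )
        _, norm, cls = epsc.input_output_curve(sw, (-50, 0), (0, 40))
        assert cls == "graded"
        assert norm[-1] > 2.0

    def test_constant_noiseless_amplitudes(self):
        p = preset_with("cf_ctrl", noise_sd=1e-4)
        sw = synth.make_epsc_intensity_series(
            p, np.arange(1, 7), "all_or_none", thresholds=[0.0], seed=4
        )
        _, norm, cls = epsc.input_output_curve(sw, (-50, 0), (0, 40))
        assert cls == "all_or_none"


class TestDiscreteLevels:
    def test_hand_clustered_example(self):
        amps = [0, 0, 29, 31, 30, 60, 61]
        assert epsc.count_discrete_levels(amps, noise_sd=1.0) == 2

    def test_all_equal_single_level(self):
        assert epsc.count_discrete_levels([30, 30, 30], noise_sd=1.0) == 1

    def test_all_failures_zero(self):
        assert epsc.count_discrete_levels([0.1, 0.2, 0.1], noise_sd=1.0) == 0

    def test_three_fiber_recruitment(self):
        """Step-wise intensity series with three fibers yields three levels."""
        p = preset_with("cf_ctrl", noise_sd=1.0)
        sw = synth.make_epsc_intensity_series(
            p,
            np.arange(1, 13),
            "multi_level",
            level_amplitudes=[30.0, 25.0, 35.0],
            thresholds=[2.0, 6.0, 10.0],
            seed=5,
        )
        amps = [epsc.measure_peak(tr, (-50, 0), (0, 40)) for tr in sw.traces]
        assert epsc.count_discrete_levels(amps, noise_sd=1.0) == 3


class TestInvariances:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(k=st.floats(0.25, 8.0))
    def test_scale_equivariance(self, k, cf_noiseless):
        """Scaling a trace by k scales peak and charge by k and leaves
        rise time, decay tau and PPR unchanged."""
        tr = make_epsc_sweep(cf_noiseless, PAIRED_50MS, dt=0.05)
        scaled = Trace(k * tr.samples, dt=tr.dt, t0=tr.t0)
        args = ((-50, 0), (0, 40))
        assert epsc.measure_peak(scaled, *args) == pytest.approx(
            k * epsc.measure_peak(tr, *args), rel=1e-9
        )
        assert epsc.charge(scaled, (0, 45), (-50, 0)) == pytest.approx(
            k * epsc.charge(tr, (0, 45), (-50, 0)), rel=1e-9
        )
        assert epsc.rise_time(scaled, *args) == pytest.approx(
            epsc.rise_time(tr, *args), rel=1e-9
        )
        assert epsc.paired_pulse_ratio(scaled) == pytest.approx(
            epsc.paired_pulse_ratio(tr), rel=1e-9
        )

    def test_time_shift_moves_onset_only(self, cf_noiseless):
        tr = make_epsc_sweep(cf_noiseless, dt=0.02)
        shifted = Trace(tr.samples, dt=tr.dt, t0=tr.t0 - 5.0)
        on0 = epsc.onset_latency(tr, (-50, 0), (0, 40))
        on1 = epsc.onset_latency(shifted, (-55, -5), (-5, 35))
        assert on1 == pytest.approx(on0 - 5.0, abs=0.05)
        assert epsc.rise_time(shifted, (-55, -5), (-5, 35)) == pytest.approx(
            epsc.rise_time(tr, (-50, 0), (0, 40)), rel=1e-6
        )
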