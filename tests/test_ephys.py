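"""Derived electrophysiological measures: arithmetic, kinetics, detection."""

import math

import numpy as np
import pytest

from quantal import QuantalParams
from quantal.ephys import (
    DetectionError,
    SweepTrace,
    VoltagesContext,
    corrected_ipsp,
    detect_minis,
    iv_conductance,
    onset_latency,
    paired_pulse_ratio,
    recurrent_inhibition_conductance,
    response_kinetics,
    scaled_conductance,
    subtract_artifact,
    synaptic_conductance,
)
from quantal.simulate import event_kernel, simulate_event_train


class TestConductanceArithmetic:
    def test_driving_force_worked_case(self):
        # -600 pA at -60 mV against a 0 mV reversal: 10 nS magnitude
        sigma = synaptic_conductance(-600.0, VoltagesContext(v_cell=-60, v_reversal=0))
        assert sigma.magnitude == pytest.approx(10.0)
        assert sigma.signed == pytest.approx(-10.0)

    def test_zero_current_and_proportionality(self):
        ctx = VoltagesContext(v_cell=-60, v_reversal=0)
        assert synaptic_conductance(0.0, ctx).signed == 0
        half = VoltagesContext(v_cell=-30, v_reversal=0)
        assert synaptic_conductance(-600.0, half).magnitude == pytest.approx(
            2 * synaptic_conductance(-600.0, ctx).magnitude)

    def test_equal_voltages_raise(self):
        with pytest.raises(ZeroDivisionError):
            synaptic_conductance(-100.0, VoltagesContext(v_cell=0, v_reversal=0))

    def test_scaled_conductance(self):
        assert scaled_conductance(10.0, 100.0) == pytest.approx(10.0)
        assert scaled_conductance(37.0, 37.0) == pytest.approx(100.0)
        assert scaled_conductance(3 * 10.0, 3 * 100.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            scaled_conductance(10.0, 0.0)

    def test_corrected_ipsp(self):
        # identity at the resting potential
        ctx = VoltagesContext(v_rest=-60, v_reversal=-75, v_membrane=-60)
        assert corrected_ipsp(2.0, ctx) == pytest.approx(2.0)
        # worked case: 2 mV at -50 mV -> 2 * 15/25 = 1.2 mV
        ctx = VoltagesContext(v_rest=-60, v_reversal=-75, v_membrane=-50)
        assert corrected_ipsp(2.0, ctx) == pytest.approx(1.2)
        assert corrected_ipsp(0.0, ctx) == 0.0
        with pytest.raises(ZeroDivisionError):
            corrected_ipsp(2.0, VoltagesContext(v_reversal=-75, v_membrane=-75))

    def test_iv_slope_exact_line(self):
        i = [-200.0, -100.0, 0.0, 100.0]
        v = [-20.0, -10.0, 0.0, 10.0]
        assert iv_conductance(i, v) == pytest.approx(10.0)
        assert iv_conductance(i, np.array(v) + 7.5) == pytest.approx(10.0)

    def test_iv_slope_with_noise(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-20, 20, 1000)
        i = 12.0 * v + rng.normal(0, 5.0, 1000)
        assert iv_conductance(i, v) == pytest.approx(12.0, rel=0.01)

    def test_recurrent_inhibition_difference(self):
        v = np.array([-10.0, -5.0, 0.0, 5.0])
        rest = (100.0 * v, v)       # 100 nS cell
        train = (150.0 * v, v)      # 150 nS during the 200-Hz train
        extra = recurrent_inhibition_conductance(rest, train)
        assert extra == pytest.approx(50.0)
        assert recurrent_inhibition_conductance(rest, rest) == pytest.approx(0.0)
        assert scaled_conductance(extra, 100.0) == pytest.approx(50.0)

    def test_recurrent_inhibition_negative_flagged(self):
        v = np.array([-10.0, 0.0, 10.0])
        with pytest.warns(RuntimeWarning):
            out = recurrent_inhibition_conductance((100.0 * v, v), (80.0 * v, v))
        assert out == pytest.approx(-20.0)

    def test_ppr(self):
        assert paired_pulse_ratio(5.0, 5.0) == 1.0
        assert paired_pulse_ratio(10.0, 4.0) == pytest.approx(0.4)
        assert paired_pulse_ratio(20.0, 8.0) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            paired_pulse_ratio(0.0, 1.0)


class TestArtifactSubtraction:
    dt = 2e-5

    def _trace(self, samples, **kw):
        return SweepTrace(np.asarray(samples, float), self.dt, **kw)

    def test_pure_exponential_self_fit(self):
        t = np.arange(0, 0.02, self.dt)
        y = 50.0 * np.exp(-t / 2e-3)
        out = subtract_artifact(self._trace(y), (0.0, 0.02), model="single")
        assert np.abs(out.samples).max() < 1e-6 * 50.0

    def test_zero_trace_stays_zero(self):
        out = subtract_artifact(self._trace(np.zeros(500)), (0.0, 0.005))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-9)

    def test_recovers_planted_epsc_under_double_exp_artifact(self):
        t = np.arange(0, 0.04, self.dt)
        artifact = 400.0 * np.exp(-t / 0.4e-3) + 80.0 * np.exp(-t / 2.5e-3)
        epsc_amp = 60.0
        onset = 0.012
        kern = event_kernel(t - onset, rise_tau=3e-4, decay_tau=4e-3)
        y = artifact + epsc_amp * kern
        out = subtract_artifact(self._trace(y), (0.002, 0.010), model="double")
        sl = slice(int(onset / self.dt), int(0.03 / self.dt))
        assert out.samples[sl].max() == pytest.approx(epsc_amp, rel=0.02)

    def test_original_untouched(self):
        y = 10.0 * np.exp(-np.arange(500) * self.dt / 1e-3)
        trace = self._trace(y)
        subtract_artifact(trace, (0.0, 0.005))
        np.testing.assert_array_equal(trace.samples, y)


class TestKinetics:
    dt = 2e-5

    def _decay_trace(self, tau=3e-3, amp=1.0):
        # instantaneous rise at 5 ms, exponential decay
        n = int(0.05 / self.dt)
        t = np.arange(n) * self.dt
        y = np.where(t >= 5e-3, amp * np.exp(-(t - 5e-3) / tau), 0.0)
        return SweepTrace(y, self.dt, baseline_window=(0.0, 4e-3))

    def test_10_90_decay_closed_form(self):
        kin = response_kinetics(self._decay_trace(), (4e-3, 0.05), 0.1, 0.9)
        assert kin.decay_time == pytest.approx(3e-3 * math.log(9), rel=1e-3)
        assert kin.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_20_80_decay_closed_form(self):
        kin = response_kinetics(self._decay_trace(), (4e-3, 0.05), 0.2, 0.8)
        assert kin.decay_time == pytest.approx(3e-3 * math.log(4), rel=1e-3)

    def test_times_invariant_to_amplitude_scaling(self):
        k1 = response_kinetics(self._decay_trace(amp=1.0), (4e-3, 0.05))
        k2 = response_kinetics(self._decay_trace(amp=2.0), (4e-3, 0.05))
        assert k2.rise_time == pytest.approx(k1.rise_time, rel=1e-9)
        assert k2.decay_time == pytest.approx(k1.decay_time, rel=1e-9)
        assert k2.amplitude == pytest.approx(2 * k1.amplitude)

    def test_dc_offset_invariance(self):
        tr = self._decay_trace()
        shifted = SweepTrace(tr.samples + 13.0, self.dt, baseline_window=(0.0, 4e-3))
        k1 = response_kinetics(tr, (4e-3, 0.05))
        k2 = response_kinetics(shifted, (4e-3, 0.05))
        assert k2.decay_time == pytest.approx(k1.decay_time, rel=1e-9)
        assert k2.amplitude == pytest.approx(k1.amplitude, rel=1e-9)

    def test_flat_window_raises(self):
        tr = SweepTrace(np.zeros(1000), self.dt, baseline_window=(0.0, 4e-3))
        with pytest.raises(DetectionError):
            response_kinetics(tr, (5e-3, 0.02))


class TestOnsetLatency:
    dt = 2e-5

    def test_flat_trace_no_response(self):
        tr = SweepTrace(np.zeros(2500), self.dt, baseline_window=(0.0, 0.01))
        assert onset_latency(tr, 0.02) is None

    def test_sharp_onset_recovered(self):
        rng = np.random.default_rng(5)
        n = int(0.05 / self.dt)
        t = np.arange(n) * self.dt
        y = rng.normal(0, 0.05, n)
        stim = 0.02
        onset = stim + 2e-3
        y += np.where(t >= onset, 40.0 * (1 - np.exp(-(t - onset) / 5e-4)), 0.0)
        tr = SweepTrace(y, self.dt, stimulus_times=(stim,), baseline_window=(0.0, 0.015))
        lat = onset_latency(tr, stim)
        assert lat == pytest.approx(2e-3, abs=2 * self.dt)
        # invariant to DC offset
        tr2 = SweepTrace(y + 100.0, self.dt, baseline_window=(0.0, 0.015))
        assert onset_latency(tr2, stim) == lat


def _planted_mini_trace():
    """3 conforming events, 1 sub-threshold, 1 with a 0.05 ms rise."""
    params = QuantalParams.from_cv(1, 50.0, 0.3)
    noise_sd = 4.0
    trace, _ = simulate_event_train(
        0.0, 1.0, params, noise_sd=noise_sd, seed=21,
        event_times=[0.1, 0.3, 0.5], event_amplitudes=[32.0, 40.0, 36.0])
    # sub-threshold event: amplitude below 1.5 x noise SD
    k = event_kernel(np.arange(0, 0.02, trace.sample_interval))
    i = int(0.7 / trace.sample_interval)
    trace.samples[i : i + k.size] += 0.8 * noise_sd * k
    # too-fast rise: ~0.05 ms 20-80% rise, otherwise conforming
    kf = event_kernel(np.arange(0, 0.02, trace.sample_interval),
                      rise_tau=2e-5, decay_tau=3e-3)
    i = int(0.9 / trace.sample_interval)
    trace.samples[i : i + kf.size] += 36.0 * kf
    return trace, noise_sd


class TestDetectMinis:
    def test_fixture_keeps_exactly_conforming_events(self):
        trace, noise_sd = _planted_mini_trace()
        events = detect_minis(trace, noise_sd)
        assert len(events) == 3
        np.testing.assert_allclose(
            [e.time for e in events], [0.1, 0.3, 0.5], atol=2e-3)

    def test_amplitudes_within_noise_of_planted(self):
        trace, noise_sd = _planted_mini_trace()
        events = detect_minis(trace, noise_sd)
        for e, planted in zip(events, [32.0, 40.0, 36.0]):
            assert abs(e.amplitude - planted) < noise_sd

    def test_pure_noise_false_positive_rate(self):
        rng = np.random.default_rng(42)
        dur, dt = 10.0, 2e-5
        trace = SweepTrace(rng.normal(0, 4.0, int(dur / dt)), dt)
        events = detect_minis(trace, 4.0)
        assert len(events) < 1 * dur / 10.0 + 1  # < 1 per 10 s

    def test_events_sorted_with_positive_ieis(self):
        trace, noise_sd = _planted_mini_trace()
        events = detect_minis(trace, noise_sd)
        times = [e.time for e in events]
        assert times == sorted(times)
        assert all(e.inter_event_interval > 0 for e in events[1:])
        assert math.isnan(events[0].inter_event_interval)
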