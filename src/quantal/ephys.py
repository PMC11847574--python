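"""Derived electrophysiological measures.

Conductance arithmetic (driving-force conductances, scaling to resting
conductance, IPSP voltage correction, I-V slope fits and the
recurrent-inhibition conductance), stimulus-artifact exponential
subtraction, response kinetics and onset latency, paired-pulse ratio,
and miniature/asynchronous event detection.

Unit conventions: currents in pA, voltages in mV, conductances in nS
(pA/mV == nS), times in seconds unless a name says otherwise.
Amplitudes are reduced to positive magnitudes internally; the caller
declares the deflection direction (``polarity``) where it matters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, signal

__all__ = [
    "SweepTrace",
    "VoltagesContext",
    "SynapticEvent",
    "Conductance",
    "Kinetics",
    "FitError",
    "DetectionError",
    "synaptic_conductance",
    "scaled_conductance",
    "corrected_ipsp",
    "iv_conductance",
    "recurrent_inhibition_conductance",
    "subtract_artifact",
    "response_kinetics",
    "onset_latency",
    "paired_pulse_ratio",
    "detect_minis",
]


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge."""


class DetectionError(RuntimeError):
    """Raised when no response/extremum can be found where one is required."""


@dataclass
class SweepTrace:
    """A time-sampled recording (mV or pA).

    ``stimulus_times`` are in seconds from the start of the sweep;
    ``baseline_window`` is a (start, stop) interval preceding the first
    stimulus used for baseline/noise measurements.
    """

    samples: np.ndarray
    sample_interval: float
    stimulus_times: tuple[float, ...] = ()
    baseline_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D sequence")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be positive")
        dur = self.samples.size * self.sample_interval
        for st in self.stimulus_times:
            if not 0.0 <= st <= dur:
                raise ValueError(f"stimulus time {st} outside the trace")
        if self.baseline_window is not None:
            b0, b1 = self.baseline_window
            if not 0.0 <= b0 < b1 <= dur:
                raise ValueError("baseline_window must be an ordered interval in the trace")
            if self.stimulus_times and b1 > min(self.stimulus_times):
                raise ValueError("baseline_window must precede the first stimulus")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval

    @property
    def duration(self) -> float:
        return self.samples.size * self.sample_interval

    def window_slice(self, window: tuple[float, float]) -> slice:
        i0 = max(0, int(math.ceil(window[0] / self.sample_interval)))
        i1 = min(self.samples.size, int(math.floor(window[1] / self.sample_interval)) + 1)
        if i1 <= i0:
            raise ValueError(f"window {window} contains no samples")
        return slice(i0, i1)


@dataclass(frozen=True)
class VoltagesContext:
    """Voltages needed by the conductance and IPSP-correction formulas.

    Defaults: resting potential -60 mV; reversal -75 mV is the Cl-
    equilibrium imposed by typical K-gluconate intra/extracellular
    solutions (used for the IPSP correction).
    """

    v_cell: float = -60.0
    v_reversal: float = 0.0
    v_rest: float = -60.0
    v_membrane: float = -60.0


class Conductance(NamedTuple):
    signed: float
    magnitude: float


class Kinetics(NamedTuple):
    rise_time: float
    decay_time: float
    amplitude: float


@dataclass(frozen=True)
class SynapticEvent:
    """A detected spontaneous/asynchronous synaptic event.

    Times in seconds; kinetics in ms; amplitude a positive magnitude.
    ``inter_event_interval`` (ms) is relative to the previous detected
    event (nan for the first).
    """

    time: float
    amplitude: float
    rise_time: float
    decay_time: float
    inter_event_interval: float = math.nan


def synaptic_conductance(current: float, context: VoltagesContext) -> Conductance:
    """Driving-force conductance ``sigma = I / (V_reversal - V_cell)``.

    ``current`` in pA and voltages in mV give nS.  Returns the signed
    value together with its magnitude (used for group comparisons).
    """
    dv = context.v_reversal - context.v_cell
    if dv == 0:
        raise ZeroDivisionError(
            "v_reversal equals v_cell: driving force is zero, conductance undefined"
        )
    sigma = current / dv
    return Conductance(signed=sigma, magnitude=abs(sigma))


def scaled_conductance(sigma: float, sigma_cell: float) -> float:
    """Synaptic conductance as a percentage of the resting conductance."""
    if not sigma_cell > 0:
        raise ValueError(f"resting conductance must be positive, got {sigma_cell!r}")
    return sigma * 100.0 / sigma_cell


def corrected_ipsp(ipsp: float, context: VoltagesContext) -> float:
    """IPSP amplitude corrected to the resting potential.

    Linear driving-force model:
    ``IPSP * (V_rest - V_reversal) / (V_membrane - V_reversal)`` -- the
    amplitude the IPSP would have had at V_rest.
    """
    denom = context.v_membrane - context.v_reversal
    if denom == 0:
        raise ZeroDivisionError(
            "v_membrane equals v_reversal: no driving force, correction undefined"
        )
    return ipsp * (context.v_rest - context.v_reversal) / denom


def iv_conductance(
    current_steps: Sequence[float], voltage_deflections: Sequence[float]
) -> float:
    """Slope conductance (nS) from an I-V line: least-squares dI/dV."""
    i = np.asarray(current_steps, dtype=float)
    v = np.asarray(voltage_deflections, dtype=float)
    if i.size != v.size or i.size < 2 or np.unique(i).size < 2:
        raise ValueError("need >= 2 distinct current steps with matching voltages")
    if np.ptp(v) == 0:
        raise FitError("all voltage deflections identical; I-V slope undefined")
    slope = np.polyfit(v, i, 1)[0]
    return float(slope)


def recurrent_inhibition_conductance(
    rest_iv: tuple[Sequence[float], Sequence[float]],
    train_iv: tuple[Sequence[float], Sequence[float]],
) -> float:
    """Extra conductance recruited during a high-frequency train.

    Difference between the I-V slope conductance during the 200-Hz
    stimulation steady state and the resting conductance; its magnitude
    is the strength of recurrent inhibition.  A negative difference is
    flagged with a warning but returned unchanged.
    """
    sigma_rest = iv_conductance(*rest_iv)
    sigma_train = iv_conductance(*train_iv)
    diff = sigma_train - sigma_rest
    if diff < 0:
        warnings.warn(
            f"conductance during the train ({sigma_train:g} nS) is below the "
            f"resting conductance ({sigma_rest:g} nS)",
            RuntimeWarning,
            stacklevel=2,
        )
    return diff


def _exp1(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _exp2(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def subtract_artifact(
    trace: SweepTrace,
    fit_window: tuple[float, float],
    model: str = "double",
) -> SweepTrace:
    """Fit the stimulus-artifact tail and subtract its extrapolation.

    A single or double exponential is least-squares fitted on
    ``fit_window`` (the end of the artifact, before the response onset),
    extrapolated forward to the end of the sweep and subtracted from the
    fit start onward.  The input trace is untouched; a corrected copy is
    returned.
    """
    if model not in ("single", "double"):
        raise ValueError(f"model must be 'single' or 'double', got {model!r}")
    sl = trace.window_slice(fit_window)
    y = trace.samples[sl]
    t = (np.arange(y.size)) * trace.sample_interval
    if np.ptp(y) == 0:
        # flat segment: subtracting its constant level is the exact fit
        out = trace.samples.copy()
        out[sl.start :] -= y[0] if y.size else 0.0
        return SweepTrace(out, trace.sample_interval, trace.stimulus_times, trace.baseline_window)

    span = max(t[-1], trace.sample_interval)
    c0 = float(y[-1])
    a0 = float(y[0] - c0) or float(np.ptp(y))
    tau0 = span / 3.0
    tau_lo, tau_hi = trace.sample_interval / 10.0, 100.0 * span
    amp_cap = 1e3 * (abs(a0) + np.ptp(y) + 1e-12)
    try:
        p1, _ = optimize.curve_fit(
            _exp1, t, y, p0=[a0, tau0, c0],
            bounds=([-amp_cap, tau_lo, -np.inf], [amp_cap, tau_hi, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"single-exponential artifact fit failed: {exc}") from exc
    if model == "single":
        popt, fun = p1, _exp1
    else:
        a, tau, c = p1
        p0 = [0.8 * a, tau, 0.2 * a if a else 0.1 * np.ptp(y), max(tau / 5.0, 2 * tau_lo), c]
        try:
            popt, _ = optimize.curve_fit(
                _exp2, t, y, p0=p0,
                bounds=(
                    [-amp_cap, tau_lo, -amp_cap, tau_lo, -np.inf],
                    [amp_cap, tau_hi, amp_cap, tau_hi, np.inf],
                ),
                maxfev=40000,
            )
            fun = _exp2
        except RuntimeError:
            # double fit failed to converge; the single fit is the fallback
            popt, fun = p1, _exp1
    t_full = (np.arange(trace.samples.size - sl.start)) * trace.sample_interval
    fitted = fun(t_full, *popt)
    resid = y - fun(t, *popt)
    if not np.all(np.isfinite(fitted)):
        raise FitError(
            f"artifact fit diverged (params {popt}, residual rms {np.sqrt(np.mean(resid**2)):g})"
        )
    out = trace.samples.copy()
    out[sl.start :] -= fitted
    return SweepTrace(out, trace.sample_interval, trace.stimulus_times, trace.baseline_window)


def _cross_time(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    """Linearly interpolated time at which y crosses ``level``."""
    if y1 == y0:
        return t1
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def _rising_cross(t: np.ndarray, y: np.ndarray, peak_idx: int, level: float) -> Optional[float]:
    """Last upward crossing of ``level`` before the peak."""
    for i in range(peak_idx, 0, -1):
        if y[i - 1] < level <= y[i]:
            return _cross_time(t[i - 1], t[i], y[i - 1], y[i], level)
    if y[0] >= level:
        return float(t[0])
    return None


def _falling_cross(t: np.ndarray, y: np.ndarray, peak_idx: int, level: float) -> Optional[float]:
    """First downward crossing of ``level`` after the peak."""
    for i in range(peak_idx + 1, y.size):
        if y[i - 1] >= level > y[i]:
            return _cross_time(t[i - 1], t[i], y[i - 1], y[i], level)
    return None


def response_kinetics(
    trace: SweepTrace,
    event_window: tuple[float, float],
    lo_frac: float = 0.1,
    hi_frac: float = 0.9,
    polarity: str = "positive",
    baseline: Optional[float] = None,
) -> Kinetics:
    """Rise time, decay time and amplitude of a response in a window.

    Amplitude is the peak minus the local baseline (the mean of the
    trace's ``baseline_window`` unless ``baseline`` is given).  The rise
    time runs from ``lo_frac`` to ``hi_frac`` of the amplitude on the
    rising limb and the decay from ``hi_frac`` to ``lo_frac`` on the
    falling limb, with linear interpolation between samples.  Evoked
    responses conventionally use 10-90%; small spontaneous events use
    20-80% (more robust against baseline noise).  Times in seconds.
    """
    if not 0.0 < lo_frac < hi_frac < 1.0:
        raise ValueError("need 0 < lo_frac < hi_frac < 1")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    if baseline is None:
        if trace.baseline_window is None:
            raise ValueError("no baseline: give `baseline` or set trace.baseline_window")
        baseline = float(trace.samples[trace.window_slice(trace.baseline_window)].mean())
    sl = trace.window_slice(event_window)
    sign = 1.0 if polarity == "positive" else -1.0
    y = sign * (trace.samples[sl] - baseline)
    t = trace.times[sl]
    peak_idx = int(np.argmax(y))
    amplitude = float(y[peak_idx])
    if amplitude <= 0:
        raise DetectionError("no extremum above baseline in the event window")
    lo, hi = lo_frac * amplitude, hi_frac * amplitude
    t_lo_r = _rising_cross(t, y, peak_idx, lo)
    t_hi_r = _rising_cross(t, y, peak_idx, hi)
    t_hi_f = _falling_cross(t, y, peak_idx, hi)
    t_lo_f = _falling_cross(t, y, peak_idx, lo)
    if t_lo_r is None or t_hi_r is None:
        raise DetectionError("rising limb does not span the requested fractions")
    if t_hi_f is None or t_lo_f is None:
        raise DetectionError("falling limb does not span the requested fractions")
    return Kinetics(
        rise_time=float(t_hi_r - t_lo_r),
        decay_time=float(t_lo_f - t_hi_f),
        amplitude=amplitude,
    )


def onset_latency(
    trace: SweepTrace,
    stimulus_time: float,
    baseline_window: Optional[tuple[float, float]] = None,
    threshold_factor: float = 5.0,
) -> Optional[float]:
    """Latency from stimulus to response onset, or None if no response.

    Onset is the first post-stimulus time at which the trace derivative
    exceeds ``threshold_factor`` (default 5) times the standard
    deviation of the baseline derivative.  Jitter across sweeps is the
    SD of these latencies (within one cell only).
    """
    window = baseline_window or trace.baseline_window
    if window is None:
        raise ValueError("a baseline window is required to measure the noise SD")
    if window[1] > stimulus_time:
        raise ValueError("baseline window must precede the stimulus")
    deriv = np.gradient(trace.samples, trace.sample_interval)
    base_sd = float(deriv[trace.window_slice(window)].std(ddof=1))
    threshold = threshold_factor * base_sd
    i0 = int(math.ceil(stimulus_time / trace.sample_interval))
    after = np.abs(deriv[i0:]) > threshold
    if threshold == 0 or not after.any():
        return None
    return float(int(np.argmax(after)) * trace.sample_interval)


def paired_pulse_ratio(amp1: float, amp2: float) -> float:
    """Second/first response amplitude for paired stimuli (e.g. 33 Hz)."""
    if not amp1 > 0:
        raise ValueError(f"first amplitude must be positive, got {amp1!r}")
    return amp2 / amp1


def detect_minis(
    trace: SweepTrace,
    noise_sd: float,
    threshold_factor: float = 1.5,
    min_rise_ms: float = 0.1,
    min_decay_ms: float = 0.5,
    lo_frac: float = 0.2,
    hi_frac: float = 0.8,
    polarity: str = "positive",
    baseline_ms: float = 2.0,
    baseline_gap_ms: float = 1.0,
    amplitude_window_ms: float = 0.5,
) -> list[SynapticEvent]:
    """Detect spontaneous synaptic events on a continuous trace.

    Candidate peaks at least ``threshold_factor`` (default 1.5) times
    the baseline noise SD are kept only if their 20-80% rise exceeds
    ``min_rise_ms`` and their decay exceeds ``min_decay_ms`` -- the
    waveform criterion that rejects noise excursions, which rise and
    fall within a sample or two.  Event amplitude is measured against a
    local pre-event baseline (mean over ``baseline_ms``, ending
    ``baseline_gap_ms`` before the peak).  ``noise_sd`` must come from
    an event-free window chosen by the caller.

    Returns events sorted by time with inter-event intervals filled in.
    """
    if not noise_sd > 0:
        raise ValueError("noise_sd must be positive")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    sign = 1.0 if polarity == "positive" else -1.0
    s = sign * trace.samples
    dt = trace.sample_interval
    dt_ms = dt * 1e3
    min_sep = max(1, int(round(min_decay_ms / dt_ms)))
    height = threshold_factor * noise_sd
    candidates, _ = signal.find_peaks(s, height=height, distance=min_sep)

    # group candidate maxima belonging to one event: two peaks are the
    # same event unless the signal returns below the detection threshold
    # between them; the larger peak represents the event
    peaks: list[int] = []
    for pk in candidates:
        if peaks and s[peaks[-1] : pk + 1].min() >= height:
            if s[pk] > s[peaks[-1]]:
                peaks[-1] = pk
        else:
            peaks.append(pk)

    n_base = max(1, int(round(baseline_ms / dt_ms)))
    n_gap = max(1, int(round(baseline_gap_ms / dt_ms)))
    # amplitude is read off a boxcar-smoothed copy at the local smoothed
    # maximum: the raw peak sample rides the noise maximum and is biased
    # upward, and grouping can shift the raw peak onto the decay
    n_smooth = max(1, int(round(amplitude_window_ms / dt_ms)))
    kernel_box = np.ones(n_smooth) / n_smooth
    s_smooth = np.convolve(s, kernel_box, mode="same")
    events: list[SynapticEvent] = []
    for pk in peaks:
        b1 = pk - n_gap
        b0 = max(0, b1 - n_base)
        baseline = float(s[b0:b1].mean()) if b1 > b0 else 0.0
        r = max(1, int(round(1.0 / dt_ms)))
        seg = s_smooth[max(0, pk - r) : pk + r + 1]
        amplitude = float(seg.max() - baseline)
        if amplitude < height:
            continue
        lo, hi = lo_frac * amplitude, hi_frac * amplitude
        w0 = max(0, pk - n_base - n_gap)
        w1 = min(s.size, pk + int(round(12 * min_decay_ms / dt_ms)) + 1)
        y = s[w0:w1] - baseline
        tt = np.arange(w0, w1) * dt
        pi = pk - w0
        t_lo_r = _rising_cross(tt, y, pi, lo)
        t_hi_r = _rising_cross(tt, y, pi, hi)
        t_hi_f = _falling_cross(tt, y, pi, hi)
        t_lo_f = _falling_cross(tt, y, pi, lo)
        if None in (t_lo_r, t_hi_r, t_hi_f, t_lo_f):
            continue
        rise_ms = (t_hi_r - t_lo_r) * 1e3
        decay_ms = (t_lo_f - t_hi_f) * 1e3
        if rise_ms <= min_rise_ms or decay_ms <= min_decay_ms:
            continue
        events.append(
            SynapticEvent(
                time=float(pk * dt),
                amplitude=amplitude,
                rise_time=float(rise_ms),
                decay_time=float(decay_ms),
            )
        )
    events.sort(key=lambda e: e.time)
    out: list[SynapticEvent] = []
    for i, ev in enumerate(events):
        iei = math.nan if i == 0 else (ev.time - events[i - 1].time) * 1e3
        out.append(
            SynapticEvent(
                time=ev.time,
                amplitude=ev.amplitude,
                rise_time=ev.rise_time,
                decay_time=ev.decay_time,
                inter_event_interval=iei,
            )
        )
    return out
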