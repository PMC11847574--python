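"""Forward simulation of the binomial-gamma quantal model.

Two generators:

* :func:`simulate_observations` draws amplitude tables under one or more
  release-probability conditions (emulating recordings at different
  extracellular Ca2+ levels) from the same composite model the inference
  assumes: per sweep, ``j ~ Binomial(n, p)`` releases, amplitude =
  sum of j iid Gamma(gamma, lambda) quanta + Gaussian noise.
* :func:`simulate_event_train` lays difference-of-exponential synaptic
  events at Poisson times on a noisy trace, with ground truth returned,
  as a fixture source for event detection and kinetics code.

All randomness flows through a single ``numpy.random.Generator`` seeded
explicitly, so every simulation is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .core import ObservationSet, QuantalParams
from .ephys import SweepTrace

__all__ = [
    "SimulationDesign",
    "PlantedEvent",
    "simulate_observations",
    "simulate_event_train",
    "event_kernel",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Design of a simulated multi-condition quantal experiment.

    ``condition_ps`` gives the per-site release probability of each
    condition; ``sweeps_per_condition`` may be a single int (balanced
    design) or one int per condition.  ``noise_sd`` is the baseline
    noise SD in response units.
    """

    params: QuantalParams
    condition_ps: tuple[float, ...]
    sweeps_per_condition: Union[int, tuple[int, ...]]
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.condition_ps) == 0:
            raise ValueError("need at least one condition")
        for p in self.condition_ps:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"condition p must lie in [0, 1], got {p!r}")
        for m in self.counts():
            if m < 2:
                raise ValueError("each condition needs >= 2 sweeps")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")

    def counts(self) -> tuple[int, ...]:
        m = self.sweeps_per_condition
        if isinstance(m, (int, np.integer)):
            return (int(m),) * len(self.condition_ps)
        if len(m) != len(self.condition_ps):
            raise ValueError("sweeps_per_condition length must match conditions")
        return tuple(int(v) for v in m)


def simulate_observations(
    design: SimulationDesign,
    noise_mode: str = "known",
    n_baseline_sweeps: int = 200,
    return_counts: bool = False,
    rng: Optional[np.random.Generator] = None,
):
    """Draw an :class:`ObservationSet` from the quantal generative model.

    Per sweep the number of successful releases is binomial and the
    evoked amplitude is an exact Gamma(j*gamma, lambda) draw (the sum of
    j iid uniquantal gammas) plus Gaussian noise.  In ``known`` noise
    mode the ObservationSet carries the true noise SD; in ``estimated``
    mode it carries the unbiased sample SD of ``n_baseline_sweeps``
    simulated stimulus-free sweeps.

    With ``return_counts=True`` also returns the latent per-sweep
    release counts (for validation against ground truth).
    """
    if noise_mode not in ("known", "estimated"):
        raise ValueError(f"noise_mode must be 'known' or 'estimated', got {noise_mode!r}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    params = design.params
    amplitudes = []
    counts = []
    for p, m in zip(design.condition_ps, design.counts()):
        j = rng.binomial(params.n, p, size=m)
        amps = np.zeros(m)
        released = j > 0
        if released.any():
            amps[released] = rng.standard_gamma(
                j[released] * params.gamma_shape
            ) * params.lambda_scale
        amps += rng.normal(0.0, design.noise_sd, size=m)
        amplitudes.append(amps)
        counts.append(j)
    if noise_mode == "known":
        noise_sd = design.noise_sd
    else:
        baseline = rng.normal(0.0, design.noise_sd, size=n_baseline_sweeps)
        noise_sd = float(baseline.std(ddof=1))
    obs = ObservationSet(amplitudes, noise_sd=noise_sd)
    if return_counts:
        return obs, counts
    return obs


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one simulated synaptic event."""

    time: float
    amplitude: float


def event_kernel(
    t: np.ndarray, rise_tau: float = 3e-4, decay_tau: float = 3e-3
) -> np.ndarray:
    """Difference-of-exponentials synaptic kernel, normalized to unit peak.

    Defaults (0.3 ms rise, 3 ms decay) are on the scale of a glycinergic
    IPSC at near-physiological temperature.
    """
    if not 0 < rise_tau < decay_tau:
        raise ValueError("need 0 < rise_tau < decay_tau")
    k = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    return k / peak


def simulate_event_train(
    rate: Union[float, Callable[[np.ndarray], np.ndarray]],
    duration: float,
    params: QuantalParams,
    noise_sd: float,
    seed: int = 0,
    sample_interval: float = 2e-5,
    rise_tau: float = 3e-4,
    decay_tau: float = 3e-3,
    event_times: Optional[Sequence[float]] = None,
    event_amplitudes: Optional[Sequence[float]] = None,
) -> tuple[SweepTrace, list[PlantedEvent]]:
    """Simulate a continuous sweep of spontaneous synaptic events.

    Events occur at Poisson times with the given rate (a constant in Hz,
    or a callable ``rate(t)`` for a time-varying profile, sampled per
    time bin), each with a uniquantal gamma amplitude (mean ``params.q``)
    shaped by a difference-of-exponentials kernel, on top of Gaussian
    noise.  Passing explicit ``event_times``/``event_amplitudes``
    bypasses the random draws (deterministic fixtures).

    Returns the trace together with the planted ground truth.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration / sample_interval))
    t = np.arange(n_samp) * sample_interval

    if event_times is None:
        if callable(rate):
            lam = np.clip(np.asarray(rate(t), dtype=float), 0.0, None)
        else:
            if rate < 0:
                raise ValueError("rate must be non-negative")
            lam = np.full(n_samp, float(rate))
        n_per_bin = rng.poisson(lam * sample_interval)
        idx = np.repeat(np.arange(n_samp), n_per_bin)
        times = t[idx]
        amps = rng.gamma(params.gamma_shape, params.lambda_scale, size=times.size)
    else:
        times = np.asarray(event_times, dtype=float)
        if event_amplitudes is None:
            amps = rng.gamma(params.gamma_shape, params.lambda_scale, size=times.size)
        else:
            amps = np.asarray(event_amplitudes, dtype=float)
            if amps.size != times.size:
                raise ValueError("event_times and event_amplitudes must match")

    trace = rng.normal(0.0, noise_sd, size=n_samp) if noise_sd > 0 else np.zeros(n_samp)
    k_len = int(round(8 * decay_tau / sample_interval))
    kt = np.arange(k_len) * sample_interval
    kernel = event_kernel(kt, rise_tau, decay_tau)
    for time, amp in zip(times, amps):
        i0 = int(round(time / sample_interval))
        if i0 >= n_samp:
            continue
        seg = min(k_len, n_samp - i0)
        trace[i0 : i0 + seg] += amp * kernel[:seg]

    events = [PlantedEvent(float(ti), float(ai)) for ti, ai in zip(times, amps)]
    events.sort(key=lambda e: e.time)
    sweep = SweepTrace(samples=trace, sample_interval=sample_interval)
    return sweep, events
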