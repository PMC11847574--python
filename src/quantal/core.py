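"""Probability model for quantal synaptic transmission.

The generative model treats an evoked postsynaptic response as the sum of
``j`` uniquantal events plus baseline noise, where ``j`` is the number of
release sites (out of ``n``) that released a vesicle on that stimulus.
Release at each site is a Bernoulli trial with probability ``p`` (so ``j``
is binomial), each uniquantal amplitude is gamma distributed with shape
``gamma_shape`` and scale ``lambda_scale`` (mean ``q``), and the baseline
noise is zero-mean Gaussian with standard deviation ``noise_sd``.

Key relations:

* quantal size        ``q = gamma_shape * lambda_scale``
* uniquantal CV       ``cv = 1 / sqrt(gamma_shape)``
* mean response       ``mu = n * p * q``

Amplitudes are analysed on a positive-going sign convention: loaders flip
the sign of inward currents or hyperpolarizing potentials, because the
gamma uniquantal density has support on (0, inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "QuantalParams",
    "ReleaseCondition",
    "ObservationSet",
    "binomial_pmf",
    "gamma_pdf",
    "noise_pdf",
    "composite_amplitude_density",
    "log_likelihood",
    "release_probability",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class QuantalParams:
    """One point in quantal parameter space.

    Parameters
    ----------
    n : int
        Number of release sites (>= 1).
    q : float
        Quantal size: mean of the uniquantal distribution, in response
        units (mV or pA depending on the recording mode).
    gamma_shape : float
        Shape parameter of the gamma uniquantal distribution
        (dimensionless); determines the uniquantal coefficient of
        variation via ``cv = 1/sqrt(gamma_shape)``.
    """

    n: int
    q: float
    gamma_shape: float

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if not self.q > 0:
            raise ValueError(f"quantal size q must be positive, got {self.q!r}")
        if not self.gamma_shape > 0:
            raise ValueError(
                f"gamma_shape must be positive, got {self.gamma_shape!r}"
            )

    @property
    def lambda_scale(self) -> float:
        """Latent gamma scale parameter, ``lambda = q / gamma_shape``."""
        return self.q / self.gamma_shape

    @property
    def cv(self) -> float:
        """Uniquantal coefficient of variation, ``1/sqrt(gamma_shape)``."""
        return 1.0 / math.sqrt(self.gamma_shape)

    @classmethod
    def from_cv(cls, n: int, q: float, cv: float) -> "QuantalParams":
        """Build parameters from the uniquantal CV instead of the shape."""
        if not cv > 0:
            raise ValueError(f"cv must be positive, got {cv!r}")
        return cls(n=n, q=q, gamma_shape=1.0 / cv**2)


@dataclass(frozen=True)
class ReleaseCondition:
    """A single release-probability condition (e.g. one Ca2+ level).

    ``p`` is the per-site release probability under this condition;
    ``mean_response`` and ``se_response`` summarise the observed
    amplitudes, and ``count`` is the number of sweeps.
    """

    index: int
    p: float
    mean_response: float = math.nan
    se_response: float = math.nan
    count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"release probability must lie in [0, 1], got {self.p!r}")
        if self.index < 0:
            raise ValueError("condition index must be non-negative")


def release_probability(params: QuantalParams, mean_response: float) -> float:
    """Per-site release probability implied by ``mu = n * p * q``."""
    return mean_response / (params.n * params.q)


class ObservationSet:
    """Evoked amplitudes grouped by release-probability condition.

    Parameters
    ----------
    amplitudes : sequence of 1-D arrays
        One vector of sweep amplitudes per condition, positive-going.
    noise_sd : float
        Standard deviation of the baseline noise, measured from the raw
        data (failure sweeps or a pre-stimulus window).
    condition_index : sequence of int, optional
        Labels for the conditions; defaults to ``0..c-1``.

    Notes
    -----
    Each condition needs at least two sweeps so that its standard error
    is defined.  Conditions with zero sweeps can only be created through
    :meth:`from_summary`, which exists for prior-predictive checks where
    only the condition means are known.
    """

    def __init__(
        self,
        amplitudes: Sequence[Sequence[float]],
        noise_sd: float,
        condition_index: Optional[Sequence[int]] = None,
    ) -> None:
        if not noise_sd > 0:
            raise ValueError(f"noise_sd must be positive, got {noise_sd!r}")
        amps = [np.asarray(a, dtype=float).ravel() for a in amplitudes]
        if len(amps) == 0:
            raise ValueError("ObservationSet needs at least one condition")
        for i, a in enumerate(amps):
            if a.size == 1:
                raise ValueError(
                    f"condition {i} has a single sweep; need >= 2 so the "
                    "standard error is defined"
                )
            if not np.all(np.isfinite(a)):
                raise ValueError(f"condition {i} contains non-finite amplitudes")
        self.amplitudes = amps
        self.noise_sd = float(noise_sd)
        if condition_index is None:
            condition_index = list(range(len(amps)))
        if len(condition_index) != len(amps):
            raise ValueError("condition_index length must match amplitudes")
        self.condition_index = [int(k) for k in condition_index]
        self._means_override: Optional[np.ndarray] = None

    @classmethod
    def from_summary(
        cls, means: Sequence[float], noise_sd: float
    ) -> "ObservationSet":
        """Data-free observation set carrying only condition means.

        Used for prior-predictive checks: the means fix the support of
        the quantal-size grid but no amplitudes enter the likelihood.
        """
        means = np.asarray(means, dtype=float).ravel()
        obj = cls([np.empty(0)] * means.size, noise_sd)
        obj._means_override = means
        return obj

    @property
    def n_conditions(self) -> int:
        return len(self.amplitudes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([a.size for a in self.amplitudes])

    @property
    def means(self) -> np.ndarray:
        if self._means_override is not None:
            return self._means_override
        return np.array([a.mean() for a in self.amplitudes])

    @property
    def sds(self) -> np.ndarray:
        """Unbiased (ddof=1) per-condition sample standard deviations."""
        return np.array(
            [a.std(ddof=1) if a.size >= 2 else math.nan for a in self.amplitudes]
        )

    @property
    def ses(self) -> np.ndarray:
        """Per-condition standard errors of the mean."""
        return self.sds / np.sqrt(np.maximum(self.counts, 1))

    def conditions(self, params: QuantalParams) -> list[ReleaseCondition]:
        """Release conditions with p derived from ``mu = n p q``."""
        out = []
        for k, (a, mu, se) in enumerate(zip(self.amplitudes, self.means, self.ses)):
            out.append(
                ReleaseCondition(
                    index=self.condition_index[k],
                    p=release_probability(params, mu),
                    mean_response=float(mu),
                    se_response=float(se),
                    count=int(a.size),
                )
            )
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ObservationSet(c={self.n_conditions}, counts={self.counts.tolist()}, "
            f"noise_sd={self.noise_sd:g})"
        )


def binomial_pmf(j, n: int, p: float):
    """Probability of ``j`` successful releases from ``n`` sites.

    Standard binomial mass ``C(n, j) p^j (1-p)^(n-j)``.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    jarr = np.asarray(j)
    if np.any(jarr < 0) or np.any(jarr > n):
        raise ValueError(f"j must lie in 0..n={n}, got {j!r}")
    out = stats.binom.pmf(jarr, n, p)
    return float(out) if np.isscalar(j) else out


def gamma_pdf(x, gamma_shape: float, lambda_scale: float):
    """Uniquantal gamma density ``x^(g-1) e^(-x/l) / (l^g Gamma(g))``."""
    if not gamma_shape > 0 or not lambda_scale > 0:
        raise ValueError("gamma_shape and lambda_scale must be positive")
    xarr = np.asarray(x, dtype=float)
    if np.any(xarr <= 0):
        raise ValueError("gamma_pdf is defined for positive x only")
    out = stats.gamma.pdf(xarr, a=gamma_shape, scale=lambda_scale)
    return float(out) if np.isscalar(x) else out


def noise_pdf(x, noise_sd: float):
    """Zero-mean Gaussian density of the baseline noise."""
    if not noise_sd > 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd!r}")
    out = stats.norm.pdf(np.asarray(x, dtype=float), loc=0.0, scale=noise_sd)
    return float(out) if np.isscalar(x) else out


def _composite_log_density(
    x: np.ndarray, p: float, params: QuantalParams, noise_sd: float
) -> np.ndarray:
    """Log of the composite quantal amplitude density, vectorised over x.

    The mixture is ``B(0; n, p) N(x | 0, eps) + sum_j B(j; n, p)
    G(x | j*gamma, lambda)``: the j-th gamma component is the exact
    distribution of the sum of j iid uniquantal gammas.  Accumulation is
    done with logsumexp so long sweep lists cannot underflow.
    """
    n = params.n
    jj = np.arange(n + 1)
    logw = stats.binom.logpmf(jj, n, p)
    comps = np.full((n + 1, x.size), -np.inf)
    comps[0] = logw[0] + stats.norm.logpdf(x, 0.0, noise_sd)
    pos = x > 0
    if np.any(pos):
        xp = x[pos]
        for j in range(1, n + 1):
            comps[j, pos] = logw[j] + stats.gamma.logpdf(
                xp, a=j * params.gamma_shape, scale=params.lambda_scale
            )
    return special.logsumexp(comps, axis=0)


def composite_amplitude_density(
    x, condition: ReleaseCondition, params: QuantalParams, noise_sd: float
):
    """Mixture density of an evoked amplitude under one release condition.

    A failure (j = 0 releases) contributes the noise Gaussian; j >= 1
    releases contribute a gamma with shape ``j * gamma_shape`` and scale
    ``lambda_scale``, so that the gamma components carry all mass on
    x > 0 and the noise term all mass elsewhere.
    """
    if not 0.0 <= condition.p <= 1.0:
        raise ValueError(
            f"release probability must lie in [0, 1], got {condition.p!r}"
        )
    if not noise_sd > 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd!r}")
    xarr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.exp(_composite_log_density(xarr, condition.p, params, noise_sd))
    return float(out[0]) if np.isscalar(x) else out.reshape(np.shape(x))


def log_likelihood(obs: ObservationSet, params: QuantalParams) -> float:
    """Composite quantal log-likelihood of an observation set.

    Per condition i the likelihood multiplies a Gaussian evaluated at the
    condition mean with SD equal to the standard error of its amplitudes
    -- a term that reduces to the constant weight ``-log(se * sqrt(2*pi))``
    and gives conditions with more sweeps more weight -- by the composite
    quantal density of every sweep amplitude.  The per-condition release
    probability is the latent ``p_i = mu_i / (n q)``; parameter points
    whose implied p_i falls outside [0, 1] have zero likelihood and
    return ``-inf`` (not an exception), as do points where any sweep
    density underflows to zero.

    The arbitrary grid offset L is *not* added here; it is applied once
    per grid during posterior evaluation.
    """
    total = 0.0
    for a, mu, se in zip(obs.amplitudes, obs.means, obs.ses):
        if a.size == 0:
            continue
        p = release_probability(params, mu)
        if p < 0.0 or p > 1.0:
            return -np.inf
        total += -(math.log(se) + _LOG_SQRT_2PI)
        logq = _composite_log_density(a, p, params, obs.noise_sd)
        if not np.all(np.isfinite(logq)):
            return -np.inf
        total += float(logq.sum())
    return total
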