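"""Statistics for nested (hierarchical) electrophysiology data.

Electrophysiological measurements are rarely independent: events come
from cells, cells from animals.  This module implements the analysis
toolbox for such data:

* :func:`icc_1_1` -- one-way random-effects intraclass correlation
  ICC(1,1) from ANOVA mean squares, quantifying how much variance lies
  between units (cells/animals) versus within.
* :func:`hedges_g` and :func:`bootstrap_effect` -- standardized and raw
  effect sizes with percentile bootstrap confidence intervals.
* :func:`hierarchical_bootstrap_effect` -- a two-level bootstrap
  (units, then events within units) that avoids pseudo-replication and
  gives every unit equal expected weight regardless of its event count.
* :func:`choose_analysis_path` -- the routing rule mapping ICC and
  per-unit observation counts to an analysis (treat as independent,
  hierarchical bootstrap, or recommend a linear mixed model -- the LMM
  itself is out of scope here and left to a dedicated fitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GroupSample",
    "ICCResult",
    "EffectSizeResult",
    "icc_1_1",
    "hedges_g",
    "bootstrap_effect",
    "hierarchical_bootstrap_effect",
    "choose_analysis_path",
]


@dataclass
class GroupSample:
    """Measurements with unit (cell) and optional animal nesting."""

    values: np.ndarray
    unit_id: np.ndarray
    group: Optional[str] = None
    animal_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.unit_id = np.asarray(self.unit_id).ravel()
        if self.values.size != self.unit_id.size:
            raise ValueError("values and unit_id must have equal length")
        if self.values.size == 0:
            raise ValueError("empty sample")

    def by_unit(self) -> list[np.ndarray]:
        units = np.unique(self.unit_id)
        return [self.values[self.unit_id == u] for u in units]


@dataclass(frozen=True)
class ICCResult:
    ms_between: float
    ms_within: float
    k_bar: float
    icc: float
    label: str


def _icc_label(icc: float) -> str:
    if icc <= 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_1_1(sample: GroupSample) -> ICCResult:
    """One-way random-effects intraclass correlation, ICC(1,1).

    ``(MS_between - MS_within) / (MS_between + (k - 1) MS_within)`` with
    the unit as the class.  For unbalanced designs ``k`` is the standard
    one-way correction ``k0 = (N - sum(n_i^2)/N) / (a - 1)``.  The label
    follows the conventional cut-points (poor <= 0.50 < moderate <=
    0.75 < good <= 0.90 < excellent).
    """
    groups = sample.by_unit()
    a = len(groups)
    if a < 2:
        raise ValueError("ICC needs at least two units")
    sizes = np.array([g.size for g in groups], dtype=float)
    n_total = sizes.sum()
    grand = sample.values.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_between = ss_between / (a - 1)
    df_within = n_total - a
    if df_within <= 0:
        raise ValueError("ICC needs at least one unit with > 1 observation")
    ms_within = ss_within / df_within
    if sizes.min() == sizes.max():
        k_bar = float(sizes[0])
    else:
        k_bar = float((n_total - (sizes**2).sum() / n_total) / (a - 1))
    denom = ms_between + (k_bar - 1.0) * ms_within
    if denom == 0:
        raise ValueError("no variance in the data; ICC undefined")
    icc = (ms_between - ms_within) / denom
    return ICCResult(
        ms_between=ms_between,
        ms_within=ms_within,
        k_bar=k_bar,
        icc=float(icc),
        label=_icc_label(icc),
    )


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    return math.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size - 1 + b.size - 1))


def hedges_g(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference ``(mean_a - mean_b) / pooled SD``.

    Group order convention: ``a`` is the case group and ``b`` the
    control, so positive g means the case group is larger.  The pooled
    SD uses the (n1 - 1) + (n2 - 1) denominator.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    sd = _pooled_sd(a, b)
    if sd == 0:
        raise ValueError("zero pooled standard deviation; g undefined")
    return float((a.mean() - b.mean()) / sd)


@dataclass
class EffectSizeResult:
    """Bootstrap distributions and percentile CIs for two effect sizes.

    ``mean_difference`` and ``hedges_g`` are the means of the respective
    bootstrap distributions; CIs are the 2.5/97.5 percentiles.  A
    comparison is flagged ``meaningful`` when its 95% CI excludes zero.
    ``n_dropped`` counts replicas discarded for a zero pooled SD.
    """

    mean_difference: float
    hedges_g: float
    mean_difference_ci: tuple[float, float]
    hedges_g_ci: tuple[float, float]
    mean_difference_draws: np.ndarray
    hedges_g_draws: np.ndarray
    n_replicas: int
    n_dropped: int
    seed: Optional[int]

    @property
    def meaningful_mean_difference(self) -> bool:
        lo, hi = self.mean_difference_ci
        return lo > 0 or hi < 0

    @property
    def meaningful_hedges_g(self) -> bool:
        lo, hi = self.hedges_g_ci
        return lo > 0 or hi < 0


def _effects_from_matrices(ra: np.ndarray, rb: np.ndarray):
    """Mean difference and g per bootstrap row; g is nan when pooled SD is 0."""
    ma, mb = ra.mean(axis=1), rb.mean(axis=1)
    va, vb = ra.var(axis=1, ddof=1), rb.var(axis=1, ddof=1)
    n1, n2 = ra.shape[1], rb.shape[1]
    pooled = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 - 1 + n2 - 1))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(pooled > 0, diff / pooled, np.nan)
    return diff, g


def _finish(diff: np.ndarray, g: np.ndarray, n_replicas: int, seed) -> EffectSizeResult:
    keep = np.isfinite(g)
    n_dropped = int(np.count_nonzero(~keep))
    diff, g = diff[keep], g[keep]
    if diff.size == 0:
        raise ValueError("every bootstrap replica had zero pooled SD")
    return EffectSizeResult(
        mean_difference=float(diff.mean()),
        hedges_g=float(g.mean()),
        mean_difference_ci=tuple(float(v) for v in np.percentile(diff, [2.5, 97.5])),
        hedges_g_ci=tuple(float(v) for v in np.percentile(g, [2.5, 97.5])),
        mean_difference_draws=diff,
        hedges_g_draws=g,
        n_replicas=n_replicas,
        n_dropped=n_dropped,
        seed=seed,
    )


def bootstrap_effect(
    a: Sequence[float],
    b: Sequence[float],
    n_replicas: int = 10_000,
    seed: Optional[int] = None,
    paired: bool = False,
) -> EffectSizeResult:
    """Bootstrapped mean difference and Hedges' g between two groups.

    Each replica resamples each group at its own size with replacement
    (or, with ``paired=True``, resamples index pairs jointly -- used for
    within-cell latency/jitter comparisons) and recomputes both effect
    sizes.  Replicas whose pooled SD is zero are dropped and counted.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if paired and a.size != b.size:
        raise ValueError("paired resampling needs equal group sizes")
    rng = np.random.default_rng(seed)
    if paired:
        idx = rng.integers(0, a.size, size=(n_replicas, a.size))
        ra, rb = a[idx], b[idx]
    else:
        ra = a[rng.integers(0, a.size, size=(n_replicas, a.size))]
        rb = b[rng.integers(0, b.size, size=(n_replicas, b.size))]
    diff, g = _effects_from_matrices(ra, rb)
    return _finish(diff, g, n_replicas, seed)


def _hier_setup(sample: GroupSample):
    per_unit = sample.by_unit()
    if len(per_unit) < 2:
        raise ValueError("hierarchical bootstrap needs >= 2 units per group")
    lens = np.array([u.size for u in per_unit])
    if lens.min() < 1:
        raise ValueError("every unit needs >= 1 event")
    k = int(lens.max())
    padded = np.zeros((len(per_unit), k))
    for i, u in enumerate(per_unit):
        padded[i, : u.size] = u
    return padded, lens, k


def _hier_resample(padded, lens, k, rng, n_rep) -> np.ndarray:
    n_units = padded.shape[0]
    uidx = rng.integers(0, n_units, size=(n_rep, n_units))
    eidx = (rng.random((n_rep, n_units, k)) * lens[uidx][..., None]).astype(np.intp)
    vals = padded[uidx[..., None], eidx]
    return vals.reshape(n_rep, n_units * k)


def hierarchical_bootstrap_effect(
    a: GroupSample,
    b: GroupSample,
    n_replicas: int = 10_000,
    seed: Optional[int] = None,
    max_chunk_elements: int = 20_000_000,
) -> EffectSizeResult:
    """Two-level bootstrap: resample units, then events within units.

    Per replica and group: draw n units with replacement (n = number of
    units in that group), then k events with replacement from each drawn
    unit (k = the maximum events-per-unit in that group), and pool the
    n*k events.  A unit with a single event contributes that value k
    times when sampled.  Effect sizes per replica as in
    :func:`bootstrap_effect`.  Work is chunked to bound memory.
    """
    pa, la, ka = _hier_setup(a)
    pb, lb, kb = _hier_setup(b)
    rng = np.random.default_rng(seed)
    row_elems = pa.shape[0] * ka + pb.shape[0] * kb
    chunk = max(1, min(n_replicas, max_chunk_elements // max(row_elems, 1)))
    diffs, gs = [], []
    done = 0
    while done < n_replicas:
        m = min(chunk, n_replicas - done)
        ra = _hier_resample(pa, la, ka, rng, m)
        rb = _hier_resample(pb, lb, kb, rng, m)
        d, g = _effects_from_matrices(ra, rb)
        diffs.append(d)
        gs.append(g)
        done += m
    return _finish(np.concatenate(diffs), np.concatenate(gs), n_replicas, seed)


def choose_analysis_path(
    icc: ICCResult, min_obs_per_unit: int, total_obs: int
) -> str:
    """Route a nested dataset to an analysis strategy.

    ICC at or below 0.50 (most variance within units): treat
    observations as independent and bootstrap directly.  Above 0.50 with
    rich units (>= 20 observations each): hierarchical bootstrap.  Above
    0.50 with sparse units: recommend a linear mixed model (routing
    only; no model is fitted here).  ``total_obs`` is accepted for
    context/reporting and does not alter the rule.
    """
    if icc.icc <= 0.50:
        return "independent_bootstrap"
    if min_obs_per_unit >= 20:
        return "hierarchical_bootstrap"
    return "lmm_recommended"
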