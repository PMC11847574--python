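"""File formats and run configuration.

Tabular I/O is plain CSV (RFC 4180, UTF-8, "." decimal); estimates and
manifests are JSON.  Schemas:

* observations: columns ``condition_id, amplitude``; a JSON sidecar
  (``<file>.json``) or an explicit argument supplies ``noise_sd``.
* sweeps: columns ``time_s, value``; the JSON sidecar carries units,
  ``stimulus_times`` and ``baseline_window``.
* group tables (long format): columns ``group, animal_id, unit_id,
  value``.

Amplitude units are metadata only -- every computation is unit-agnostic
except the conductance operations, which require mV/pA/nS consistency.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ObservationSet
from .ephys import SweepTrace
from .grid import GridSpec, QuantalEstimates
from .stats import GroupSample

__all__ = [
    "AnalysisConfig",
    "read_observation_csv",
    "write_observation_csv",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_group_csv",
    "group_samples_from_frame",
    "estimates_to_dict",
    "write_estimates",
    "write_marginals_csv",
    "write_manifest",
    "load_config",
]

PathLike = Union[str, Path]


@dataclass
class AnalysisConfig:
    """Resolved settings of a run; defaults reproduce the reference
    analysis (128 x 64 grid, CV [0.05, 1.0], p [0.04, 0.96], 10,000
    bootstrap replicas, 95% CI)."""

    grid: GridSpec = field(default_factory=GridSpec)
    noise_mode: str = "known"
    sign_convention: str = "outward_positive"
    seed: int = 0
    n_replicas: int = 10_000
    ci_level: float = 95.0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.noise_mode not in ("known", "estimated"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.sign_convention not in ("inward_negative", "outward_positive"):
            raise ValueError(f"unknown sign_convention {self.sign_convention!r}")


def load_config(path: PathLike) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML file; grid options nest under
    a ``grid`` key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    grid_kwargs = raw.pop("grid", {}) or {}
    for key in ("cv_range", "p_range"):
        if key in grid_kwargs:
            grid_kwargs[key] = tuple(grid_kwargs[key])
    return AnalysisConfig(grid=GridSpec(**grid_kwargs), **raw)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_observation_csv(
    path: PathLike,
    noise_sd: Optional[float] = None,
    sign_convention: str = "outward_positive",
) -> ObservationSet:
    """Read an amplitude table into an :class:`ObservationSet`.

    Row order within each condition is preserved; ``inward_negative``
    flips the sign so amplitudes are positive-going.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    missing = {"condition_id", "amplitude"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    amp = pd.to_numeric(df["amplitude"], errors="coerce")
    bad = amp.isna() & df["amplitude"].notna() | df["amplitude"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: non-numeric amplitude at row {row}")
    if sign_convention == "inward_negative":
        amp = -amp
    elif sign_convention != "outward_positive":
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    if noise_sd is None:
        sidecar = _sidecar(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            noise_sd = meta.get("noise_sd")
        if noise_sd is None:
            raise ValueError(
                f"{path}: noise_sd not given and no sidecar {sidecar.name} found"
            )
    order = []
    groups: dict = {}
    for cid, sub in amp.groupby(df["condition_id"], sort=False):
        order.append(cid)
        groups[cid] = sub.to_numpy()
    for cid in order:
        if groups[cid].size < 2:
            raise ValueError(
                f"{path}: condition {cid!r} has {groups[cid].size} sweep(s); need >= 2"
            )
    idx = list(range(len(order)))
    return ObservationSet([groups[c] for c in order], noise_sd=float(noise_sd), condition_index=idx)


def write_observation_csv(
    obs: ObservationSet, path: PathLike, extra_meta: Optional[dict] = None
) -> None:
    """Write an amplitude table plus JSON sidecar (noise_sd, metadata)."""
    path = Path(path)
    rows = []
    for k, amps in zip(obs.condition_index, obs.amplitudes):
        for x in amps:
            rows.append((k, x))
    pd.DataFrame(rows, columns=["condition_id", "amplitude"]).to_csv(path, index=False)
    meta = {"noise_sd": obs.noise_sd}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_sweep_csv(path: PathLike) -> SweepTrace:
    """Read a two-column (time_s, value) sweep and its JSON sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: a sweep needs >= 2 samples")
    dt = float(np.median(np.diff(t)))
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    bw = meta.get("baseline_window")
    return SweepTrace(
        samples=df["value"].to_numpy(dtype=float),
        sample_interval=dt,
        stimulus_times=tuple(meta.get("stimulus_times", ())),
        baseline_window=tuple(bw) if bw else None,
    )


def write_sweep_csv(trace: SweepTrace, path: PathLike, units: str = "") -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "value": trace.samples}).to_csv(path, index=False)
    meta = {
        "units": units,
        "sample_interval": trace.sample_interval,
        "stimulus_times": list(trace.stimulus_times),
        "baseline_window": list(trace.baseline_window) if trace.baseline_window else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_group_csv(path: PathLike) -> pd.DataFrame:
    """Read a long-format group table (group, animal_id, unit_id, value)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"group", "unit_id", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
        raise ValueError(f"{path}: non-numeric value at row {row}")
    df = df.copy()
    df["value"] = vals
    return df


def group_samples_from_frame(df: pd.DataFrame) -> dict[str, GroupSample]:
    """Split a long-format table into per-group :class:`GroupSample`s."""
    out = {}
    for name, sub in df.groupby("group", sort=False):
        out[str(name)] = GroupSample(
            values=sub["value"].to_numpy(),
            unit_id=sub["unit_id"].to_numpy(),
            group=str(name),
            animal_id=sub["animal_id"].to_numpy() if "animal_id" in sub else None,
        )
    return out


def estimates_to_dict(est: QuantalEstimates) -> dict:
    return {
        "n_hat": est.n_hat,
        "q_hat": est.q_hat,
        "gamma_hat": est.gamma_hat,
        "lambda_hat": est.lambda_hat,
        "cv_hat": est.cv_hat,
        "p_hat": list(map(float, est.p_hat)),
        "p_warning": est.p_warning,
    }


def write_estimates(est: QuantalEstimates, path: PathLike) -> None:
    Path(path).write_text(json.dumps(estimates_to_dict(est), indent=2))


def write_marginals_csv(est: QuantalEstimates, directory: PathLike) -> list[Path]:
    """Write the three marginal posteriors as CSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    frames = {
        "marginal_n.csv": pd.DataFrame(
            {"n": est.n_values, "posterior": est.marginal_n}
        ),
        "marginal_q.csv": pd.DataFrame(
            {"q": np.exp(est.log_q_axis), "posterior": est.marginal_log_q}
        ),
        "marginal_gamma.csv": pd.DataFrame(
            {"gamma": np.exp(est.log_gamma_axis), "posterior": est.marginal_log_gamma}
        ),
    }
    for name, frame in frames.items():
        p = directory / name
        frame.to_csv(p, index=False)
        paths.append(p)
    return paths


def write_manifest(
    directory: PathLike, config: AnalysisConfig, command: str, inputs: Optional[dict] = None
) -> Path:
    """Record everything needed to reproduce a run bit-identically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "quantal",
        "version": __version__,
        "command": command,
        "seed": config.seed,
        "config": {
            "grid": asdict(config.grid),
            "noise_mode": config.noise_mode,
            "sign_convention": config.sign_convention,
            "n_replicas": config.n_replicas,
            "ci_level": config.ci_level,
        },
        "inputs": inputs or {},
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
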