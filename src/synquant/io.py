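"""File formats and run configuration.

Sweep data travels as delimited text (CSV with header) with columns
``sweep_id, spike_time_s, amplitude_mV``; rows are grouped by sweep and
time-ordered within a sweep.  Posterior samples are written as CSV
(iteration, one column per free parameter, loglik) and summaries as JSON.
All units are fixed — seconds and millivolts — and never rescaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams, SpikeTrain, Variant
from .inference import PARAM_ORDER, Chain, ParameterGrid, PosteriorSummary
from .likelihood import Dataset, Sweep

__all__ = [
    "read_sweeps",
    "write_sweeps",
    "write_truth",
    "write_posterior",
    "read_posterior",
    "write_summary",
    "read_summary",
    "RunConfig",
    "read_params_file",
]

_SWEEP_COLUMNS = ["sweep_id", "spike_time_s", "amplitude_mV"]
_FLOAT_FMT = "%.12g"  # >= 9 significant digits, lossless for our data


def read_sweeps(path) -> Dataset:
    """Read a sweep CSV into a Dataset, enforcing format invariants."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse sweep file {path}: {exc}") from exc
    if list(df.columns) != _SWEEP_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_SWEEP_COLUMNS}, got {list(df.columns)}"
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: missing cell at line {bad}")
    sweeps = []
    for sweep_id, group in df.groupby("sweep_id", sort=False):
        times = group["spike_time_s"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(
                f"{path}: spike times not strictly increasing in sweep {sweep_id!r}"
            )
        amps = group["amplitude_mV"].to_numpy(dtype=float)
        sweeps.append(Sweep(spikes=SpikeTrain(times), amplitudes=amps))
    return Dataset(sweeps=tuple(sweeps))


def write_sweeps(dataset: Dataset, path) -> None:
    """Write a Dataset to sweep CSV (round-trips through read_sweeps)."""
    path = Path(path)
    rows = []
    for i, sweep in enumerate(dataset):
        for t, a in zip(sweep.spikes.times, sweep.amplitudes):
            rows.append((i, t, a))
    df = pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_truth(truths, path) -> None:
    """Ground-truth sidecar: sweep_id, spike_index, k, y_before."""
    rows = []
    for i, tr in enumerate(truths):
        for m, (k, y) in enumerate(zip(tr.k, tr.y_before)):
            rows.append((i, m, int(k), int(y)))
    pd.DataFrame(rows, columns=["sweep_id", "spike_index", "k", "y_before"]).to_csv(
        path, index=False
    )


def write_posterior(chain: Chain, path) -> None:
    """Posterior sample table: iteration, free parameters, loglik."""
    if len(chain) == 0:
        raise ValueError("refusing to write an empty chain")
    path = Path(path)
    data = {"iteration": np.arange(chain.burn_in, chain.n_samples)}
    for p in chain.grid.free_names:
        data[p] = chain.values(p)
    data["loglik"] = chain.logliks
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_posterior(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "loglik" not in df.columns or "iteration" not in df.columns:
        raise ValueError(f"{path}: not a posterior table (iteration/loglik missing)")
    return df


def write_summary(summary: PosteriorSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")


def read_summary(path) -> PosteriorSummary:
    return PosteriorSummary.from_dict(json.loads(Path(path).read_text()))


_GRID_KEYS = {"min", "max", "step", "points", "scale", "value", "values"}
_SAMPLER_KEYS = {"samples", "burn_in", "chains", "seed"}
_CONFIG_KEYS = {"variant", "mode", "grid", "sampler", "level"}


@dataclass
class RunConfig:
    """Validated inference run configuration (YAML or JSON)."""

    variant: Variant
    grid: ParameterGrid
    mode: str = "correlated"
    samples: int = 100_000
    burn_in: int | None = None
    chains: int = 1
    seed: int = 0
    level: float = 0.95

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        variant = Variant(data.get("variant", "depression_facilitation"))
        mode = data.get("mode", "correlated")
        if mode not in ("correlated", "uncorrelated"):
            raise ValueError(f"unknown mode {mode!r}")
        grid_spec = data.get("grid")
        if not isinstance(grid_spec, dict) or not grid_spec:
            raise ValueError("config must contain a non-empty 'grid' mapping")
        axes: dict[str, np.ndarray] = {}
        clamps: dict[str, float] = {}
        for name, spec in grid_spec.items():
            axes_or_clamp = _parse_axis(name, spec)
            if isinstance(axes_or_clamp, float):
                clamps[name] = axes_or_clamp
            else:
                axes[name] = axes_or_clamp
        grid = ParameterGrid(axes=axes, clamps=clamps, variant=variant)
        sampler = data.get("sampler", {})
        unknown = set(sampler) - _SAMPLER_KEYS
        if unknown:
            raise ValueError(f"unknown sampler key(s): {sorted(unknown)}")
        return cls(
            variant=variant,
            grid=grid,
            mode=mode,
            samples=int(sampler.get("samples", 100_000)),
            burn_in=None if sampler.get("burn_in") is None else int(sampler["burn_in"]),
            chains=int(sampler.get("chains", 1)),
            seed=int(sampler.get("seed", 0)),
            level=float(data.get("level", 0.95)),
        )


def _parse_axis(name: str, spec):
    if isinstance(spec, (int, float)):
        return float(spec)
    if not isinstance(spec, dict):
        raise ValueError(f"grid entry {name!r} must be a mapping or a number")
    unknown = set(spec) - _GRID_KEYS
    if unknown:
        raise ValueError(f"grid entry {name!r}: unknown key(s) {sorted(unknown)}")
    if "value" in spec:
        return float(spec["value"])
    if "values" in spec:
        return np.asarray(spec["values"], dtype=float)
    lo, hi = float(spec["min"]), float(spec["max"])
    scale = spec.get("scale", "linear")
    if "step" in spec:
        if scale != "linear":
            raise ValueError(f"grid entry {name!r}: 'step' requires linear scale")
        return np.arange(lo, hi + 0.5 * float(spec["step"]), float(spec["step"]))
    points = int(spec["points"])
    if scale == "log":
        return np.geomspace(lo, hi, points)
    if scale == "linear":
        return np.linspace(lo, hi, points)
    raise ValueError(f"grid entry {name!r}: unknown scale {scale!r}")


def read_params_file(path) -> ModelParams:
    """Read true model parameters from a YAML/JSON mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    allowed = set(PARAM_ORDER) | {"variant"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return ModelParams(**data)
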