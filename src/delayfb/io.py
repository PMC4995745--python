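"""Configuration and tabular input/output.

Model configurations are plain YAML key-value files (model_id plus the
scalar parameters I, alpha, beta, delta, tau, n, K_m, nu, kappa).
Trajectories are CSV files (columns t, C, R) with a JSON metadata
sidecar carrying the full parameter set for provenance; observed time
series are two-column delimited text with '#' comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dde import Trajectory
from .fitting import TimeSeriesData
from .models import ModelParams, ModelSpec
from .stability import StabilityResult

__all__ = [
    "read_config",
    "params_from_config",
    "write_trajectory",
    "read_trajectory",
    "read_timeseries",
    "write_timeseries",
    "stability_report",
    "write_json",
]


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return cfg


def params_from_config(cfg: dict) -> tuple[ModelSpec, ModelParams]:
    """Validated (ModelSpec, ModelParams) from a config mapping."""
    if "model_id" not in cfg:
        raise ValueError("config must set model_id (1-4)")
    spec = ModelSpec(int(cfg["model_id"]))
    params = ModelParams.from_dict(cfg)
    return spec, params


def _provenance(extra: dict | None = None) -> dict:
    out = {"package": "delayfb", "version": __version__}
    if extra:
        out.update(extra)
    return out


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"t": traj.t, "C": traj.C, "R": traj.R})
    # %.17g round-trips doubles exactly, keeping write->read->write a fixed point
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(_provenance(traj.meta), fh, indent=2, default=float)


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return Trajectory(
        t=df["t"].to_numpy(), C=df["C"].to_numpy(), R=df["R"].to_numpy(), meta=meta
    )


def read_timeseries(path: str | Path) -> TimeSeriesData:
    arr = np.loadtxt(path, comments="#")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (t, value)")
    return TimeSeriesData(t=arr[:, 0], x=arr[:, 1])


def write_timeseries(data: TimeSeriesData, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for t, x in zip(data.t, data.x):
            fh.write(f"{t:.10g}\t{x:.10g}\n")


def stability_report(spec: ModelSpec, params: ModelParams, res: StabilityResult) -> dict:
    """Flat JSON-ready report of one stability classification."""
    return _provenance({
        "model_id": spec.model_id,
        "params": params.to_dict(),
        "C_s": res.equilibrium.C_s,
        "R_s": res.equilibrium.R_s,
        "x": res.coeffs.x,
        "y": res.coeffs.y,
        "classification": res.classification,
        "tau_m": res.tau_m,
        "omega": res.omega,
    })


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")
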