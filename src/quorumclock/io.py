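"""File formats: YAML/JSON configs, HDF5 trajectory container, CSV tables.

Conventions: time columns are always minutes; species columns are named
exactly as the ``CellState`` fields; CSV files carry '#'-prefixed metadata
header lines and round-trip losslessly at 1e-12 relative precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .emulator import ClusterTraceSet
from .ensemble import EnsembleTrajectory
from .errors import ConfigError
from .model import ModelParameters, SPECIES

#: Keys a run config may carry in addition to the ModelParameters fields.
RUN_KEYS = ("n_cells", "t_end", "dt_out", "seed", "transient",
            "init_high", "dt_internal")

_RUN_DEFAULTS = {"n_cells": 500, "t_end": 20000.0, "dt_out": 20.0, "seed": 0,
                 "transient": 500.0, "init_high": 50.0, "dt_internal": 0.01}


def load_config(path) -> tuple[ModelParameters, dict]:
    """Parse a flat YAML/JSON key-value config.

    Keys naming ``ModelParameters`` fields configure the model; the run keys
    in :data:`RUN_KEYS` configure the simulation.  Any other key raises
    :class:`ConfigError` naming the offending key.
    Returns ``(params, run_settings)``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a flat key-value mapping")
    param_names = {f.name for f in dataclasses.fields(ModelParameters)}
    params_d, run_d = {}, dict(_RUN_DEFAULTS)
    for key, val in data.items():
        if key in param_names:
            params_d[key] = val
        elif key in RUN_KEYS:
            run_d[key] = val
        else:
            raise ConfigError(f"unknown config key: {key!r}", key=key)
    try:
        params = ModelParameters(**params_d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from exc
    return params, run_d


def save_config(path, params: ModelParameters, run: dict | None = None) -> None:
    data = params.to_dict()
    if run:
        data.update({k: run[k] for k in RUN_KEYS if k in run})
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_trajectory_h5(path, traj: EnsembleTrajectory) -> None:
    """Store a trajectory as an HDF5 hierarchy (times/values/cell_scales)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("values", data=traj.values, compression="gzip")
        f.create_dataset("cell_scales", data=traj.cell_scales)
        f.attrs["species"] = list(SPECIES)
        f.attrs["seed"] = -1 if traj.seed is None else traj.seed
        f.attrs["n_clipped"] = traj.n_clipped
        f.attrs["params_json"] = json.dumps(traj.params.to_dict())


def read_trajectory_h5(path) -> EnsembleTrajectory:
    with h5py.File(path, "r") as f:
        params = ModelParameters.from_dict(json.loads(f.attrs["params_json"]))
        seed = int(f.attrs["seed"])
        return EnsembleTrajectory(
            times=f["times"][:], values=f["values"][:], params=params,
            seed=None if seed < 0 else seed, cell_scales=f["cell_scales"][:],
            n_clipped=int(f.attrs["n_clipped"]))


def _write_csv(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.15g")


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a '#'-headed CSV; returns (frame, metadata dict)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def write_gfp_summary(path, traj: EnsembleTrajectory) -> None:
    """Per-cell GFP table plus arithmetic- and weighted-mean columns."""
    from .analysis import weighted_mean_trace
    g = traj.gfp
    df = pd.DataFrame(g, columns=[f"cell_{i}" for i in range(traj.n_cells)])
    df.insert(0, "time_min", traj.times)
    df["arithmetic_mean"] = g.mean(axis=1)
    df["weighted_mean"] = weighted_mean_trace(g)
    _write_csv(path, df, {"columns": "time_min, per-cell GFP, means",
                          "species": "p_GFP", "n_cells": traj.n_cells,
                          "seed": traj.seed})


def write_cluster_csv(path, cts: ClusterTraceSet) -> None:
    df = pd.DataFrame(cts.intensities,
                      columns=[f"cluster_{c}" for c in cts.cluster_ids])
    df.insert(0, "time_min", cts.frame_times)
    meta = {"frame_grid": "inclusive from 0, every "
                          f"{cts.frame_interval:g} min ({len(cts.frame_times)} frames)"}
    meta.update(cts.noise_meta)
    _write_csv(path, df, meta)


def read_cluster_csv(path):
    """Returns (frame_times, intensities, metadata)."""
    df, meta = read_csv(path)
    times = df["time_min"].to_numpy()
    cols = [c for c in df.columns if c.startswith("cluster_")]
    return times, df[cols].to_numpy(), meta


class Manifest:
    """Run manifest: config snapshot, seeds, runtimes, output checksums."""

    def __init__(self, command: str, params: ModelParameters, run: dict):
        from . import __version__
        self.data = {"command": command, "package_version": __version__,
                     "params": params.to_dict(), "run": dict(run),
                     "stages": {}, "outputs": {}}
        self._t0 = _time.monotonic()

    def stage_done(self, name: str) -> None:
        self.data["stages"][name] = round(_time.monotonic() - self._t0, 3)
        self._t0 = _time.monotonic()

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["outputs"][path.name] = digest

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))
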