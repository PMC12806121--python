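"""Writers, readers and run manifests for reproducible runs."""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .fde import Trajectory

CSV_COLUMNS = ("time", "node", "variable", "value")


def trajectory_to_frame(
    traj: Trajectory, variable_names: list[str], n_nodes: int = 1
) -> pd.DataFrame:
    """Tidy long format: one row per (time, node, variable)."""
    if len(variable_names) * n_nodes != traj.states.shape[1]:
        raise ValueError("variable_names x n_nodes does not match state dimension")
    # states are blocked by variable then node
    times = []
    nodes = []
    variables = []
    values = []
    for ti, t in enumerate(traj.times):
        for vi, name in enumerate(variable_names):
            block = traj.states[ti, vi * n_nodes : (vi + 1) * n_nodes]
            times.append(np.full(n_nodes, t))
            nodes.append(np.arange(n_nodes))
            variables.append(np.full(n_nodes, name, dtype=object))
            values.append(block)
    return pd.DataFrame(
        {
            "time": np.concatenate(times),
            "node": np.concatenate(nodes),
            "variable": np.concatenate(variables),
            "value": np.concatenate(values),
        }
    )


def write_trajectory_csv(
    traj: Trajectory, path: str | Path, variable_names: list[str], n_nodes: int = 1
) -> None:
    trajectory_to_frame(traj, variable_names, n_nodes).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> tuple[Trajectory, list[str], int]:
    """Inverse of :func:`write_trajectory_csv` (exact round trip)."""
    df = pd.read_csv(path)
    if tuple(df.columns) != CSV_COLUMNS:
        raise ValueError(f"unexpected columns {tuple(df.columns)}")
    times = df["time"].unique()
    variables = list(df["variable"].unique())
    n_nodes = int(df["node"].max()) + 1
    states = np.empty((len(times), len(variables) * n_nodes))
    for ti, t in enumerate(times):
        sub = df[df["time"] == t]
        for vi, name in enumerate(variables):
            vals = sub[sub["variable"] == name].sort_values("node")["value"].to_numpy()
            states[ti, vi * n_nodes : (vi + 1) * n_nodes] = vals
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    traj = Trajectory(times, states, alpha=float("nan"), dt=dt, solver="from-csv")
    return traj, variables, n_nodes


def write_trajectory_hdf5(
    traj: Trajectory, path: str | Path, variable_names: list[str], n_nodes: int = 1
) -> None:
    """Compact binary option for large network runs (requires h5py)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("states", data=traj.states, compression="gzip")
        f.attrs["alpha"] = traj.alpha
        f.attrs["dt"] = traj.dt
        f.attrs["solver"] = traj.solver
        f.attrs["variables"] = variable_names
        f.attrs["n_nodes"] = n_nodes


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    input_files: list[str | Path] = (),
    seed: int | None = None,
) -> dict:
    """JSON run manifest: resolved config, version, seeds, input checksums."""
    from . import __version__

    manifest = {
        "package": "fracbrain",
        "version": __version__,
        "config": config,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in input_files},
        "platform": platform.platform(),
        "python": platform.python_version(),
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
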