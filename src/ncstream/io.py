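"""Configuration files, trajectory serialization, and run manifests.

Configurations are flat key–value documents (YAML mapping syntax, one
key per parameter, e.g. ``lambda_fn: 60``); unknown keys are rejected.
Trajectories are written as two CSV tables (cells and FN elements, one
row per agent per snapshot) plus a JSON manifest that records the full
parameter snapshot, the seed, and the software version — enough to
re-run the realization bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import Snapshot, Trajectory
from .params import SimulationParameters, parameters_from_dict, validate

__all__ = ["ConfigError", "load_config", "save_config",
           "write_trajectory", "read_trajectory"]


class ConfigError(ValueError):
    """A configuration file could not be turned into valid parameters."""


def load_config(path: str | Path) -> SimulationParameters:
    """Parse a key–value config; defaults overlaid with the file's values."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    try:
        params = parameters_from_dict(data)
    except KeyError as exc:
        raise ConfigError(f"{path}: {exc.args[0]}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    issues = validate(params)
    if issues:
        raise ConfigError(f"{path}: " + "; ".join(issues))
    return params


def save_config(params: SimulationParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def _cells_frame(snap: Snapshot) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": snap.t,
            "id": np.arange(snap.n_cells),
            "phenotype": np.where(snap.leader, "secretory", "non_secretory"),
            "x": snap.pos[:, 0],
            "y": snap.pos[:, 1],
            "vx": snap.vel[:, 0],
            "vy": snap.vel[:, 1],
        }
    )


def _fn_frame(snap: Snapshot) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": snap.t,
            "x": snap.fn_pos[:, 0],
            "y": snap.fn_pos[:, 1],
            "kind": np.where(snap.fn_fiber, "fiber", "punctum"),
            "phi": np.where(snap.fn_fiber, snap.fn_phi, np.nan),
        }
    )


def write_trajectory(traj: Trajectory, out_dir: str | Path) -> dict[str, Path]:
    """Write cells.csv, fn.csv and manifest.json; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells_path = out / "cells.csv"
    fn_path = out / "fn.csv"
    manifest_path = out / "manifest.json"
    pd.concat([_cells_frame(s) for s in traj.snapshots]).to_csv(
        cells_path, index=False
    )
    pd.concat([_fn_frame(s) for s in traj.snapshots]).to_csv(fn_path, index=False)
    manifest = {
        "seed": traj.seed,
        "params": traj.params.to_dict(),
        "version": __version__,
        "written_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "files": {"cells": cells_path.name, "fn": fn_path.name},
        "snapshot_times": [s.t for s in traj.snapshots],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"cells": cells_path, "fn": fn_path, "manifest": manifest_path}


def read_trajectory(out_dir: str | Path) -> Trajectory:
    """Reload a written trajectory (state only; RNG stream is not restored)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    params = parameters_from_dict(manifest["params"])
    cells = pd.read_csv(out / "cells.csv")
    fn = pd.read_csv(out / "fn.csv")
    snapshots = []
    for t in manifest["snapshot_times"]:
        c = cells[np.isclose(cells["t"], t)]
        f = fn[np.isclose(fn["t"], t)]
        snapshots.append(
            Snapshot(
                t=float(t),
                pos=c[["x", "y"]].to_numpy(),
                vel=c[["vx", "vy"]].to_numpy(),
                leader=(c["phenotype"] == "secretory").to_numpy(),
                fn_pos=f[["x", "y"]].to_numpy(),
                fn_fiber=(f["kind"] == "fiber").to_numpy(),
                fn_phi=np.nan_to_num(f["phi"].to_numpy()),
            )
        )
    return Trajectory(params=params, seed=manifest["seed"], snapshots=snapshots)


def records_to_frame(records) -> pd.DataFrame:
    """SummaryRecord list → tidy DataFrame (one row per realization)."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])
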