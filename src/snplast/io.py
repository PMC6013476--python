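"""Result serialization: JSON manifest + CSV trial table + NPZ arrays.

A saved experiment directory holds everything needed to reproduce the run
bit-for-bit (config snapshot, master seed, per-simulation derived seeds,
package version) plus the per-trial table and any arrays (occupancy,
weight snapshots, sampled trajectories/actions).
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .protocols import ExperimentResult, TrialRecord, derive_seeds

MANIFEST = "manifest.json"
TRIALS = "trials.csv"
ARRAYS = "arrays.npz"
FORMAT_VERSION = 1


def write_results(result: ExperimentResult, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = result.config.get("m", 0)
    manifest = dict(
        format_version=FORMAT_VERSION,
        tool_version=__version__,
        written=datetime.now(timezone.utc).isoformat(),
        config=result.config,
        master_seed=result.master_seed,
        sim_seeds=[int(s) for s in derive_seeds(result.master_seed, m)] if m else [],
    )
    (path / MANIFEST).write_text(json.dumps(manifest, indent=2))
    result.table().to_csv(path / TRIALS, index=False)
    arrays = {}
    if result.occupancy is not None:
        arrays["occupancy"] = result.occupancy
    for (sim, tr), w in result.weight_snapshots.items():
        arrays[f"w_snapshot_{sim}_{tr}"] = w
    for rec in result.trials:
        if rec.trajectory is not None:
            arrays[f"traj_{rec.sim}_{rec.trial}"] = rec.trajectory
        if rec.actions is not None:
            arrays[f"acts_{rec.sim}_{rec.trial}"] = rec.actions
    if arrays:
        np.savez_compressed(path / ARRAYS, **arrays)
    return path


def read_results(path) -> ExperimentResult:
    path = Path(path)
    try:
        manifest = json.loads((path / MANIFEST).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError(f"corrupt or missing manifest in {path}: {exc}") from exc
    if manifest.get("format_version") != FORMAT_VERSION:
        raise IOError(
            f"result format version {manifest.get('format_version')} "
            f"not supported (expected {FORMAT_VERSION})"
        )
    table = pd.read_csv(path / TRIALS) if (path / TRIALS).exists() else pd.DataFrame()
    arrays = {}
    if (path / ARRAYS).exists():
        with np.load(path / ARRAYS) as z:
            arrays = {k: z[k] for k in z.files}
    result = ExperimentResult(config=manifest["config"],
                              master_seed=manifest["master_seed"])
    for _, row in table.iterrows():
        sim, tr = int(row["sim"]), int(row["trial"])
        result.trials.append(TrialRecord(
            sim=sim, trial=tr, success=bool(row["success"]),
            t_rew=None if pd.isna(row["t_rew"]) else float(row["t_rew"]),
            duration=float(row["duration"]), bounces=int(row["bounces"]),
            entered_old=bool(row["entered_old"]),
            visited_left=bool(row["visited_left"]),
            visited_right=bool(row["visited_right"]),
            arm=None if row["arm"] < 0 else int(row["arm"]),
            trajectory=arrays.get(f"traj_{sim}_{tr}"),
            actions=arrays.get(f"acts_{sim}_{tr}"),
        ))
    result.occupancy = arrays.get("occupancy")
    for k, v in arrays.items():
        if k.startswith("w_snapshot_"):
            _, _, sim, tr = k.split("_")
            result.weight_snapshots[(int(sim), int(tr))] = v
    return result
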