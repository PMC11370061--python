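"""Tabular I/O: profile/phenotype CSVs, long-format trajectory CSVs.

Trajectory files are long format with columns (subject_id, trial, frame,
marker, x_mm, y_mm, z_mm), marker in {elbow, wrist_ulnar, wrist_radial,
hand_dorsum}, accompanied by a JSON sidecar holding the sample rate and
the generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import MARKERS, TrialTrajectory

TRAJECTORY_COLUMNS = ("subject_id", "trial", "frame", "marker", "x_mm", "y_mm", "z_mm")


class SchemaError(Exception):
    """Input file does not match the documented column contract."""


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_trajectories(
    trials_by_subject: dict[str, list[TrialTrajectory]],
    csv_path: str | Path,
    sidecar: dict | None = None,
) -> None:
    csv_path = Path(csv_path)
    chunks = []
    sample_rate = None
    for sid, trials in trials_by_subject.items():
        for t in trials:
            sample_rate = t.sample_rate
            n = t.n_frames
            for mi, marker in enumerate(MARKERS):
                xyz = t.data[:, 3 * mi : 3 * mi + 3]
                chunks.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "trial": t.trial,
                            "frame": np.arange(n),
                            "marker": marker,
                            "x_mm": xyz[:, 0],
                            "y_mm": xyz[:, 1],
                            "z_mm": xyz[:, 2],
                        }
                    )
                )
    pd.concat(chunks, ignore_index=True).to_csv(csv_path, index=False, float_format="%.6g")
    meta = {"sample_rate": sample_rate, "markers": list(MARKERS)}
    if sidecar:
        meta.update(_jsonable(sidecar))
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trajectories(csv_path: str | Path) -> dict[str, list[TrialTrajectory]]:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{csv_path.name}: missing columns {missing}")
    bad_markers = set(df["marker"].unique()) - set(MARKERS)
    if bad_markers:
        raise SchemaError(f"{csv_path.name}: unknown markers {sorted(bad_markers)}")
    sidecar = csv_path.with_suffix(".json")
    sample_rate = 60.0
    if sidecar.exists():
        sample_rate = float(json.loads(sidecar.read_text()).get("sample_rate", 60.0))

    out: dict[str, list[TrialTrajectory]] = {}
    for (sid, trial), g in df.groupby(["subject_id", "trial"], sort=True):
        n = int(g["frame"].max()) + 1
        data = np.full((n, 12), np.nan)
        for mi, marker in enumerate(MARKERS):
            gm = g[g["marker"] == marker].sort_values("frame")
            if len(gm) != n:
                raise SchemaError(f"{sid} trial {trial}: marker {marker} has missing frames")
            data[:, 3 * mi : 3 * mi + 3] = gm[["x_mm", "y_mm", "z_mm"]].to_numpy()
        out.setdefault(str(sid), []).append(TrialTrajectory(str(sid), int(trial), data, sample_rate))
    return out
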