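"""File formats: trial CSVs, study manifest, survey tables, BVH motion files.

Trial files are long-format CSV with one row per frame per segment
(``frame,time_s,segment,qw,qx,qy,qz``), named
``{participant}_{condition}_{task}_{repetition}.csv``; a manifest CSV lists
every trial together with the participant's handedness.  A minimal BVH
reader is provided for hierarchy-bearing recordings (Y-up right-handed
files; rotation channels applied in the order the file declares).
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .kinematics import SEGMENTS, OrientationSeries
from .rom import TrialRecording

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "read_manifest",
    "load_study_trials",
    "read_survey_csv",
    "read_bvh",
]

_TRIAL_COLUMNS = ["frame", "time_s", "segment", "qw", "qx", "qy", "qz"]


def write_trial_csv(trial: TrialRecording, path) -> None:
    """One row per frame per segment: frame,time_s,segment,qw,qx,qy,qz."""
    frames = []
    n = trial.n_frames
    t = np.arange(n) / trial.sample_rate
    for name in sorted(trial.segments):
        series = trial.segments[name]
        df = pd.DataFrame(series.frames, columns=["qw", "qx", "qy", "qz"])
        df.insert(0, "segment", name)
        df.insert(0, "time_s", t)
        df.insert(0, "frame", np.arange(n))
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format="%.9g")


def read_trial_csv(
    path,
    participant_id: str,
    condition: str,
    task: str,
    repetition: int,
    handedness: str,
) -> TrialRecording:
    """Load one trial file; metadata comes from the manifest/filename."""
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[["qw", "qx", "qy", "qz"]].isna().any().any():
        bad = int(df[["qw", "qx", "qy", "qz"]].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric quaternion at row {bad}")
    segments = {}
    sample_rate = None
    for name, group in df.groupby("segment"):
        group = group.sort_values("frame")
        times = group["time_s"].to_numpy()
        if len(times) > 1:
            sample_rate = 1.0 / float(np.median(np.diff(times)))
        segments[str(name)] = OrientationSeries(
            str(name),
            sample_rate or 96.0,
            group[["qw", "qx", "qy", "qz"]].to_numpy(),
        )
    return TrialRecording(
        participant_id=participant_id,
        condition=condition,
        task=task,
        repetition=repetition,
        handedness=handedness,
        segments=segments,
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "condition", "task", "repetition", "handedness", "file"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(required)}")
    return df


def load_study_trials(study_dir):
    """Yield TrialRecordings listed in ``{study_dir}/manifest.csv``."""
    root = Path(study_dir)
    manifest = read_manifest(root / "manifest.csv")
    for row in manifest.itertuples(index=False):
        yield read_trial_csv(
            root / row.file,
            participant_id=str(row.participant),
            condition=row.condition,
            task=row.task,
            repetition=int(row.repetition),
            handedness=row.handedness,
        )


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "pad", "protector", "question", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"survey {path} must have columns {sorted(required)}")
    return df


# ----------------------------------------------------------------- BVH


def read_bvh(
    source: Union[str, Path],
    segment_map: Mapping[str, str],
    default_frame_time: float = 1.0 / 96.0,
) -> dict[str, OrientationSeries]:
    """Parse a BVH file into global per-segment orientation series.

    ``segment_map`` maps BVH joint names to the package's segment
    identifiers; unmapped joints contribute to the kinematic chain but are
    not returned.  Rotation channels are applied intrinsically in the order
    each joint declares; position channels are ignored.
    """
    s = str(source)
    text = s if "\n" in s else Path(s).read_text()
    lines = [ln.strip() for ln in _stdio.StringIO(text) if ln.strip()]
    joints: list[dict] = []
    stack: list[int] = []
    frame_time = default_frame_time
    n_frames = 0
    data_rows: list[list[float]] = []
    in_motion = False
    i = 0
    while i < len(lines):
        ln = lines[i]
        if in_motion:
            if ln.lower().startswith("frames:"):
                n_frames = int(ln.split(":")[1])
            elif ln.lower().startswith("frame time:"):
                frame_time = float(ln.split(":")[1])
            else:
                data_rows.append([float(v) for v in ln.split()])
        elif ln.startswith(("ROOT", "JOINT")):
            name = ln.split(None, 1)[1]
            joints.append(
                {"name": name, "parent": stack[-1] if stack else None, "channels": []}
            )
        elif ln.startswith("End Site"):
            joints.append({"name": None, "parent": stack[-1], "channels": []})
        elif ln == "{":
            stack.append(len(joints) - 1)
        elif ln == "}":
            stack.pop()
        elif ln.startswith("CHANNELS"):
            parts = ln.split()
            joints[stack[-1]]["channels"] = parts[2:]
        elif ln == "MOTION":
            in_motion = True
        i += 1
    if not data_rows:
        raise ValueError("BVH file has no motion data")
    data = np.asarray(data_rows, dtype=float)
    if n_frames and len(data) != n_frames:
        raise ValueError(f"BVH declares {n_frames} frames but has {len(data)}")

    fs = 1.0 / frame_time
    col = 0
    globals_: dict[int, Rotation] = {}
    out: dict[str, OrientationSeries] = {}
    for idx, joint in enumerate(joints):
        chans = joint["channels"]
        rot_order = "".join(c[0].upper() for c in chans if c.lower().endswith("rotation"))
        rot_cols = [col + j for j, c in enumerate(chans) if c.lower().endswith("rotation")]
        col += len(chans)
        local = (
            Rotation.from_euler(rot_order, data[:, rot_cols], degrees=True)
            if rot_order
            else Rotation.identity(len(data))
        )
        parent = joint["parent"]
        globals_[idx] = local if parent is None else globals_[parent] * local
        name = joint["name"]
        if name in segment_map:
            seg = segment_map[name]
            if seg not in SEGMENTS:
                raise ValueError(f"segment_map target {seg!r} is not a known segment")
            q = globals_[idx].as_quat()[:, [3, 0, 1, 2]]
            out[seg] = OrientationSeries(seg, fs, q)
    if not out:
        raise ValueError("no BVH joints matched the segment map")
    return out
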