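"""Range-of-motion extraction from labelled orientation trials.

A study trial is a multi-segment orientation recording for one participant,
pad condition, task and repetition.  Nine static tasks (single-DOF shoulder,
elbow and forearm movements) yield one ROM value each, measured from the
initial anatomical angle (mean over a short baseline window) to the extremum
in the task's movement direction, then averaged over the left and right
sides.  The two dynamic tasks (wrist and slap shots) are segmented by shot
events — shot initiation (SI) and shot release (SR) for the wrist shot, plus
swing top (ST) for the slap shot — and ROM is the max-min excursion of each
joint-plane angle within the event window (SI-SR, SI-ST, ST-SR).

Right-handed shooters are mirrored to left-handed form before dynamic
analysis so all trials share one reference, and repetitions are averaged to a
typical trial per participant x condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kinematics import (
    OrientationSeries,
    angular_speed,
    euler_yxz,
    filter_quaternions,
    joint_quaternion,
)

logger = logging.getLogger("padrom.rom")

__all__ = [
    "CONDITIONS",
    "PAD_CONDITIONS",
    "STATIC_TASKS",
    "DYNAMIC_TASKS",
    "TASKS",
    "STATIC_TASK_PLANES",
    "DYNAMIC_PLANES",
    "ARM_CHAIN_SEGMENTS",
    "FULL_BODY_SEGMENTS",
    "TrialRecording",
    "ShotEvents",
    "RomRecord",
    "ExtractionConfig",
    "ShotDetectionError",
    "joint_angle_series",
    "middle_axis_continuous",
    "static_rom",
    "average_sides",
    "detect_shot_events",
    "phase_rom",
    "mirror_handedness",
    "average_trials",
    "normalize_rom",
    "restriction_percent",
    "extract_trial_records",
    "extract_study_records",
    "condition_matrix",
]

# ---------------------------------------------------------------- vocabulary

CONDITIONS = ("no_pads", "bauer_vapor", "bauer_nsx", "vik_max", "heilong", "ibx")
PAD_CONDITIONS = CONDITIONS[1:]
#: human-readable pad names, in the study's fixed condition order
CONDITION_LABELS = {
    "no_pads": "No S/EPs",
    "bauer_vapor": "Bauer Vapor",
    "bauer_nsx": "Bauer NSX",
    "vik_max": "Vik-Max",
    "heilong": "Heilong",
    "ibx": "IBX",
}

STATIC_TASKS = (
    "sho_flex",
    "sho_ext",
    "sho_add",
    "sho_abd",
    "sho_int_rot",
    "sho_ext_rot",
    "elb_flex",
    "forearm_pro",
    "forearm_sup",
)
DYNAMIC_TASKS = ("wrist_shot", "slap_shot")
TASKS = STATIC_TASKS + DYNAMIC_TASKS

#: joint definitions: name -> (proximal segment stem, distal segment stem)
JOINT_SEGMENTS = {
    "shoulder": ("upper_spine", "upper_arm"),
    "elbow": ("upper_arm", "forearm"),
    "forearm": ("forearm", "hand"),
}

#: static task -> (joint, euler channel, movement direction sign)
#: channels: y = flexion/extension, x = adduction(+)/abduction(-),
#: z = internal(+)/external(-) rotation or pronation(+)/supination(-)
STATIC_TASK_PLANES = {
    "sho_flex": ("shoulder", "y", +1),
    "sho_ext": ("shoulder", "y", -1),
    "sho_add": ("shoulder", "x", +1),
    "sho_abd": ("shoulder", "x", -1),
    "sho_int_rot": ("shoulder", "z", +1),
    "sho_ext_rot": ("shoulder", "z", -1),
    "elb_flex": ("elbow", "y", +1),
    "forearm_pro": ("forearm", "z", +1),
    "forearm_sup": ("forearm", "z", -1),
}

#: joint planes analysed in the shot tasks (per side): name -> (joint, channel)
DYNAMIC_PLANES = {
    "sho_flex_ext": ("shoulder", "y"),
    "sho_add_abd": ("shoulder", "x"),
    "sho_rot": ("shoulder", "z"),
    "elb_flex": ("elbow", "y"),
    "forearm_pro_sup": ("forearm", "z"),
}

#: phases per dynamic task
TASK_PHASES = {"wrist_shot": ("si_sr",), "slap_shot": ("si_st", "st_sr")}

ARM_CHAIN_SEGMENTS = (
    "upper_spine",
    "upper_arm_l",
    "upper_arm_r",
    "forearm_l",
    "forearm_r",
    "hand_l",
    "hand_r",
)
FULL_BODY_SEGMENTS = ("head", "lower_spine") + ARM_CHAIN_SEGMENTS

_CHANNEL_INDEX = {"y": 0, "x": 1, "z": 2}


class ShotDetectionError(RuntimeError):
    """Raised when no shot event structure can be found in a dynamic trial."""


# ---------------------------------------------------------------- containers


@dataclass
class TrialRecording:
    """One task repetition: labelled per-segment orientation series."""

    participant_id: str
    condition: str
    task: str
    repetition: int
    handedness: str
    segments: Mapping[str, OrientationSeries]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right'")
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        required = ARM_CHAIN_SEGMENTS if self.is_static else FULL_BODY_SEGMENTS
        missing = [s for s in required if s not in self.segments]
        if missing:
            raise ValueError(f"trial missing segments: {missing}")
        lengths = {len(s) for s in self.segments.values()}
        rates = {s.sample_rate for s in self.segments.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValueError("all segment series must share length and sample rate")

    @property
    def is_static(self) -> bool:
        return self.task in STATIC_TASKS

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.segments.values())))

    @property
    def sample_rate(self) -> float:
        return next(iter(self.segments.values())).sample_rate


@dataclass(frozen=True)
class ShotEvents:
    """SI / (ST) / SR frame indices segmenting a dynamic trial."""

    si_frame: int
    sr_frame: int
    st_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.st_frame is None:
            if not self.si_frame < self.sr_frame:
                raise ValueError("require si_frame < sr_frame")
        elif not self.si_frame < self.st_frame < self.sr_frame:
            raise ValueError("require si_frame < st_frame < sr_frame")
        if self.si_frame < 0:
            raise ValueError("event frames must be non-negative")


@dataclass(frozen=True)
class RomRecord:
    """One ROM value for participant x condition x task x joint-plane."""

    participant_id: str
    condition: str
    task: str
    phase: str
    joint_plane: str
    rom_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rom_deg <= 360.0:
            raise ValueError(f"rom_deg out of range: {self.rom_deg}")
        if (self.phase == "static") != (self.task in STATIC_TASKS):
            raise ValueError("phase 'static' iff the task is a static task")
        if self.phase not in ("static", "si_sr", "si_st", "st_sr"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the ROM extraction stage."""

    cutoff_hz: float = 6.0
    filter_order: int = 4
    baseline_window_s: float = 0.25
    onset_frac: float = 0.10  # SI threshold, fraction of peak hand speed
    min_peak_speed: float = 30.0  # deg/s; below this no shot is declared
    st_direction: int = +1  # sign of the lead-shoulder backswing extremum


# ------------------------------------------------------------- joint angles


def joint_angle_series(
    trial: TrialRecording,
    joint: str,
    side: str,
    config: ExtractionConfig = ExtractionConfig(),
) -> np.ndarray:
    """Filtered YXZ joint-angle series, shape ``(n, 3)`` as ``(y, x, z)`` deg."""
    prox_stem, dist_stem = JOINT_SEGMENTS[joint]
    prox = trial.segments[f"{prox_stem}_{side}" if prox_stem != "upper_spine" else prox_stem]
    dist = trial.segments[f"{dist_stem}_{side}"]
    qp = filter_quaternions(prox.frames, config.cutoff_hz, config.filter_order, prox.sample_rate)
    qd = filter_quaternions(dist.frames, config.cutoff_hz, config.filter_order, dist.sample_rate)
    qj = joint_quaternion(qp, qd)
    ay, ax, az = euler_yxz(qj)
    return np.stack([ay, ax, az], axis=-1)


def middle_axis_continuous(angles: np.ndarray) -> np.ndarray:
    """Reflection-unwrap of the middle (X) Euler channel.

    A single-axis rotation about X beyond +/-90 deg decomposes in YXZ as a
    reflected X angle with the Y and Z channels jumping to 180 deg.  For
    movements such as shoulder abduction (ROM up to ~170 deg) the anatomical
    angle is recovered by mapping ``x -> sign(x) * 180 - x`` on frames where
    both outer channels have flipped.
    """
    ay, ax, az = angles[..., 0], angles[..., 1], angles[..., 2]
    flipped = (np.abs(ay) > 90.0) & (np.abs(az) > 90.0)
    reflected = np.where(ax >= 0.0, 180.0 - ax, -180.0 - ax)
    return np.where(flipped, reflected, ax)


# ----------------------------------------------------------------- static ROM


def static_rom(
    angles: np.ndarray,
    sample_rate: float,
    direction: int = +1,
    baseline_window_s: float = 0.25,
) -> float:
    """ROM from the initial anatomical angle to the movement-direction extremum.

    The initial anatomical angle is the mean over the first
    ``baseline_window_s`` seconds (24 frames at 96 Hz by default).
    """
    series = np.asarray(angles, dtype=float)
    n_base = max(1, int(round(baseline_window_s * sample_rate)))
    if len(series) < n_base:
        raise ValueError(
            f"series of {len(series)} frames shorter than the "
            f"{n_base}-frame baseline window"
        )
    baseline = float(series[:n_base].mean())
    extremum = float(series.max() if direction > 0 else series.min())
    return abs(extremum - baseline)


def average_sides(left_rom: Optional[float], right_rom: Optional[float]) -> float:
    """Mean of left and right ROM; propagates a single present side."""
    if left_rom is None and right_rom is None:
        raise ValueError("both sides missing")
    if left_rom is None or right_rom is None:
        present = left_rom if right_rom is None else right_rom
        logger.warning("one side missing; propagating the present side (%.2f deg)", present)
        return float(present)
    return 0.5 * (float(left_rom) + float(right_rom))


# ------------------------------------------------------------- shot events


def _hand_speeds(trial: TrialRecording, config: ExtractionConfig) -> dict:
    speeds = {}
    for side in ("l", "r"):
        frames = filter_quaternions(
            trial.segments[f"hand_{side}"].frames,
            config.cutoff_hz,
            config.filter_order,
            trial.sample_rate,
        )
        speeds[side] = angular_speed(frames, trial.sample_rate)
    return speeds


def detect_shot_events(
    trial: TrialRecording,
    config: ExtractionConfig = ExtractionConfig(),
) -> ShotEvents:
    """Locate SI/(ST)/SR from hand angular speed and shoulder backswing.

    SR is the frame of peak hand angular speed (the faster hand leads); SI is
    found by searching backward from SR for the last frame below
    ``onset_frac`` of the peak speed; ST (slap shot only) is the extremal
    backswing of the lead-shoulder flexion/extension channel between SI and
    SR.
    """
    if trial.task not in DYNAMIC_TASKS:
        raise ValueError(f"shot events undefined for task {trial.task!r}")
    speeds = _hand_speeds(trial, config)
    lead = max(speeds, key=lambda s: float(speeds[s].max()))
    speed = speeds[lead]
    sr = int(np.argmax(speed))
    peak = float(speed[sr])
    if peak < config.min_peak_speed:
        raise ShotDetectionError(
            f"no shot detected: peak hand angular speed {peak:.1f} deg/s "
            f"below threshold {config.min_peak_speed} deg/s"
        )
    below = np.flatnonzero(speed[:sr] < config.onset_frac * peak)
    if len(below) == 0:
        raise ShotDetectionError(
            "no shot initiation found: hand speed never drops below "
            f"{config.onset_frac:.0%} of its peak before the release frame"
        )
    si = int(below[-1]) + 1
    if trial.task == "wrist_shot":
        return ShotEvents(si_frame=si, sr_frame=sr)
    # slap shot: swing top on the lead-shoulder flexion/extension channel
    angles = joint_angle_series(trial, "shoulder", lead, config)
    window = config.st_direction * angles[si : sr + 1, 0]
    st = si + int(np.argmax(window))
    if not si < st < sr:
        raise ShotDetectionError(
            f"no swing top found strictly between SI={si} and SR={sr} "
            f"(backswing extremum at frame {st})"
        )
    return ShotEvents(si_frame=si, sr_frame=sr, st_frame=st)


def phase_rom(angles: np.ndarray, events: ShotEvents, phase: str) -> float:
    """max - min of a joint-angle channel within the closed event window."""
    series = np.asarray(angles, dtype=float)
    if phase == "si_sr":
        lo, hi = events.si_frame, events.sr_frame
    elif phase in ("si_st", "st_sr"):
        if events.st_frame is None:
            raise ValueError(f"phase {phase!r} requires a swing-top event (slap shot only)")
        lo, hi = (
            (events.si_frame, events.st_frame)
            if phase == "si_st"
            else (events.st_frame, events.sr_frame)
        )
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if hi >= len(series):
        raise ValueError("event window exceeds series length")
    window = series[lo : hi + 1]
    return float(window.max() - window.min())


# ---------------------------------------------------------------- mirroring


def _mirror_segment_name(name: str) -> str:
    if name.endswith("_l"):
        return name[:-2] + "_r"
    if name.endswith("_r"):
        return name[:-2] + "_l"
    return name


def mirror_handedness(trial: TrialRecording) -> TrialRecording:
    """Mirror a trial across the sagittal plane and swap left/right labels.

    Quaternions map as ``(w, x, y, z) -> (w, -x, y, -z)``: the sagittal (Y)
    Euler channel is preserved while the lateral (X) and axial (Z) channels
    are negated.  The operation is an involution; the handedness label flips.
    """
    mirrored = {}
    for name, series in trial.segments.items():
        frames = series.frames * np.array([1.0, -1.0, 1.0, -1.0])
        new_name = _mirror_segment_name(name)
        mirrored[new_name] = OrientationSeries(new_name, series.sample_rate, frames)
    return replace(
        trial,
        handedness="right" if trial.handedness == "left" else "left",
        segments=mirrored,
    )


# ---------------------------------------------------------------- averaging


def average_trials(records: Sequence[RomRecord]) -> RomRecord:
    """Mean ROM across repetitions of one participant x condition x task x plane."""
    if not records:
        raise ValueError("cannot average an empty set of records")
    keys = {(r.participant_id, r.condition, r.task, r.phase, r.joint_plane) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple cells: {sorted(keys)}")
    mean = float(np.mean([r.rom_deg for r in records]))
    return replace(records[0], rom_deg=mean)


def normalize_rom(pad_rom: float, control_rom: float) -> float:
    """Pad ROM as a fraction of the control (no pads) ROM."""
    if control_rom <= 0:
        raise ValueError("control_rom must be positive")
    return float(pad_rom) / float(control_rom)


def restriction_percent(control_mean: float, pad_mean: float) -> float:
    """Percent ROM limitation relative to control; negative if ROM increased."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return (float(control_mean) - float(pad_mean)) / float(control_mean) * 100.0


# ------------------------------------------------------------ trial records


def extract_trial_records(
    trial: TrialRecording,
    config: ExtractionConfig = ExtractionConfig(),
) -> list[RomRecord]:
    """All ROM records of one trial (side-averaged static, per-phase dynamic)."""
    if trial.is_static:
        joint, channel, direction = STATIC_TASK_PLANES[trial.task]
        ci = _CHANNEL_INDEX[channel]
        sides = {}
        for side in ("l", "r"):
            angles = joint_angle_series(trial, joint, side, config)
            chan = middle_axis_continuous(angles) if channel == "x" else angles[:, ci]
            sides[side] = static_rom(
                chan, trial.sample_rate, direction, config.baseline_window_s
            )
        rom = average_sides(sides["l"], sides["r"])
        return [
            RomRecord(
                trial.participant_id,
                trial.condition,
                trial.task,
                "static",
                trial.task,
                min(rom, 360.0),
            )
        ]

    work = trial
    if trial.handedness == "right":
        logger.info(
            "mirroring right-handed trial %s/%s/%s rep %d to left-handed form",
            trial.participant_id, trial.condition, trial.task, trial.repetition,
        )
        work = mirror_handedness(trial)
    events = detect_shot_events(work, config)
    logger.info(
        "%s/%s/%s rep %d events: SI=%d%s SR=%d",
        work.participant_id, work.condition, work.task, work.repetition,
        events.si_frame,
        f" ST={events.st_frame}" if events.st_frame is not None else "",
        events.sr_frame,
    )
    records = []
    for side in ("l", "r"):
        for plane, (joint, channel) in DYNAMIC_PLANES.items():
            angles = joint_angle_series(work, joint, side, config)
            chan = angles[:, _CHANNEL_INDEX[channel]]
            for phase in TASK_PHASES[work.task]:
                rom = phase_rom(chan, events, phase)
                records.append(
                    RomRecord(
                        work.participant_id,
                        work.condition,
                        work.task,
                        phase,
                        f"{plane}_{side}",
                        min(rom, 360.0),
                    )
                )
    return records


def extract_study_records(
    trials: Iterable[TrialRecording],
    config: ExtractionConfig = ExtractionConfig(),
    average_repetitions: bool = True,
) -> pd.DataFrame:
    """Long-format ROM table over many trials.

    Columns: participant, condition, task, phase, joint_plane, rom_deg
    (plus repetition when ``average_repetitions`` is False).  With averaging
    on, repetitions are collapsed to the typical trial per cell.
    """
    rows = []
    for trial in trials:
        for rec in extract_trial_records(trial, config):
            rows.append(
                {
                    "participant": rec.participant_id,
                    "condition": rec.condition,
                    "task": rec.task,
                    "phase": rec.phase,
                    "joint_plane": rec.joint_plane,
                    "repetition": trial.repetition,
                    "rom_deg": rec.rom_deg,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no trials supplied")
    if average_repetitions:
        df = (
            df.groupby(
                ["participant", "condition", "task", "phase", "joint_plane"],
                as_index=False,
            )["rom_deg"]
            .mean()
        )
    return df


def condition_matrix(
    rom_table: pd.DataFrame, task: str, joint_plane: str, phase: str
) -> pd.DataFrame:
    """Participants x conditions ROM matrix for one task/plane/phase."""
    sel = rom_table[
        (rom_table["task"] == task)
        & (rom_table["joint_plane"] == joint_plane)
        & (rom_table["phase"] == phase)
    ]
    mat = sel.pivot(index="participant", columns="condition", values="rom_deg")
    present = [c for c in CONDITIONS if c in mat.columns]
    return mat[present]
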