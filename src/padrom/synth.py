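"""Synthetic study generator with known ground truth.

Emulates the reference study's design — 9 participants x 11 tasks x 6 pad
conditions x 5 repetitions at 96 Hz, 7 left- and 2 right-handed shooters —
as multi-segment quaternion orientation streams plus a coupled Likert
survey, so every downstream stage (kinematics, ROM extraction, statistics,
comfort) is testable without the deposited raw data.

Construction
------------
Static trials hold an anatomical baseline, rise along a smooth minimum-jerk
profile to a peak on the task's joint-angle channel, and hold the peak.  The
peak is ``control ROM x f`` where the per-condition restriction factors
``f in (0, 1]`` default to the reference study's pad/control ratios, with
multiplicative between-participant and repetition-to-repetition variability.
Dynamic trials embed shot events: the lead (left) wrist carries an angular
speed profile with a crisp onset at SI and its global peak at SR, while each
analysed joint plane traverses a piecewise-linear excursion whose max-min
within each event window equals the configured phase ROM (slap-shot planes
rise by the SI-ST ROM to a kinked maximum at ST, then fall by the ST-SR
ROM).  Right-handed participants are emitted mirrored.

Orientation noise is additive white Gaussian on the relative-joint Euler
channels before quaternion conversion (the quaternion composition itself
goes through ``scipy.spatial.transform.Rotation``, an independent route from
the analysis code).  Ground-truth event frames are obtained by applying the
event definitions to the noise-free composed motion; ground-truth ROM is the
designed excursion.  Survey scores come from a discretised latent-variable
model whose correlation with the injected restriction is set by the comfort
coupling coefficient.

One global seed feeds per-trial counter-based substreams, so any trial is
reproducible in isolation and the full study is byte-for-byte deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import reference
from .kinematics import (
    OrientationSeries,
    angular_speed,
    filter_quaternions,
    lowpass_filter,
)
from .rom import (
    ARM_CHAIN_SEGMENTS,
    CONDITIONS,
    DYNAMIC_PLANES,
    DYNAMIC_TASKS,
    FULL_BODY_SEGMENTS,
    PAD_CONDITIONS,
    STATIC_TASK_PLANES,
    STATIC_TASKS,
    TASK_PHASES,
    TrialRecording,
    mirror_handedness,
)

logger = logging.getLogger("padrom.synth")

__all__ = [
    "GeneratorConfig",
    "TrialGroundTruth",
    "generate_static_trial",
    "generate_shot_trial",
    "generate_survey",
    "generate_study",
    "write_study",
    "protector_restriction",
]

_CHANNEL_COL = {"y": 0, "x": 1, "z": 2}
#: reference ROM (deg) at which the variability SDs are stated; smaller
#: movements scale proportionally (constant coefficient of variation)
_REFERENCE_ROM = 160.0


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce the reference study's conditions: 9 participants
    (7 left-, 2 right-handed), 5 repetitions, 96 Hz, restriction factors
    seeded from the published pad/control ROM ratios, 0.5 deg orientation
    noise, and comfort strongly (0.9) coupled to the injected restriction.
    """

    n_participants: int = 9
    repetitions: int = 5
    sample_rate: float = 96.0
    orientation_noise_sd: float = 0.5  # deg, white, per Euler channel
    participant_rom_sd: float = 8.0  # deg at a 160 deg movement
    trial_rom_sd: float = 3.0  # deg at a 160 deg movement
    comfort_coupling: float = 0.9
    n_left_handed: int = 7
    seed: int = 0
    static_factors: dict = field(default_factory=reference.static_restriction_factors)
    dynamic_factors: dict = field(default_factory=reference.dynamic_restriction_factors)
    onset_frac: float = 0.10  # event rule mirrored by the ROM stage

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.repetitions < 1:
            raise ValueError("need at least one participant and one repetition")
        if not 0 <= self.n_left_handed <= self.n_participants:
            raise ValueError("n_left_handed out of range")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for sd in (self.orientation_noise_sd, self.participant_rom_sd, self.trial_rom_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        if not -1.0 <= self.comfort_coupling <= 1.0:
            raise ValueError("comfort_coupling must lie in [-1, 1]")
        for key, f in {**self.static_factors, **self.dynamic_factors}.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(f"restriction factor out of (0, 1]: {key} -> {f}")
            if key[0] == "no_pads" and f != 1.0:
                raise ValueError("control condition must have f = 1 exactly")

    @property
    def participants(self) -> list[str]:
        return [f"p{i + 1:02d}" for i in range(self.n_participants)]

    def handedness_of(self, participant_idx: int) -> str:
        return "left" if participant_idx < self.n_left_handed else "right"


@dataclass(frozen=True)
class TrialGroundTruth:
    """Designed (pre-noise) truth of one trial, never read by the pipeline."""

    participant_id: str
    condition: str
    task: str
    repetition: int
    rom_deg: dict  # static: {task: mean, task_l/_r: side}; dynamic: {"phase:plane_side": deg}
    si_frame: Optional[int] = None
    st_frame: Optional[int] = None
    sr_frame: Optional[int] = None
    # nominal template frames the profiles were built around; the ROM design
    # (max - min per phase window) is exact on these, while si/st/sr above are
    # the smoothed-motion events a detector is judged against
    design_si_frame: Optional[int] = None
    design_st_frame: Optional[int] = None
    design_sr_frame: Optional[int] = None


# ------------------------------------------------------------ RNG plumbing


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def _participant_base(config, p_idx: int, task_idx: int, control_rom: float) -> float:
    """Per-participant unrestricted ROM for one task/plane (CV-scaled)."""
    rng = _rng(config, 2, p_idx, task_idx)
    cv = config.participant_rom_sd / _REFERENCE_ROM
    return float(control_rom * max(1.0 + rng.normal(0.0, cv), 0.2))


# ------------------------------------------------------------ profiles


def _minjerk(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _ramp(n: int, start: int, end: int, a0: float, a1: float) -> np.ndarray:
    """Piecewise-linear channel: a0 before start, linear to a1 at end, hold."""
    out = np.full(n, a0, dtype=float)
    span = max(end - start, 1)
    seg = a0 + (a1 - a0) * np.arange(span + 1) / span
    out[start : end + 1] = seg[: max(min(end + 1, n) - start, 0)]
    out[end + 1 :] = a1
    return out


def _euler_to_rot(angles_yxz: np.ndarray) -> Rotation:
    return Rotation.from_euler("YXZ", angles_yxz, degrees=True)


def _to_wxyz(rot: Rotation) -> np.ndarray:
    q = rot.as_quat()  # scalar-last
    return q[:, [3, 0, 1, 2]]


def _compose_segments(
    config,
    n: int,
    rel_eulers: dict,
    noise_rng: Optional[np.random.Generator],
    segments: tuple,
) -> dict:
    """Compose relative-joint Euler channels into global segment orientations.

    ``rel_eulers`` maps ``spine | sho_l/r | elb_l/r | wrist_l/r`` to (n, 3)
    YXZ channel arrays.  With a noise generator, white Gaussian noise is
    added to every channel before conversion.
    """
    def channels(name: str) -> np.ndarray:
        arr = rel_eulers.get(name)
        arr = np.zeros((n, 3)) if arr is None else arr.copy()
        if noise_rng is not None and config.orientation_noise_sd > 0:
            arr += noise_rng.normal(0.0, config.orientation_noise_sd, size=arr.shape)
        return arr

    spine = _euler_to_rot(channels("spine"))
    out = {"upper_spine": spine}
    for side in ("l", "r"):
        sho = spine * _euler_to_rot(channels(f"sho_{side}"))
        elb = sho * _euler_to_rot(channels(f"elb_{side}"))
        hand = elb * _euler_to_rot(channels(f"wrist_{side}"))
        out[f"upper_arm_{side}"] = sho
        out[f"forearm_{side}"] = elb
        out[f"hand_{side}"] = hand
    for extra in ("head", "lower_spine"):
        if extra in segments:
            out[extra] = _euler_to_rot(channels(extra))
    return {
        name: OrientationSeries(name, config.sample_rate, _to_wxyz(out[name]))
        for name in segments
    }


# ------------------------------------------------------------ static trials


def generate_static_trial(
    config: GeneratorConfig,
    participant_idx: int,
    condition: str,
    task: str,
    rep: int,
) -> tuple[TrialRecording, TrialGroundTruth]:
    """One static-task repetition: baseline hold, minimum-jerk rise, peak hold."""
    if task not in STATIC_TASKS:
        raise ValueError(f"{task!r} is not a static task")
    fs = config.sample_rate
    task_idx = STATIC_TASKS.index(task)
    cond_idx = CONDITIONS.index(condition)
    rng = _rng(config, 1, participant_idx, cond_idx, task_idx, rep)

    control = float(reference.static_table().loc[task, "no_pads_mean"])
    base = _participant_base(config, participant_idx, task_idx, control)
    f = config.static_factors[(condition, task)]
    cv_t = config.trial_rom_sd / _REFERENCE_ROM

    n_hold = int(round(0.5 * fs))
    n_rise = int(round(1.2 * fs))
    n = n_hold + n_rise + int(round(0.5 * fs))
    shape = np.concatenate(
        [
            np.zeros(n_hold),
            _minjerk(np.arange(n_rise) / (n_rise - 1)),
            np.ones(n - n_hold - n_rise),
        ]
    )

    joint, channel, direction = STATIC_TASK_PLANES[task]
    joint_key = {"shoulder": "sho", "elbow": "elb", "forearm": "wrist"}[joint]
    rel = {}
    peaks = {}
    for side in ("l", "r"):
        peak = float(np.clip(base * f * (1.0 + rng.normal(0.0, cv_t)), 1.0, 177.0))
        peaks[side] = peak
        arr = np.zeros((n, 3))
        arr[:, _CHANNEL_COL[channel]] = direction * peak * shape
        rel[f"{joint_key}_{side}"] = arr

    noise_rng = _rng(config, 4, participant_idx, cond_idx, task_idx, rep)
    segments = _compose_segments(config, n, rel, noise_rng, ARM_CHAIN_SEGMENTS)
    trial = TrialRecording(
        participant_id=config.participants[participant_idx],
        condition=condition,
        task=task,
        repetition=rep,
        handedness=config.handedness_of(participant_idx),
        segments=segments,
    )
    truth = TrialGroundTruth(
        trial.participant_id,
        condition,
        task,
        rep,
        rom_deg={
            f"{task}_l": peaks["l"],
            f"{task}_r": peaks["r"],
            task: 0.5 * (peaks["l"] + peaks["r"]),
        },
    )
    return trial, truth


# ------------------------------------------------------------ shot trials

# event timing (seconds) of the designed shot templates
_WRIST_T = {"si": 0.55, "sr": 1.25, "total": 2.0, "follow": 1.0 / 3.0}
_SLAP_T = {"si": 0.5, "st": 1.3, "sr": 1.8, "total": 2.8, "follow": 0.3}
_WRIST_PEAK_SPEED = 500.0  # deg/s, lead-wrist driver
_SLAP_PEAK_SPEED = 700.0


def _wrist_driver_speed(n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    si, sr = _WRIST_T["si"], _WRIST_T["sr"]
    s = np.zeros(n)
    ramp_end = si + 0.1
    m = (t >= si) & (t < ramp_end)
    s[m] = 0.3 * (t[m] - si) / 0.1
    m = (t >= ramp_end) & (t <= sr)
    v = (t[m] - ramp_end) / (sr - ramp_end)
    s[m] = 0.3 + 0.7 * v**3
    m = (t > sr) & (t <= sr + _WRIST_T["follow"])
    s[m] = np.clip(1.0 - (t[m] - sr) / _WRIST_T["follow"], 0.0, 1.0)
    return _WRIST_PEAK_SPEED * s


def _slap_driver_speed(n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    si, st, sr = _SLAP_T["si"], _SLAP_T["st"], _SLAP_T["sr"]
    s = np.zeros(n)
    # backswing bump: fast onset ramp, sine-squared body, floor 0.14 of peak
    ramp_end = si + 0.1
    m = (t >= si) & (t < ramp_end)
    s[m] = 0.14 * (t[m] - si) / 0.1
    m = (t >= ramp_end) & (t < st)
    u = (t[m] - ramp_end) / (st - ramp_end)
    s[m] = 0.14 + 0.21 * np.sin(np.pi * u) ** 2
    # downswing: rise from the floor to the release peak
    m = (t >= st) & (t <= sr)
    u = (t[m] - st) / (sr - st)
    s[m] = 0.14 + 0.86 * u**2
    m = (t > sr) & (t <= sr + _SLAP_T["follow"])
    s[m] = np.clip(1.0 - (t[m] - sr) / _SLAP_T["follow"], 0.0, 1.0)
    return _SLAP_PEAK_SPEED * s


def _clean_events(
    config, segments: dict, sho_y: np.ndarray, task: str
) -> tuple[int, Optional[int], int]:
    """Event frames of the noise-free motion under the standard smoothing.

    The event definitions include the pipeline's 6 Hz zero-phase low-pass
    (events are features of the smoothed movement); applying them to the
    noise-free composed streams yields the ground truth that a noisy
    extraction is judged against.
    """
    speeds = {
        side: angular_speed(
            filter_quaternions(
                segments[f"hand_{side}"].frames, sample_rate=config.sample_rate
            ),
            config.sample_rate,
        )
        for side in ("l", "r")
    }
    sho_y = lowpass_filter(sho_y, sample_rate=config.sample_rate)
    lead = max(speeds, key=lambda s: float(speeds[s].max()))
    speed = speeds[lead]
    sr = int(np.argmax(speed))
    below = np.flatnonzero(speed[:sr] < config.onset_frac * float(speed[sr]))
    si = int(below[-1]) + 1 if len(below) else 0
    st = None
    if task == "slap_shot":
        st = si + int(np.argmax(sho_y[si : sr + 1]))
    return si, st, sr


def generate_shot_trial(
    config: GeneratorConfig,
    participant_idx: int,
    condition: str,
    shot_type: str,
    rep: int,
) -> tuple[TrialRecording, TrialGroundTruth]:
    """One dynamic repetition with embedded SI/(ST)/SR events.

    Built left-handed; right-handed participants are returned mirrored.
    Each analysed joint plane's max-min excursion inside its event window
    equals the configured phase ROM exactly in the noise-free design.
    """
    if shot_type not in DYNAMIC_TASKS:
        raise ValueError(f"{shot_type!r} is not a dynamic task")
    fs = config.sample_rate
    timing = _WRIST_T if shot_type == "wrist_shot" else _SLAP_T
    n = int(round(timing["total"] * fs))
    task_idx = len(STATIC_TASKS) + DYNAMIC_TASKS.index(shot_type)
    cond_idx = CONDITIONS.index(condition)
    rng = _rng(config, 1, participant_idx, cond_idx, task_idx, rep)
    cv_t = config.trial_rom_sd / _REFERENCE_ROM

    si_f = int(round(timing["si"] * fs))
    sr_f = int(round(timing["sr"] * fs))
    st_f = int(round(timing["st"] * fs)) if shot_type == "slap_shot" else None

    if shot_type == "wrist_shot":
        ref_table = reference.wrist_table()
        amp_of = lambda plane_side: float(ref_table.loc[plane_side, "no_pads_mean"])
    else:
        slap = reference.slap_table()
        amp_of = None  # looked up per phase below

    rel = {f"{j}_{s}": np.zeros((n, 3)) for j in ("sho", "elb", "wrist") for s in ("l", "r")}
    truth_rom: dict[str, float] = {}
    plane_order = list(DYNAMIC_PLANES.items())
    for side_idx, side in enumerate(("l", "r")):
        for plane_idx, (plane, (joint, channel)) in enumerate(plane_order):
            plane_side = f"{plane}_{side}"
            joint_key = {"shoulder": "sho", "elbow": "elb", "forearm": "wrist"}[joint]
            col = _CHANNEL_COL[channel]
            # per-participant mobility for this plane (stable across conditions)
            sub_idx = 100 * task_idx + 10 * side_idx + plane_idx
            if shot_type == "wrist_shot":
                base = _participant_base(
                    config, participant_idx, sub_idx, amp_of(plane_side)
                )
                f = config.dynamic_factors[(condition, "si_sr", plane_side)]
                amp = base * f * max(1.0 + rng.normal(0.0, cv_t), 0.05)
                truth_rom[f"si_sr:{plane_side}"] = amp
                rel[f"{joint_key}_{side}"][:, col] = _ramp(
                    n, si_f + 5, sr_f - 5, 0.0, amp
                )
            else:
                base1 = _participant_base(
                    config,
                    participant_idx,
                    sub_idx,
                    float(slap.loc[("si_st", plane_side), "no_pads_mean"]),
                )
                base2 = _participant_base(
                    config,
                    participant_idx,
                    sub_idx + 1000,
                    float(slap.loc[("st_sr", plane_side), "no_pads_mean"]),
                )
                f1 = config.dynamic_factors[(condition, "si_st", plane_side)]
                f2 = config.dynamic_factors[(condition, "st_sr", plane_side)]
                a1 = base1 * f1 * max(1.0 + rng.normal(0.0, cv_t), 0.05)
                a2 = base2 * f2 * max(1.0 + rng.normal(0.0, cv_t), 0.05)
                truth_rom[f"si_st:{plane_side}"] = a1
                truth_rom[f"st_sr:{plane_side}"] = a2
                up = _ramp(n, si_f + 3, st_f, 0.0, a1)
                down = _ramp(n, st_f, sr_f - 3, 0.0, -a2)
                rel[f"{joint_key}_{side}"][:, col] = up + down

    # lead-wrist angular-speed driver (wrist flexion, not an analysed plane)
    driver = (
        _wrist_driver_speed(n, fs) if shot_type == "wrist_shot" else _slap_driver_speed(n, fs)
    )
    rel["wrist_l"][:, 0] += np.cumsum(driver) / fs

    clean = _compose_segments(config, n, rel, None, FULL_BODY_SEGMENTS)
    sho_y_lead = rel["sho_l"][:, 0]
    si, st, sr = _clean_events(config, clean, sho_y_lead, shot_type)

    noise_rng = _rng(config, 4, participant_idx, cond_idx, task_idx, rep)
    segments = _compose_segments(config, n, rel, noise_rng, FULL_BODY_SEGMENTS)
    trial = TrialRecording(
        participant_id=config.participants[participant_idx],
        condition=condition,
        task=shot_type,
        repetition=rep,
        handedness="left",
        segments=segments,
    )
    if config.handedness_of(participant_idx) == "right":
        trial = mirror_handedness(trial)  # emitted right-handed
    truth = TrialGroundTruth(
        trial.participant_id,
        condition,
        shot_type,
        rep,
        rom_deg=truth_rom,
        si_frame=si,
        st_frame=st,
        sr_frame=sr,
        design_si_frame=si_f,
        design_st_frame=st_f,
        design_sr_frame=sr_f,
    )
    return trial, truth


# ------------------------------------------------------------ survey


def protector_restriction(config: GeneratorConfig) -> pd.DataFrame:
    """Mean injected restriction (1 - f) per pad x protector."""
    sho_static = [t for t in STATIC_TASKS if t.startswith("sho_")]
    elb_static = [t for t in STATIC_TASKS if not t.startswith("sho_")]
    rows = {}
    for pad in PAD_CONDITIONS:
        sho = [config.static_factors[(pad, t)] for t in sho_static]
        elb = [config.static_factors[(pad, t)] for t in elb_static]
        for (cond, phase, plane), f in config.dynamic_factors.items():
            if cond != pad:
                continue
            (sho if plane.startswith("sho_") else elb).append(f)
        rows[pad] = {
            "shoulder": 1.0 - float(np.mean(sho)),
            "elbow": 1.0 - float(np.mean(elb)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(list(PAD_CONDITIONS))


def generate_survey(config: GeneratorConfig) -> pd.DataFrame:
    """Likert responses coupled to the injected restriction.

    Q1 (comfort) and Q4 (would wear) decrease with restriction, Q3
    (perceived restriction) increases, Q2 (safety) is independent; scores
    come from a latent normal variable with correlation
    ``comfort_coupling`` to the standardised restriction, discretised and
    clipped to 1..5.
    """
    restr = protector_restriction(config)
    c = config.comfort_coupling
    resid = float(np.sqrt(max(1.0 - c * c, 0.0)))
    rows = []
    for prot in PROTECTOR_ORDER:
        r = restr[prot].to_numpy()
        spread = float(r.std())
        z = (r - r.mean()) / spread if spread > 0 else np.zeros_like(r)
        for p_idx, pid in enumerate(config.participants):
            rng = _rng(config, 5, p_idx, PROTECTOR_ORDER.index(prot))
            for q_idx, question in enumerate(_SURVEY_QUESTIONS):
                eps = rng.normal(0.0, 1.0, size=len(z))
                if question == "q2_safe":
                    latent = eps
                elif question == "q3_restricts":
                    latent = c * z + resid * eps
                else:  # q1_comfort, q4_would_wear
                    latent = -c * z + resid * eps
                scores = np.clip(np.rint(3.0 + 1.2 * latent), 1, 5).astype(int)
                for pad, score in zip(PAD_CONDITIONS, scores):
                    rows.append(
                        {
                            "participant": pid,
                            "pad": pad,
                            "protector": prot,
                            "question": question,
                            "score": int(score),
                        }
                    )
    return pd.DataFrame(rows)


PROTECTOR_ORDER = ("shoulder", "elbow")
_SURVEY_QUESTIONS = ("q1_comfort", "q2_safe", "q3_restricts", "q4_would_wear")


# ------------------------------------------------------------ full study


def generate_study(
    config: GeneratorConfig,
    tasks: Optional[tuple] = None,
    conditions: Optional[tuple] = None,
) -> Iterator[tuple[TrialRecording, TrialGroundTruth]]:
    """Yield every trial of the design (optionally restricted to subsets)."""
    tasks = tuple(tasks) if tasks is not None else STATIC_TASKS + DYNAMIC_TASKS
    conditions = tuple(conditions) if conditions is not None else CONDITIONS
    for p_idx in range(config.n_participants):
        for condition in conditions:
            for task in tasks:
                for rep in range(1, config.repetitions + 1):
                    if task in STATIC_TASKS:
                        yield generate_static_trial(config, p_idx, condition, task, rep)
                    else:
                        yield generate_shot_trial(config, p_idx, condition, task, rep)


def write_study(config: GeneratorConfig, out_dir, overwrite: bool = False) -> Path:
    """Write the full study layout: manifest, trial CSVs, survey, ground truth."""
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite=True)")
    trial_dir = out / "trials"
    trial_dir.mkdir(exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for trial, truth in generate_study(config):
        fname = f"{trial.participant_id}_{trial.condition}_{trial.task}_{trial.repetition}.csv"
        pio.write_trial_csv(trial, trial_dir / fname)
        manifest_rows.append(
            {
                "participant": trial.participant_id,
                "condition": trial.condition,
                "task": trial.task,
                "repetition": trial.repetition,
                "handedness": trial.handedness,
                "file": f"trials/{fname}",
            }
        )
        for key, rom in truth.rom_deg.items():
            truth_rows.append(
                {
                    "participant": truth.participant_id,
                    "condition": truth.condition,
                    "task": truth.task,
                    "repetition": truth.repetition,
                    "measure": key,
                    "true_rom_deg": rom,
                    "si_frame": truth.si_frame,
                    "st_frame": truth.st_frame,
                    "sr_frame": truth.sr_frame,
                }
            )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    generate_survey(config).to_csv(out / "survey.csv", index=False)
    logger.info("wrote %d trials to %s", len(manifest_rows), out)
    return out
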