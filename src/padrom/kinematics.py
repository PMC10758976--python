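"""Quaternion joint-angle kinematics for IMU-derived segment orientations.

Segment orientations arrive as unit quaternions (scalar-first ``(w, x, y, z)``,
Hamilton convention).  The relative rotation of a distal segment with respect
to its proximal neighbour is

    q_joint = q_proximal^{-1} (x) q_distal

which is decomposed into clinical angles with an intrinsic Y-X'-Z'' Euler
sequence: the Y channel carries flexion/extension (rotation about the
mediolateral axis), X abduction/adduction, and Z axial rotation
(internal/external rotation at the shoulder, pronation/supination at the
forearm).  All public functions accept either a single quaternion of shape
``(4,)`` or a time series of shape ``(n, 4)`` and are fully vectorised.

Noise suppression follows the standard biomechanics recipe: a zero-phase
(forward-backward) low-pass Butterworth filter applied to the four quaternion
components independently, followed by renormalisation.  Antipodal sign flips
(q and -q encode the same rotation) are removed before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "SEGMENTS",
    "Quaternion",
    "EulerYXZ",
    "OrientationSeries",
    "quat_normalize",
    "quat_canonical",
    "quat_multiply",
    "quat_inverse",
    "joint_quaternion",
    "quat_from_axis_angle",
    "euler_yxz",
    "euler_yxz_to_quat",
    "quat_rotation_angle",
    "sign_align",
    "lowpass_filter",
    "filter_quaternions",
    "angular_speed",
]

#: Upper-body segment identifiers tracked by the motion-capture montage.
SEGMENTS = (
    "head",
    "upper_spine",
    "lower_spine",
    "upper_arm_l",
    "upper_arm_r",
    "forearm_l",
    "forearm_r",
    "hand_l",
    "hand_r",
)

_UNIT_TOL = 1e-9
#: proximity to the +/-90 deg gimbal singularity of the middle (X) axis, degrees
GIMBAL_TOL_DEG = 0.01


def _as_quat_array(q) -> np.ndarray:
    arr = np.asarray(q, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError(f"quaternions must have 4 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("quaternion components must be finite")
    return arr


def quat_normalize(q) -> np.ndarray:
    """Scale to unit norm.  Raises on (near-)zero quaternions."""
    arr = _as_quat_array(q)
    norm = np.linalg.norm(arr, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return arr / norm


def quat_canonical(q) -> np.ndarray:
    """Canonical sign representative: the hemisphere with w >= 0."""
    arr = quat_normalize(q)
    sign = np.where(arr[..., :1] < 0.0, -1.0, 1.0)
    return arr * sign


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product a (x) b, renormalised.  Non-commutative."""
    qa = quat_normalize(a)
    qb = quat_normalize(b)
    w1, x1, y1, z1 = (qa[..., i] for i in range(4))
    w2, x2, y2, z2 = (qb[..., i] for i in range(4))
    out = np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )
    return quat_normalize(out)


def quat_inverse(q) -> np.ndarray:
    """Inverse of a unit quaternion (its conjugate)."""
    arr = quat_normalize(q)
    return arr * np.array([1.0, -1.0, -1.0, -1.0])


def joint_quaternion(q_proximal, q_distal) -> np.ndarray:
    """Relative rotation carrying the proximal frame onto the distal frame.

    Both inputs must be expressed in the same global reference frame; a
    mismatch cannot be detected and is the caller's contract.
    """
    return quat_multiply(quat_inverse(q_proximal), q_distal)


def quat_from_axis_angle(axis: Sequence[float], angle_deg) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_deg`` about ``axis``."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    half = np.deg2rad(np.asarray(angle_deg, dtype=float)) / 2.0
    w = np.cos(half)
    xyz = np.sin(half)[..., None] * ax
    return np.concatenate([w[..., None], xyz], axis=-1)


def euler_yxz(q, return_gimbal: bool = False):
    """Intrinsic Y-X'-Z'' Euler angles of a unit quaternion, in degrees.

    Returns ``(angle_y, angle_x, angle_z)`` arrays (scalars for a single
    quaternion) with ``angle_y, angle_z in (-180, 180]`` and
    ``angle_x in [-90, 90]``.  Within :data:`GIMBAL_TOL_DEG` of the
    ``|angle_x| = 90`` singularity the Y-Z coupling is folded entirely into
    ``angle_y`` and ``angle_z`` is set to zero; with ``return_gimbal=True`` a
    boolean flag marking those samples is returned as a fourth element.
    """
    arr = quat_normalize(q)
    w, x, y, z = (arr[..., i] for i in range(4))
    # rotation-matrix elements of R = Ry(ay) @ Rx(ax) @ Rz(az)
    r12 = 2.0 * (y * z - w * x)
    r02 = 2.0 * (x * z + w * y)
    r22 = 1.0 - 2.0 * (x * x + y * y)
    r10 = 2.0 * (x * y + w * z)
    r11 = 1.0 - 2.0 * (x * x + z * z)
    r20 = 2.0 * (x * z - w * y)
    r00 = 1.0 - 2.0 * (y * y + z * z)

    ax = np.degrees(np.arcsin(np.clip(-r12, -1.0, 1.0)))
    gimbal = np.abs(np.abs(ax) - 90.0) < GIMBAL_TOL_DEG
    ay = np.degrees(np.arctan2(r02, r22))
    az = np.degrees(np.arctan2(r10, r11))
    if np.any(gimbal):
        # fold the full Y-Z coupling into angle_y, tie-break angle_z = 0
        ay_g = np.degrees(np.arctan2(-r20, r00))
        ay = np.where(gimbal, ay_g, ay)
        az = np.where(gimbal, 0.0, az)
    if arr.ndim == 1:
        ay, ax, az, gimbal = float(ay), float(ax), float(az), bool(gimbal)
    if return_gimbal:
        return ay, ax, az, gimbal
    return ay, ax, az


def euler_yxz_to_quat(angle_y, angle_x, angle_z) -> np.ndarray:
    """Compose intrinsic YXZ angles (degrees) back into a unit quaternion."""
    qy = quat_from_axis_angle([0.0, 1.0, 0.0], angle_y)
    qx = quat_from_axis_angle([1.0, 0.0, 0.0], angle_x)
    qz = quat_from_axis_angle([0.0, 0.0, 1.0], angle_z)
    return quat_multiply(quat_multiply(qy, qx), qz)


def quat_rotation_angle(q) -> np.ndarray:
    """Total rotation angle in degrees, in [0, 180]."""
    arr = quat_normalize(q)
    w = np.clip(np.abs(arr[..., 0]), -1.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def sign_align(frames: np.ndarray) -> np.ndarray:
    """Enforce antipodal continuity: consecutive frames with dot >= 0."""
    arr = _as_quat_array(frames).copy()
    if arr.ndim != 2:
        raise ValueError("sign_align expects a (n, 4) series")
    dots = np.einsum("ij,ij->i", arr[:-1], arr[1:])
    flips = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    arr[1:] *= flips[:, None]
    return arr


def lowpass_filter(
    series: np.ndarray,
    cutoff: float = 6.0,
    order: int = 4,
    sample_rate: float = 96.0,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    A forward-backward pass of an ``order``-th Butterworth design (effective
    attenuation order ``2 * order``, zero phase distortion).  DC gain is
    exactly 1, so a constant series is returned unchanged.
    """
    arr = np.asarray(series, dtype=float)
    n = arr.shape[0]
    if cutoff <= 0 or cutoff >= sample_rate / 2.0:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={sample_rate / 2.0} Hz), got {cutoff}"
        )
    if n < 3 * order:
        raise ValueError(f"series of length {n} too short for order-{order} filtering")
    b, a = signal.butter(order, cutoff, btype="low", fs=sample_rate)
    padlen = min(3 * (max(len(a), len(b)) - 1), n - 1)
    return signal.filtfilt(b, a, arr, axis=0, padlen=padlen)


def filter_quaternions(
    frames: np.ndarray,
    cutoff: float = 6.0,
    order: int = 4,
    sample_rate: float = 96.0,
) -> np.ndarray:
    """Sign-align, low-pass the four components, renormalise."""
    aligned = sign_align(quat_normalize(frames))
    return quat_normalize(lowpass_filter(aligned, cutoff, order, sample_rate))


def angular_speed(frames: np.ndarray, sample_rate: float) -> np.ndarray:
    """Frame-wise angular speed in deg/s (central estimate, same length)."""
    arr = quat_normalize(frames)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frames for angular speed")
    step = quat_rotation_angle(quat_multiply(quat_inverse(arr[:-1]), arr[1:]))
    speed = step * sample_rate
    # same-length series: average of adjacent increments in the interior
    out = np.empty(arr.shape[0])
    out[0] = speed[0]
    out[-1] = speed[-1]
    out[1:-1] = 0.5 * (speed[:-1] + speed[1:])
    return out


@dataclass(frozen=True)
class Quaternion:
    """Scalar-first unit quaternion (Hamilton convention), canonical w >= 0."""

    w: float
    x: float
    y: float
    z: float

    @classmethod
    def from_array(cls, q) -> "Quaternion":
        arr = quat_canonical(q)
        return cls(*(float(c) for c in arr))

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def __mul__(self, other: "Quaternion") -> "Quaternion":
        return Quaternion.from_array(quat_multiply(self.as_array(), other.as_array()))

    def inverse(self) -> "Quaternion":
        return Quaternion.from_array(quat_inverse(self.as_array()))

    def euler_yxz(self) -> "EulerYXZ":
        ay, ax, az = euler_yxz(self.as_array())
        return EulerYXZ(ay, ax, az)


@dataclass(frozen=True)
class EulerYXZ:
    """Intrinsic YXZ angles, degrees.

    Channel-to-plane mapping (fixed by convention, configurable in the ROM
    layer): Y flexion/extension, X abduction/adduction, Z axial rotation.
    """

    angle_y: float
    angle_x: float
    angle_z: float


@dataclass
class OrientationSeries:
    """Orientation time series of one body segment."""

    segment_id: str
    sample_rate: float = 96.0
    frames: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    def __post_init__(self) -> None:
        if self.segment_id not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment_id!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.frames = quat_normalize(self.frames) if len(self.frames) else np.empty((0, 4))

    def __len__(self) -> int:
        return len(self.frames)

    def filtered(self, cutoff: float = 6.0, order: int = 4) -> "OrientationSeries":
        if len(self) < 2:
            raise ValueError("need at least 2 frames to filter")
        return OrientationSeries(
            self.segment_id,
            self.sample_rate,
            filter_quaternions(self.frames, cutoff, order, self.sample_rate),
        )
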