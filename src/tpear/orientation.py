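"""Attitude estimation for ear-worn IMUs via an error-state Kalman filter.

The filter propagates a unit quaternion (body -> NED navigation frame) with
the gyroscope and corrects roll/pitch with the accelerometer's gravity
observation.  Yaw is observable only through gyro integration (no
magnetometer), so heading is relative: yaw starts at 0 at the beginning of
each trial, which is exactly what the turn-segmentation thresholds need.

The analysis frame (SI up, ML left, AP forward) maps to the NED body frame as
x = AP (forward), y = -ML (right), z = -SI (down); the mapping lives entirely
inside :func:`estimate_orientation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .imu_io import ImuTrial

GRAVITY = 9.80665  # m/s^2


@dataclass(frozen=True)
class EskfParams:
    """Tuning of the attitude filter.

    gyro_noise_dps
        Gyroscope white-noise density driving the attitude random walk, deg/s.
    accel_noise
        Std of the normalized gravity-direction observation (unitless, applied
        to the unit-vector innovation).
    init_tilt_std_deg
        1-sigma uncertainty of the accelerometer-based initial roll/pitch.
    accel_gate_ms2
        Reject gravity updates when | ||a|| - g | exceeds this (free-fall or
        impact samples); the filter then coasts on the gyro.
    """

    gyro_noise_dps: float = 0.5
    accel_noise: float = 0.05
    init_tilt_std_deg: float = 5.0
    accel_gate_ms2: float = 3.0


@dataclass
class OrientationTrack:
    """Per-sample attitude: quaternions (w, x, y, z), Euler angles in degrees.

    ``euler`` columns are roll, pitch, yaw under the intrinsic Z-Y-X
    (yaw-pitch-roll) aerospace convention, yaw about the down axis.
    """

    quat: np.ndarray       # (N, 4) unit, scalar-first
    euler: np.ndarray      # (N, 3) roll, pitch, yaw in degrees
    fs: float

    @property
    def yaw(self) -> np.ndarray:
        return self.euler[:, 2]


def _quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
    axis = v / angle
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def _gravity_body(q: np.ndarray) -> np.ndarray:
    """Unit specific-force direction Rot(q)^T [0,0,-1] predicted in body axes."""
    w, x, y, z = q
    # third row of the body->nav rotation matrix
    row = np.array([2.0 * (x * z - w * y),
                    2.0 * (y * z + w * x),
                    1.0 - 2.0 * (x * x + y * y)])
    return -row


def estimate_orientation(trial: ImuTrial,
                         params: Optional[EskfParams] = None) -> OrientationTrack:
    """Run the error-state filter over a gap-filled trial.

    Returns unit quaternions and Euler angles for every sample; yaw is 0 at
    the first sample by construction (roll/pitch initialized from the first
    accelerometer reading).
    """
    params = params or EskfParams()
    dt = 1.0 / trial.fs
    # analysis frame -> NED body frame
    acc = np.column_stack([trial.ap, -trial.ml, -trial.si])
    gyr = np.deg2rad(np.column_stack([trial.gyro[:, 2],
                                      -trial.gyro[:, 1],
                                      -trial.gyro[:, 0]]))
    n = len(acc)
    quats = np.empty((n, 4))

    a0 = acc[0]
    norm0 = np.linalg.norm(a0)
    if norm0 > 1e-9:
        a0n = a0 / norm0
        pitch = np.arcsin(np.clip(a0n[0], -1.0, 1.0))
        roll = np.arctan2(-a0n[1], -a0n[2])
    else:
        pitch = roll = 0.0
    q = _rot_to_quat(Rotation.from_euler("ZYX", [0.0, pitch, roll]))

    sig_g = np.deg2rad(params.gyro_noise_dps)
    Q = (sig_g ** 2 * dt) * np.eye(3)
    R_meas = (params.accel_noise ** 2) * np.eye(3)
    P = (np.deg2rad(params.init_tilt_std_deg) ** 2) * np.diag([1.0, 1.0, 1e-6])
    I3 = np.eye(3)

    quats[0] = q
    for i in range(1, n):
        w = gyr[i]
        q = _quat_mul(q, _quat_from_rotvec(w * dt))
        q /= np.linalg.norm(q)
        F = I3 - _skew(w * dt)
        P = F @ P @ F.T + Q
        a = acc[i]
        norm = np.linalg.norm(a)
        if abs(norm - GRAVITY) < params.accel_gate_ms2 and norm > 1e-9:
            gb = _gravity_body(q)
            H = _skew(gb)
            S = H @ P @ H.T + R_meas
            K = P @ H.T @ np.linalg.inv(S)
            delta = K @ (a / norm - gb)
            q = _quat_mul(q, _quat_from_rotvec(delta))
            q /= np.linalg.norm(q)
            P = (I3 - K @ H) @ P
        quats[i] = q

    rot = Rotation.from_quat(np.column_stack([quats[:, 1], quats[:, 2],
                                              quats[:, 3], quats[:, 0]]))
    ypr = rot.as_euler("ZYX", degrees=True)  # yaw, pitch, roll
    euler = ypr[:, ::-1].copy()
    return OrientationTrack(quat=quats, euler=euler, fs=trial.fs)


def _rot_to_quat(rot: Rotation) -> np.ndarray:
    x, y, z, w = rot.as_quat()
    return np.array([w, x, y, z])


def yaw_rate(track: Union[OrientationTrack, np.ndarray], fs: Optional[float] = None,
             smooth_hz: Optional[float] = None) -> np.ndarray:
    """Angular yaw rate in deg/s from an orientation track or raw yaw series.

    The yaw series is unwrapped (no +-180 degree discontinuities) before
    differentiation; central differences interior, one-sided at the ends.
    An optional zero-phase low-pass (``smooth_hz``) can be applied to the
    rate — off by default.
    """
    if isinstance(track, OrientationTrack):
        yaw = track.yaw
        fs = fs or track.fs
    else:
        yaw = np.asarray(track, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw yaw series")
    unwrapped = np.unwrap(yaw, period=360.0)
    rate = np.gradient(unwrapped) * fs
    if smooth_hz is not None and len(rate) > 12:
        sos = butter(2, smooth_hz, btype="low", fs=fs, output="sos")
        rate = sosfiltfilt(sos, rate)
    return rate
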