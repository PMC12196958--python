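"""Synthetic ear-worn IMU gait trials with exact ground truth.

The generator emulates the four study-style tasks — straight walking, walking
with vertical or horizontal head turns, and a timed-up-and-go-style trial
with a single body turn — at 100 Hz with a known event timeline, so every
downstream module can be tested without recorded data.

Signal model (analysis frame, SI up / ML left / AP forward):

* Timeline: the left foot strikes first at ``lead_in_s``; initial contacts
  alternate every half stride.  Each foot's terminal contact (foot-off)
  follows its own IC by ``stance_fraction * stride_s``.  Within a bout of
  ``n_cycles`` strides per foot that places one contralateral toe-off a
  double-support time after every IC — including the gait-initiation toe-off
  after the very first IC — giving exactly ``n_cycles`` ICs and TCs per side.
* SI: gravity (+9.81) plus one Gaussian burst per event — a large burst at
  each IC, a smaller one at each TC — so peak locations are analytically
  known.  Vertical head turns add a sinusoid here.
* ML: one lateral sway per stride, phased so that its signed slope at each IC
  encodes the stepping side (rising = left, the detectors' convention) and
  its extrema fall on the TCs (the baseline detector's TC rule).  Horizontal
  head turns add a sinusoid at the instructed ~2 Hz rate.
* AP: low-amplitude oscillation at step frequency.
* Gyro: the body turn appears as a smooth raised-cosine yaw ramp on the
  SI-axis rate (yaw is about the down axis, hence the sign flip); white noise
  elsewhere.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .events import GaitEvent
from .exceptions import ConfigError
from .imu_io import ImuTrial
from .turns import TurnInterval, segment_turn

logger = logging.getLogger(__name__)

GRAVITY_SI = 9.80665


@dataclass(frozen=True)
class TurnSpec:
    """Single body turn: raised-cosine yaw ramp."""

    onset_s: float
    duration_s: float
    total_yaw_deg: float


@dataclass
class GaitSimConfig:
    """Study conditions for one synthetic trial.

    ``n_cycles`` is the number of strides per foot; ``head_turn`` perturbs
    the ML (horizontal) or SI (vertical) channel with a sinusoid at
    ``head_turn_rate_hz`` (the instructed ~2 Hz); ``turn`` adds the single
    body turn of a timed-up-and-go-style trial.
    """

    n_cycles: int = 20
    stride_s: float = 1.1
    stance_fraction: float = 0.6
    fs: float = 100.0
    si_peak_amp: float = 2.0        # m/s^2, IC burst
    tc_peak_ratio: float = 0.5      # TC burst amplitude relative to IC burst
    ml_amp: float = 1.0             # m/s^2 lateral sway
    ap_amp: float = 0.3             # m/s^2
    burst_width_s: float = 0.03     # Gaussian burst sigma
    noise_sd: float = 0.1           # m/s^2 accelerometer white noise
    gyro_noise_sd: float = 0.2      # deg/s
    head_turn: str = "none"         # none | vertical | horizontal
    head_turn_rate_hz: float = 2.0
    head_turn_amp: float = 1.0      # m/s^2
    turn: Optional[TurnSpec] = None
    dropped_samples: list = field(default_factory=list)  # [(start, length)]
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles < 2:
            raise ConfigError("n_cycles must be >= 2")
        if not 0.5 <= self.stance_fraction < 1.0:
            raise ConfigError("stance_fraction must lie in [0.5, 1) so that "
                              "double support is non-negative")
        if self.head_turn not in ("none", "vertical", "horizontal"):
            raise ConfigError(f"unknown head_turn {self.head_turn!r}")
        if self.turn is not None:
            if self.turn.onset_s + self.turn.duration_s > self.duration_s:
                raise ConfigError("turn extends beyond the trial")

    @property
    def duration_s(self) -> float:
        walk = (self.n_cycles - 1) * self.stride_s + \
            self.stance_fraction * self.stride_s
        return self.lead_in_s + walk + self.lead_out_s


@dataclass
class SimTruth:
    """Ground truth of one simulated trial."""

    events: list[GaitEvent]
    turn_interval: Optional[TurnInterval]
    stride_s: float
    stance_s: float
    swing_s: float


def _gauss_bursts(t: np.ndarray, centers: np.ndarray, amp: float,
                  sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        out += amp * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return out


def _taper(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """Smooth 0->1->0 window over [start, stop] with cosine ramps."""
    w = np.zeros_like(t)
    core = (t >= start) & (t <= stop)
    w[core] = 1.0
    up = (t >= start - ramp) & (t < start)
    w[up] = 0.5 * (1.0 + np.cos(np.pi * (start - t[up]) / ramp))
    down = (t > stop) & (t <= stop + ramp)
    w[down] = 0.5 * (1.0 + np.cos(np.pi * (t[down] - stop) / ramp))
    return w


def simulate_trial(config: GaitSimConfig) -> tuple[ImuTrial, SimTruth]:
    """Generate one trial and its exact event/turn ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs, stride = cfg.fs, cfg.stride_s
    stance = cfg.stance_fraction * stride
    double_support = stance - stride / 2.0
    t0 = cfg.lead_in_s
    n = cfg.n_cycles

    ic_left = t0 + stride * np.arange(n)
    ic_right = t0 + stride / 2.0 + stride * np.arange(n)
    # contralateral toe-off one double-support after every IC; the first right
    # toe-off is the gait-initiation foot-off from standing
    tc_right = ic_left + double_support
    tc_left = ic_right + double_support

    duration = cfg.duration_s
    n_samples = int(round(duration * fs)) + 1
    t = np.arange(n_samples) / fs

    si = np.full(n_samples, GRAVITY_SI)
    sigma = cfg.burst_width_s
    si += _gauss_bursts(t, ic_left, cfg.si_peak_amp, sigma)
    si += _gauss_bursts(t, ic_right, cfg.si_peak_amp, sigma)
    tc_amp = cfg.si_peak_amp * cfg.tc_peak_ratio
    si += _gauss_bursts(t, tc_left, tc_amp, sigma)
    si += _gauss_bursts(t, tc_right, tc_amp, sigma)

    walk_start, walk_stop = float(ic_left[0]), float(tc_left[-1])
    taper = _taper(t, walk_start, walk_stop, ramp=0.3)
    # sway phased so minima fall on left TCs, maxima on right TCs, and the
    # slope at each IC is positive-left / negative-right
    sway_phase = 2.0 * np.pi * (t - t0 - stance) / stride
    ml = -cfg.ml_amp * np.cos(sway_phase) * taper
    ap = cfg.ap_amp * np.sin(2.0 * np.pi * 2.0 * (t - t0) / stride) * taper

    if cfg.head_turn == "horizontal":
        ml = ml + cfg.head_turn_amp * np.sin(
            2.0 * np.pi * cfg.head_turn_rate_hz * (t - t0)) * taper
    elif cfg.head_turn == "vertical":
        si = si + cfg.head_turn_amp * np.sin(
            2.0 * np.pi * cfg.head_turn_rate_hz * (t - t0)) * taper

    yaw = np.zeros(n_samples)
    yaw_rate = np.zeros(n_samples)
    if cfg.turn is not None:
        tau = (t - cfg.turn.onset_s) / cfg.turn.duration_s
        inside = (tau >= 0) & (tau <= 1)
        yaw[inside] = cfg.turn.total_yaw_deg * 0.5 * (1 - np.cos(np.pi * tau[inside]))
        yaw[tau > 1] = cfg.turn.total_yaw_deg
        yaw_rate[inside] = cfg.turn.total_yaw_deg * 0.5 * np.pi * \
            np.sin(np.pi * tau[inside]) / cfg.turn.duration_s

    accel = np.column_stack([si, ml, ap])
    if cfg.noise_sd > 0:
        accel = accel + rng.normal(0.0, cfg.noise_sd, accel.shape)
    gyro = np.zeros((n_samples, 3))
    gyro[:, 0] = -yaw_rate  # yaw is about the down axis; SI points up
    if cfg.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, cfg.gyro_noise_sd, gyro.shape)

    trial = ImuTrial(accel=accel, gyro=gyro, fs=fs)

    events = []
    for times, kind, side in ((ic_left, "IC", "L"), (ic_right, "IC", "R"),
                              (tc_left, "TC", "L"), (tc_right, "TC", "R")):
        for time in times:
            events.append(GaitEvent(int(round(time * fs)), kind, side, "truth"))
    events.sort(key=lambda e: (e.sample, e.kind))

    turn_interval = None
    if cfg.turn is not None:
        turn_interval = segment_turn(yaw, yaw_rate)

    truth = SimTruth(events=events, turn_interval=turn_interval,
                     stride_s=stride, stance_s=stance, swing_s=stride - stance)
    return trial, truth


def inject_gaps(trial: ImuTrial, gaps) -> ImuTrial:
    """Mark the listed (start, length) runs as missing (NaN + mask).

    Overlapping or adjacent runs are merged with a warning; everything else
    is untouched.
    """
    out = trial.copy()
    n = out.n_samples
    mask = np.zeros(n, dtype=bool)
    for start, length in gaps:
        if start < 0 or start + length > n:
            raise ConfigError(f"gap ({start}, {length}) out of bounds")
        if mask[start:start + length].any():
            logger.warning("overlapping gaps merged at %d", start)
        mask[start:start + length] = True
    out.accel[mask] = np.nan
    out.gyro[mask] = np.nan
    out.missing_mask = out.missing_mask | mask
    return out
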