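"""Trial I/O, dropped-sample handling and axis conventions for ear-worn IMU recordings.

The analysis frame is (SI, ML, AP): superior-inferior positive up, mediolateral
positive toward the participant's left, anterior-posterior positive forward.
Raw device axes are remapped into this frame at read time via an :class:`AxisMap`.
Accelerations are in m/s^2, angular rates in deg/s.

Recordings arrive as CSV with one row per sample at a nominal rate (default
100 Hz).  Lost transmission packets appear either as skipped sample indices or
as rows of NaN; both are treated as missing.  Trials with a run of more than
10 consecutive missing samples, or with any gap within 0.3 s of a reference
initial contact, are screened out before event detection; surviving gaps are
repaired with a cubic spline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import DataError, FormatError

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("sample", "accel_x", "accel_y", "accel_z",
                 "gyro_x", "gyro_y", "gyro_z")
EVENT_COLUMNS = ("sample", "event", "side")

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Longest tolerated run of consecutive missing samples.
MAX_GAP_SAMPLES = 10
#: Half-width (s) of the protected zone around a reference initial contact.
IC_GAP_WINDOW_S = 0.3


@dataclass(frozen=True)
class AxisMap:
    """Mapping from raw device axes to the (SI, ML, AP) analysis frame.

    Each field names a signed device axis, e.g. ``si="-z"`` means the device
    z axis points downward so SI (positive up) is its negation.  The identity
    map reads device x as SI, y as ML, z as AP.
    """

    si: str = "+x"
    ml: str = "+y"
    ap: str = "+z"

    def _parse(self, spec: str) -> tuple[int, float]:
        s = spec.strip().lower()
        sign = 1.0
        if s[0] in "+-":
            sign = -1.0 if s[0] == "-" else 1.0
            s = s[1:]
        if s not in _AXIS_INDEX:
            raise FormatError(f"bad axis spec {spec!r}; expected e.g. '+x', '-z'")
        return _AXIS_INDEX[s], sign

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Remap an (N, 3) device-frame array into (SI, ML, AP) columns."""
        cols = []
        for spec in (self.si, self.ml, self.ap):
            idx, sign = self._parse(spec)
            cols.append(sign * xyz[:, idx])
        return np.column_stack(cols)

    @classmethod
    def from_dict(cls, d: dict) -> "AxisMap":
        return cls(si=d.get("si", "+x"), ml=d.get("ml", "+y"), ap=d.get("ap", "+z"))


@dataclass
class ImuTrial:
    """One 6-axis inertial recording in the (SI, ML, AP) analysis frame.

    ``accel`` and ``gyro`` are (N, 3) arrays with columns SI, ML, AP;
    ``missing_mask`` marks samples that were absent in the raw file (and, after
    :func:`fill_gaps`, interpolated).
    """

    accel: np.ndarray
    gyro: np.ndarray
    fs: float = 100.0
    side: str = "left"
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise DataError("accel must be (N, 3)")
        if self.gyro.shape != self.accel.shape:
            raise DataError("gyro must match accel shape")
        if not self.fs > 0:
            raise DataError("fs must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.accel), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (len(self.accel),):
            raise DataError("missing_mask length must match the channels")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.accel)

    @property
    def sample_index(self) -> np.ndarray:
        return np.arange(self.n_samples)

    @property
    def t(self) -> np.ndarray:
        """Time of each sample in seconds from trial start."""
        return self.sample_index / self.fs

    @property
    def si(self) -> np.ndarray:
        return self.accel[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.accel[:, 1]

    @property
    def ap(self) -> np.ndarray:
        return self.accel[:, 2]

    def copy(self) -> "ImuTrial":
        return ImuTrial(self.accel.copy(), self.gyro.copy(), self.fs,
                        self.side, self.missing_mask.copy())


class ExclusionReason(str, Enum):
    NONE = "none"
    LONG_GAP = "long_gap"
    GAP_NEAR_IC = "gap_near_ic"


@dataclass
class GapReport:
    """Outcome of the dropped-sample screen for one trial."""

    gaps: list[tuple[int, int]]        # (start_index, length)
    max_run: int
    excluded: bool
    exclusion_reason: ExclusionReason


def read_trial(path, axis_map: Optional[AxisMap] = None, fs: float = 100.0,
               side: str = "left") -> ImuTrial:
    """Read a trial CSV, remap axes, and mark missing samples.

    Skipped sample indices are re-inserted as missing rows so the returned
    trial has a contiguous 0-based index; rows containing NaN are also marked
    missing.
    """
    axis_map = axis_map or AxisMap()
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    samples = df["sample"].to_numpy()
    if len(samples) == 0:
        raise DataError(f"{path}: empty trial")
    if np.any(np.diff(samples) <= 0):
        raise DataError(f"{path}: sample index not strictly increasing")
    full = np.arange(int(samples[0]), int(samples[-1]) + 1)
    df = df.set_index("sample").reindex(full)
    chan = df[list(TRIAL_COLUMNS[1:])].to_numpy(dtype=float)
    missing = np.any(np.isnan(chan), axis=1)
    accel = axis_map.apply(chan[:, 0:3])
    gyro = axis_map.apply(chan[:, 3:6])
    return ImuTrial(accel=accel, gyro=gyro, fs=fs, side=side, missing_mask=missing)


def write_trial(trial: ImuTrial, path) -> None:
    """Write a trial as CSV in the analysis frame (identity axis map).

    Missing samples are written with empty channel fields so a round trip
    through :func:`read_trial` restores the missing mask.
    """
    chan = np.hstack([trial.accel, trial.gyro]).astype(float)
    chan = chan.copy()
    chan[trial.missing_mask] = np.nan
    df = pd.DataFrame(chan, columns=list(TRIAL_COLUMNS[1:]))
    df.insert(0, "sample", trial.sample_index)
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip


def read_events(path):
    """Read an event table CSV (``sample,event,side``) into a GaitEvent list."""
    from .events import GaitEvent

    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = [GaitEvent(sample=int(r.sample), kind=str(r.event), side=str(r.side))
           for r in df.itertuples()]
    return sorted(out, key=lambda e: e.sample)


def write_events(events, path) -> None:
    df = pd.DataFrame({"sample": [e.sample for e in events],
                       "event": [e.kind for e in events],
                       "side": [e.side for e in events]})
    df.to_csv(path, index=False)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in a boolean mask as (start, length)."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def detect_gaps(trial: ImuTrial,
                reference_ics: Optional[Sequence[int]] = None,
                max_gap_samples: int = MAX_GAP_SAMPLES,
                ic_window_s: float = IC_GAP_WINDOW_S) -> GapReport:
    """Enumerate missing-sample runs and apply the trial-exclusion screen.

    A trial is excluded when its longest missing run exceeds ``max_gap_samples``
    or, if reference initial contacts are supplied, when any missing sample
    lies within ``ic_window_s`` seconds of one of them (such a gap would
    directly interfere with detecting that contact).
    """
    gaps = _runs(trial.missing_mask)
    max_run = max((length for _, length in gaps), default=0)
    if max_run > max_gap_samples:
        return GapReport(gaps, max_run, True, ExclusionReason.LONG_GAP)
    if reference_ics is not None and gaps:
        window = ic_window_s * trial.fs
        ics = np.asarray(list(reference_ics), dtype=float)
        if ics.size:
            for start, length in gaps:
                samples = np.arange(start, start + length)
                dist = np.min(np.abs(samples[:, None] - ics[None, :]))
                if dist <= window:
                    return GapReport(gaps, max_run, True, ExclusionReason.GAP_NEAR_IC)
    return GapReport(gaps, max_run, False, ExclusionReason.NONE)


def fill_gaps(trial: ImuTrial) -> ImuTrial:
    """Replace missing samples by cubic-spline interpolation per channel.

    Interior gaps are filled with a not-a-knot cubic spline through the
    observed samples (which reproduces cubic polynomials exactly).  Leading or
    trailing missing runs are filled by holding the nearest observed value —
    cubic extrapolation beyond the data is wild, and badly truncated trials
    are removed by the exclusion screen anyway.  Observed samples are never
    modified; the returned mask still records which positions were filled.
    """
    if not trial.missing_mask.any():
        return trial.copy()
    out = trial.copy()
    obs = ~trial.missing_mask
    n_obs = int(obs.sum())
    if n_obs < 4:
        raise DataError("need at least 4 observed samples per channel to fill gaps")
    idx = trial.sample_index
    first, last = idx[obs][0], idx[obs][-1]
    if trial.missing_mask[0] or trial.missing_mask[-1]:
        logger.warning("boundary gap filled by nearest-value hold, not spline")
    for arr in (out.accel, out.gyro):
        for c in range(3):
            y = arr[:, c]
            spline = CubicSpline(idx[obs], y[obs])  # not-a-knot ends
            interior = trial.missing_mask & (idx > first) & (idx < last)
            y[interior] = spline(idx[interior])
            y[idx < first] = y[first]
            y[idx > last] = y[last]
    return out
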