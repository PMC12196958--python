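"""Gait-event detection from ear-worn SI and ML acceleration.

Two detectors are provided.

The SSA baseline (Diao with Seifer's laterality refinement): initial contacts
(ICs) are the peaks of the dominant SSA oscillation of the superior-inferior
(SI) acceleration; each IC's side comes from the signed sample-to-sample
difference of the dominant mediolateral (ML) oscillation at the IC (positive
slope = left); the terminal contact (TC) is the next local extremum of the
trend-removed ML signal after the IC, extremum polarity chosen by the IC's
side.

TP-EAR keeps the SSA-based IC estimator but reads TCs from the SI channel,
which lateral head movements barely disturb.  The SI signal is band-pass
filtered 0.5-12 Hz (wider than the baseline's 5 Hz ceiling, to keep the
IC/TC peak pair visible); for each dominant-SI peak a "trusted" window is
opened from the last 80 %-of-peak crossing before the peak to the next
dominant minimum, and the peaks of the windowed filtered signal are counted:

* two peaks: first = IC, second = TC;
* more than two: IC = peak closest to the dominant peak, TC = latest peak
  with positive (band-passed) value;
* one peak: a peak-sharpening pass is applied and the count redone; if still
  one, IC = the dominant peak and TC = the sample of minimum gradient from
  the IC to the window end.

Laterality is determined exactly as in the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .exceptions import ConfigError
from .imu_io import ImuTrial
from .ssa import dominant_oscillation, ssa_decompose, trend_removed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitEvent:
    """One detected or ground-truth gait event."""

    sample: int
    kind: str            # "IC" | "TC"
    side: str = "U"      # "L" | "R" | "U"
    source: str = "truth"  # "diao" | "tpear" | "truth"

    def __post_init__(self):
        if self.kind not in ("IC", "TC"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.side not in ("L", "R", "U"):
            raise ValueError(f"bad side {self.side!r}")


@dataclass
class TpearWindow:
    """Per-cycle trusted window around one dominant-SI peak."""

    open_index: int
    peak_index: int
    close_index: int
    truncated: bool = False

    def __post_init__(self):
        if not (self.open_index <= self.peak_index < self.close_index):
            raise ValueError("window must satisfy open <= peak < close")


@dataclass(frozen=True)
class DetectorConfig:
    """Knobs shared by both detectors; defaults follow the published setup."""

    diao_band: tuple[float, float] = (0.5, 5.0)
    tpear_band: tuple[float, float] = (0.5, 12.0)
    filter_order: int = 4
    window_seconds: float = 2.0
    #: minimum prominence of raw-signal peaks, as a fraction of the segment's
    #: peak-to-peak range
    peak_prominence_frac: float = 0.05
    #: reject dominant-oscillation peaks below this fraction of the largest
    #: dominant peak (suppresses edge ripple outside the walking bout)
    dominant_min_rel_height: float = 0.2
    #: Diao TC polarity: extremum of the trend-removed ML sought after a left
    #: IC ("max" or "min"); the right side uses the opposite
    left_tc_extremum: str = "max"
    #: tie-break when two window peaks are equally close to the dominant peak
    tie_break: str = "earlier"
    sharpen_weight: float = 8.0


def bandpass(signal: np.ndarray, low_hz: float, high_hz: float, fs: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ConfigError(f"invalid band ({low_hz}, {high_hz}) at fs={fs}")
    sos = butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def dominant_peaks(dominant: np.ndarray, min_rel_height: float = 0.2) -> np.ndarray:
    """Maxima of a dominant oscillation via zero crossings of its derivative.

    Peaks below ``min_rel_height`` times the largest peak are dropped: the
    diagonal averaging of SSA leaves low-amplitude ripple outside the walking
    bout which would otherwise spawn spurious cycles.
    """
    d = np.diff(dominant)
    idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    if idx.size == 0:
        return idx
    top = dominant[idx].max()
    if top <= 0:
        return np.array([], dtype=int)
    return idx[dominant[idx] >= min_rel_height * top]


def determine_laterality(ml_dominant: np.ndarray,
                         ic_samples: Sequence[int]) -> list[str]:
    """Side of each IC from the slope of the dominant ML oscillation.

    A positive signed difference between consecutive samples at the IC means
    the head is swaying toward the participant's left, hence a left IC;
    otherwise right.  An IC at sample 0 uses the forward difference.
    """
    ml = np.asarray(ml_dominant, dtype=float)
    sides = []
    for ic in ic_samples:
        if ic <= 0:
            diff = ml[1] - ml[0]
        else:
            diff = ml[ic] - ml[ic - 1]
        sides.append("L" if diff > 0 else "R")
    return sides


def tpear_window(dominant_si: np.ndarray, peak_index: int) -> TpearWindow:
    """Open the trusted window belonging to one dominant-SI peak.

    Opens at the last sample before the peak where the dominant signal is at
    or below 80 % of the peak value; closes at the first local minimum after
    the peak.  Windows clipped by the series edge are flagged truncated.
    """
    x = np.asarray(dominant_si, dtype=float)
    n = x.size
    peak_value = x[peak_index]
    truncated = False
    open_index = peak_index
    threshold = 0.8 * peak_value
    while open_index > 0 and x[open_index - 1] > threshold:
        open_index -= 1
    if open_index > 0:
        open_index -= 1  # the crossing sample itself (value <= threshold)
    else:
        truncated = True
    close = peak_index
    while close + 1 < n and x[close + 1] < x[close]:
        close += 1
    if close == peak_index or close + 1 >= n:
        truncated = truncated or close + 1 >= n
        close = min(peak_index + 1, n - 1)
        # keep walking down even on a flat end so the window is non-empty
        while close + 1 < n and x[close + 1] <= x[close]:
            close += 1
    if close <= peak_index:
        raise ValueError("dominant peak at the series end has no window")
    return TpearWindow(open_index=open_index, peak_index=peak_index,
                       close_index=close, truncated=truncated)


def sharpen_peaks(segment: np.ndarray, weight: float = 8.0,
                  lag: int = 3) -> np.ndarray:
    """Amplitude-weighted even-derivative peak sharpening.

    Subtracts the smoothed second difference (taken at a short ``lag``,
    3 samples = 30 ms at 100 Hz — about the width of a foot-contact burst)
    scaled by the local normalized signal amplitude:

        y = x - weight * d2(x) * (x - min x) / ptp(x)

    The amplitude weighting confines the correction to elevated parts of the
    segment, so shoulder inflections riding on a peak's flank become
    countable local maxima while the near-zero valley between well-separated
    peaks is untouched (no artifact peaks, maxima keep their locations).
    Deterministic.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n < 3:
        return x.copy()
    lag = min(max(1, lag), n - 1)
    xp = np.pad(x, lag, mode="edge")
    d2 = xp[2 * lag:] - 2.0 * x + xp[:n]
    d2 = np.convolve(d2, np.ones(3) / 3.0, mode="same")
    rng = np.ptp(x)
    if rng <= 0:
        return x.copy()
    amp = (x - x.min()) / rng
    return x - weight * d2 * amp


def _raw_peaks(segment: np.ndarray, prominence_frac: float) -> np.ndarray:
    rng = np.ptp(segment)
    if rng <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(segment, prominence=prominence_frac * rng)
    return peaks


def _min_gradient_tc(f: np.ndarray, ic: int, close: int) -> int:
    """Sample of minimum gradient of ``f`` on (ic, close]."""
    grad = np.gradient(f)
    lo = ic + 1
    if lo > close:
        return close
    return lo + int(np.argmin(grad[lo:close + 1]))


def _next_extremum(x: np.ndarray, start: int, stop: int, kind: str) -> Optional[int]:
    """First interior local max/min of x strictly inside (start, stop)."""
    for i in range(start + 1, min(stop, x.size - 1)):
        if kind == "max":
            if x[i] >= x[i - 1] and x[i] > x[i + 1]:
                return i
        else:
            if x[i] <= x[i - 1] and x[i] < x[i + 1]:
                return i
    return None


def _prepare(trial: ImuTrial, band: tuple[float, float], cfg: DetectorConfig):
    """Band-pass the SI channel, decompose SI and ML, return working signals."""
    f = bandpass(trial.si, band[0], band[1], trial.fs, cfg.filter_order)
    dec_si = ssa_decompose(f, cfg.window_seconds, trial.fs)
    dom_si = dominant_oscillation(dec_si)
    dec_ml = ssa_decompose(trial.ml, cfg.window_seconds, trial.fs)
    dom_ml = dominant_oscillation(dec_ml)
    return f, dom_si, dec_ml, dom_ml


def detect_events_diao(trial: ImuTrial,
                       config: Optional[DetectorConfig] = None) -> list[GaitEvent]:
    """SSA baseline: ICs from the dominant SI oscillation, TCs from ML extrema."""
    cfg = config or DetectorConfig()
    _, dom_si, dec_ml, dom_ml = _prepare(trial, cfg.diao_band, cfg)
    tr_ml = trend_removed(dec_ml)
    ics = dominant_peaks(dom_si, cfg.dominant_min_rel_height)
    sides = determine_laterality(dom_ml, ics)
    events: list[GaitEvent] = []
    n = trial.n_samples
    for j, (ic, side) in enumerate(zip(ics, sides)):
        events.append(GaitEvent(int(ic), "IC", side, "diao"))
        next_ic = int(ics[j + 1]) if j + 1 < len(ics) else n - 1
        polarity = cfg.left_tc_extremum if side == "L" else \
            ("min" if cfg.left_tc_extremum == "max" else "max")
        tc = _next_extremum(tr_ml, int(ic), next_ic, polarity)
        if tc is None:
            logger.debug("no ML extremum between IC %d and next IC; TC skipped", ic)
            continue
        events.append(GaitEvent(int(tc), "TC", "U", "diao"))
    return sorted(events, key=lambda e: (e.sample, e.kind))


def detect_events_tpear(trial: ImuTrial,
                        config: Optional[DetectorConfig] = None) -> list[GaitEvent]:
    """TP-EAR: per-cycle trusted windows on the band-passed SI signal."""
    cfg = config or DetectorConfig()
    f, dom_si, _, dom_ml = _prepare(trial, cfg.tpear_band, cfg)
    peaks = dominant_peaks(dom_si, cfg.dominant_min_rel_height)
    events: list[GaitEvent] = []
    last_ic = -1
    for p in peaks:
        if int(p) >= trial.n_samples - 1:
            continue
        w = tpear_window(dom_si, int(p))
        ic, tc = _window_events(f, w, cfg)
        if ic <= last_ic:
            continue  # overlapping windows must not emit out-of-order cycles
        side = determine_laterality(dom_ml, [ic])[0]
        events.append(GaitEvent(ic, "IC", side, "tpear"))
        events.append(GaitEvent(tc, "TC", "U", "tpear"))
        last_ic = ic
    events.sort(key=lambda e: (e.sample, e.kind))
    return _drop_straddling_tcs(events)


def _window_events(f: np.ndarray, w: TpearWindow, cfg: DetectorConfig) -> tuple[int, int]:
    """Apply the peak-count branch rules inside one trusted window."""
    seg = f[w.open_index:w.close_index + 1]
    peaks = _raw_peaks(seg, cfg.peak_prominence_frac) + w.open_index
    if len(peaks) == 1:
        sharp = sharpen_peaks(seg, cfg.sharpen_weight)
        speaks = _raw_peaks(sharp, cfg.peak_prominence_frac) + w.open_index
        if len(speaks) >= 2:
            return _branch(sharp, speaks - w.open_index, w, cfg,
                           offset=w.open_index)
        return w.peak_index, _min_gradient_tc(f, w.peak_index, w.close_index)
    if len(peaks) == 0:
        return w.peak_index, _min_gradient_tc(f, w.peak_index, w.close_index)
    return _branch(f[w.open_index:w.close_index + 1], peaks - w.open_index, w,
                   cfg, offset=w.open_index)


def _branch(values: np.ndarray, peaks: np.ndarray, w: TpearWindow,
            cfg: DetectorConfig, offset: int) -> tuple[int, int]:
    abs_peaks = peaks + offset
    if len(peaks) == 2:
        return int(abs_peaks[0]), int(abs_peaks[1])
    # more than two: IC closest to the dominant peak, TC latest positive peak
    dist = np.abs(abs_peaks - w.peak_index)
    if cfg.tie_break == "earlier":
        ic = int(abs_peaks[np.argmin(dist)])
    else:
        ic = int(abs_peaks[len(dist) - 1 - np.argmin(dist[::-1])])
    positive = abs_peaks[(values[peaks] > 0) & (abs_peaks > ic)]
    if positive.size:
        return ic, int(positive[-1])
    return ic, _min_gradient_tc_from(values, offset, ic, w.close_index)


def _min_gradient_tc_from(values: np.ndarray, offset: int, ic: int, close: int) -> int:
    grad = np.gradient(values)
    lo = ic - offset + 1
    hi = close - offset
    if lo > hi:
        return close
    return offset + lo + int(np.argmin(grad[lo:hi + 1]))


def _drop_straddling_tcs(events: list[GaitEvent]) -> list[GaitEvent]:
    """Enforce: every TC lies strictly between its IC and the next IC."""
    out: list[GaitEvent] = []
    ics = [e.sample for e in events if e.kind == "IC"]
    for e in events:
        if e.kind == "IC":
            out.append(e)
            continue
        prev_ic = max((s for s in ics if s < e.sample), default=None)
        next_ic = min((s for s in ics if s > e.sample), default=None)
        if prev_ic is None:
            logger.debug("TC at %d before any IC dropped", e.sample)
            continue
        if next_ic is not None and e.sample >= next_ic:
            logger.debug("TC at %d beyond the next IC dropped", e.sample)
            continue
        out.append(e)
    return out
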