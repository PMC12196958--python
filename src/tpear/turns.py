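"""Turn segmentation from the yaw track.

Each timed-up-and-go-style trial contains a single turn.  Because the head
leads the body into a turn, the turn start is declared at the first sample
where both |yaw| > 15 degrees and |yaw rate| > 30 deg/s; the turn ends at the
first subsequent sample where |yaw| is within 5 degrees of the trial's
maximum absolute yaw (the head has reached its maximal rotation).  Yaw is
referenced to the pre-turn heading (0 at trial start), so the thresholds are
meaningful without a magnetometer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

YAW_START_DEG = 15.0
RATE_START_DPS = 30.0
END_MARGIN_DEG = 5.0


@dataclass
class TurnInterval:
    """The single detected turn: [start_index, end_index] in samples."""

    start_index: int
    end_index: int
    yaw_max_abs: float
    start_thresholds: tuple[float, float] = (YAW_START_DEG, RATE_START_DPS)
    end_margin: float = END_MARGIN_DEG


def segment_turn(yaw: np.ndarray, rate: np.ndarray,
                 yaw_start_deg: float = YAW_START_DEG,
                 rate_start_dps: float = RATE_START_DPS,
                 end_margin_deg: float = END_MARGIN_DEG) -> Optional[TurnInterval]:
    """Locate the turn; returns None when no sample meets the start criteria.

    Start: earliest sample with |yaw| > yaw_start_deg AND |rate| > rate_start_dps
    (both at the same sample).  End: earliest sample at/after start with
    |yaw| >= max|yaw| - end_margin_deg, the maximum taken over the whole trial.
    """
    yaw = np.asarray(yaw, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if yaw.shape != rate.shape:
        raise ValueError("yaw and rate must have equal length")
    if yaw.size == 0:
        return None
    yaw_abs = np.abs(yaw)
    yaw_max = float(yaw_abs.max())
    if yaw_max <= yaw_start_deg:
        return None
    start_mask = (yaw_abs > yaw_start_deg) & (np.abs(rate) > rate_start_dps)
    starts = np.flatnonzero(start_mask)
    if starts.size == 0:
        return None
    start = int(starts[0])
    runs = np.flatnonzero(np.diff(starts) > 1)
    if runs.size:
        logger.warning("multiple turn-like excursions; using the earliest start")
    ends = np.flatnonzero(yaw_abs[start:] >= yaw_max - end_margin_deg)
    end = start + int(ends[0])
    degenerate = end <= start
    if degenerate:
        # start sample already within the end margin (near-instant turn)
        logger.warning("turn start already within the end margin")
        end = min(start + 1, yaw.size - 1)
    interval = TurnInterval(start_index=start, end_index=end, yaw_max_abs=yaw_max,
                            start_thresholds=(yaw_start_deg, rate_start_dps),
                            end_margin=end_margin_deg)
    if not degenerate:
        _check(interval, yaw_abs, rate, yaw_start_deg, rate_start_dps, end_margin_deg)
    return interval


def _check(iv: TurnInterval, yaw_abs, rate, yaw_thr, rate_thr, margin) -> None:
    assert iv.start_index < iv.end_index
    assert yaw_abs[iv.start_index] > yaw_thr
    assert abs(rate[iv.start_index]) > rate_thr
    assert yaw_abs[iv.end_index] >= iv.yaw_max_abs - margin


def split_events_by_turn(events, interval: Optional[TurnInterval]):
    """Partition an event list into pre-turn / turn / post-turn segments."""
    if interval is None:
        return list(events), [], []
    pre = [e for e in events if e.sample < interval.start_index]
    mid = [e for e in events if interval.start_index <= e.sample <= interval.end_index]
    post = [e for e in events if e.sample > interval.end_index]
    return pre, mid, post
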