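"""Scoring of detected gait events against ground truth.

Events are matched per kind (ICs with ICs, TCs with TCs, sides ignored) by a
one-to-one assignment that maximizes the number of pairs within the matching
tolerance (default 300 ms) and, among those, minimizes the total absolute
offset.  Unmatched truth events count as false negatives, unmatched detected
events as false positives; sensitivity = TP / (TP + FN).  Laterality accuracy
is the fraction of matched IC pairs whose sides agree.  Temporal-parameter
errors are signed differences (detected minus truth) of stride/stance/swing
per cycle, summarized as mean +- SD of the signed and absolute error in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import correlate

from .events import GaitEvent
from .exceptions import DataError
from .temporal import CycleParams

TOLERANCE_S = 0.3
_BIG = 1e9


@dataclass
class MatchResult:
    """One-to-one event matching between a truth and a detected stream."""

    pairs: list[tuple[GaitEvent, GaitEvent, float]]  # (truth, detected, offset_s)
    false_negatives: list[GaitEvent]
    false_positives: list[GaitEvent]
    tolerance_s: float = TOLERANCE_S
    #: unmatched truth events are scored as false negatives so that
    #: sensitivity is computable
    notes: dict = field(default_factory=dict)


def align_start(imu_signal: np.ndarray, reference_signal: np.ndarray) -> int:
    """Integer lag (samples) maximizing the cross-correlation of two series.

    A positive lag means the IMU series is delayed relative to the reference:
    imu[n] ~ reference[n - lag].  Both series must share the sampling rate.
    """
    x = np.asarray(imu_signal, dtype=float)
    r = np.asarray(reference_signal, dtype=float)
    if np.ptp(x) == 0 or np.ptp(r) == 0:
        raise DataError("flat series: start-alignment lag is undefined")
    c = correlate(x - x.mean(), r - r.mean(), mode="full")
    return int(np.argmax(c)) - (len(r) - 1)


def _match_kind(truth: list[GaitEvent], detected: list[GaitEvent],
                tolerance_s: float, fs: float):
    if not truth or not detected:
        return [], list(truth), list(detected)
    ts = np.array([e.sample for e in truth], dtype=float) / fs
    ds = np.array([e.sample for e in detected], dtype=float) / fs
    cost = np.abs(ts[:, None] - ds[None, :])
    cost[cost > tolerance_s] = _BIG
    rows, cols = linear_sum_assignment(cost)
    pairs, used_t, used_d = [], set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] < _BIG:
            pairs.append((truth[i], detected[j], float(ds[j] - ts[i])))
            used_t.add(i)
            used_d.add(j)
    fn = [e for i, e in enumerate(truth) if i not in used_t]
    fp = [e for j, e in enumerate(detected) if j not in used_d]
    return pairs, fn, fp


def match_events(truth: Sequence[GaitEvent], detected: Sequence[GaitEvent],
                 tolerance_s: float = TOLERANCE_S, fs: float = 100.0) -> MatchResult:
    """Match truth and detected events per kind within the tolerance window."""
    pairs: list = []
    fn: list = []
    fp: list = []
    for kind in ("IC", "TC"):
        t = sorted((e for e in truth if e.kind == kind), key=lambda e: e.sample)
        d = sorted((e for e in detected if e.kind == kind), key=lambda e: e.sample)
        p, n, q = _match_kind(t, d, tolerance_s, fs)
        pairs += p
        fn += n
        fp += q
    return MatchResult(pairs=pairs, false_negatives=fn, false_positives=fp,
                       tolerance_s=tolerance_s,
                       notes={"unmatched_truth_scored_as": "false_negative"})


def sensitivity(match: MatchResult, kind: Optional[str] = None) -> Optional[float]:
    """100 * TP / (TP + FN) for one event kind (or all kinds together).

    Returns None when there are no truth events of that kind.
    """
    pairs = [p for p in match.pairs if kind is None or p[0].kind == kind]
    fn = [e for e in match.false_negatives if kind is None or e.kind == kind]
    total = len(pairs) + len(fn)
    if total == 0:
        return None
    return 100.0 * len(pairs) / total


def laterality_accuracy(match: MatchResult) -> Optional[float]:
    """Percent of matched IC pairs with agreeing sides; None without pairs."""
    ic_pairs = [(t, d) for t, d, _ in match.pairs if t.kind == "IC"]
    if not ic_pairs:
        return None
    correct = sum(1 for t, d in ic_pairs if t.side == d.side)
    return 100.0 * correct / len(ic_pairs)


@dataclass
class ErrorStats:
    """Mean +- SD of the absolute and signed error of one parameter, in ms."""

    mae_ms: float
    sd_ae_ms: float
    mse_ms: float   # mean signed error
    sd_se_ms: float
    n: int


def temporal_error_stats(truth_cycles: Sequence[CycleParams],
                         detected_cycles: Sequence[CycleParams],
                         match: MatchResult,
                         outlier_ms: Optional[float] = None,
                         ) -> dict[str, Optional[ErrorStats]]:
    """Per-parameter error statistics over cycles paired through matched ICs.

    A truth cycle is compared with the detected cycle whose start and end ICs
    are the ones its own ICs were matched to.  Signed error = detected minus
    truth.  Large |errors| beyond ``outlier_ms`` can optionally be excluded
    (they arise when one bounding event is early and the other late); by
    default everything is retained.
    """
    ic_map = {t.sample: d.sample for t, d, _ in match.pairs if t.kind == "IC"}
    det_by_start = {c.ic_start: c for c in detected_cycles}
    errors: dict[str, list[float]] = {"stride": [], "stance": [], "swing": []}
    for tc_cycle in truth_cycles:
        d_start = ic_map.get(tc_cycle.ic_start)
        d_end = ic_map.get(tc_cycle.ic_end)
        if d_start is None or d_end is None:
            continue
        det = det_by_start.get(d_start)
        if det is None or det.ic_end != d_end:
            continue
        errors["stride"].append(1000.0 * (det.stride_s - tc_cycle.stride_s))
        errors["stance"].append(1000.0 * (det.stance_s - tc_cycle.stance_s))
        errors["swing"].append(1000.0 * (det.swing_s - tc_cycle.swing_s))
    out: dict[str, Optional[ErrorStats]] = {}
    for param, se in errors.items():
        se_arr = np.asarray(se, dtype=float)
        if outlier_ms is not None and se_arr.size:
            se_arr = se_arr[np.abs(se_arr) <= outlier_ms]
        if se_arr.size == 0:
            out[param] = None
            continue
        ae = np.abs(se_arr)
        ddof = 1 if se_arr.size > 1 else 0
        out[param] = ErrorStats(
            mae_ms=float(ae.mean()), sd_ae_ms=float(ae.std(ddof=ddof)),
            mse_ms=float(se_arr.mean()), sd_se_ms=float(se_arr.std(ddof=ddof)),
            n=int(se_arr.size),
        )
    return out
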