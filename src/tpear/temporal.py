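"""Per-cycle temporal gait parameters from an event stream.

A gait cycle runs between consecutive initial contacts of the same foot:

    stride = (IC_end - IC_start) / fs
    stance = (TC - IC_start) / fs
    swing  = (IC_end - TC) / fs

so stride = stance + swing holds exactly by construction.  The TC in these
formulas is the foot-off of the cycle's own foot.  When the stream carries
both feet's TCs (as ground truth and both detectors do), two TCs fall inside
each cycle span: the contralateral toe-off shortly after IC_start (double
support) and the ipsilateral foot-off near 60 % of the cycle.  The cycle
therefore takes the last TC strictly inside its span — equivalently the
first TC after the opposite foot's IC — which is the ipsilateral one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .events import GaitEvent
from .exceptions import DataError

logger = logging.getLogger(__name__)


@dataclass
class CycleParams:
    """Stride/stance/swing durations of one gait cycle, in seconds."""

    ic_start: int
    tc: int
    ic_end: int
    side: str
    stride_s: float
    stance_s: float
    swing_s: float


def build_cycles(events: Sequence[GaitEvent], fs: float) -> list[CycleParams]:
    """Assemble per-cycle parameters from a sorted, side-labelled event list.

    Cycles are built per side independently from consecutive same-side ICs.
    A cycle without any TC strictly inside its span is skipped (and logged):
    this costs sensitivity downstream but never raises.
    """
    events = list(events)
    samples = [e.sample for e in events]
    if samples != sorted(samples):
        raise DataError("event list must be sorted by sample")
    tcs = np.array(sorted(e.sample for e in events if e.kind == "TC"), dtype=int)
    cycles: list[CycleParams] = []
    for side in ("L", "R"):
        ics = [e.sample for e in events if e.kind == "IC" and e.side == side]
        for a, b in zip(ics, ics[1:]):
            inside = tcs[(tcs > a) & (tcs < b)]
            if inside.size == 0:
                logger.debug("cycle %s [%d, %d] has no TC; skipped", side, a, b)
                continue
            if inside.size > 2:
                logger.warning("cycle %s [%d, %d] has %d TCs", side, a, b, inside.size)
            tc = int(inside[-1])
            cycles.append(CycleParams(
                ic_start=int(a), tc=tc, ic_end=int(b), side=side,
                stride_s=(b - a) / fs,
                stance_s=(tc - a) / fs,
                swing_s=(b - tc) / fs,
            ))
    cycles.sort(key=lambda c: c.ic_start)
    return cycles


def cycles_to_frame(cycles: Iterable[CycleParams]):
    """CycleParams list -> pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "side": c.side, "ic_start": c.ic_start, "tc": c.tc, "ic_end": c.ic_end,
        "stride_s": c.stride_s, "stance_s": c.stance_s, "swing_s": c.swing_s,
    } for c in cycles])
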