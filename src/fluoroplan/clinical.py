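"""Bundled example dataset: a six-case retrospective plate-position series.

For each case, image pairs from two intraoperative stages (before and
after insertion of the proximal screws) were evaluated: the view angle of
the selected pair at each stage and the plate offset of the head center
from the central screw trajectory in the dorsal-ventral (negative =
ventral) and cranial-caudal (negative = caudal) directions.  The series
illustrates the summary arithmetic this package applies to pre/post
measurements: per-stage view-angle statistics and componentwise absolute
plate-position shifts, the screening quantity for head-fragment
displacement during screw insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .planning import PlateOffset, offset_difference


@dataclass(frozen=True)
class CaseRecord:
    case_id: int
    pre_view_angle_deg: float
    post_view_angle_deg: float
    pre_offset: PlateOffset
    post_offset: PlateOffset


SIX_CASE_SERIES: tuple[CaseRecord, ...] = (
    CaseRecord(2, 31.0, 25.0, PlateOffset(-1.0, 5.0), PlateOffset(-2.0, 4.0)),
    CaseRecord(3, 31.0, 30.0, PlateOffset(-5.0, 8.0), PlateOffset(-5.0, 9.0)),
    CaseRecord(4, 24.0, 22.0, PlateOffset(-1.0, 7.0), PlateOffset(-1.0, 8.0)),
    CaseRecord(6, 27.0, 31.0, PlateOffset(4.0, 4.0), PlateOffset(0.0, 3.0)),
    CaseRecord(10, 34.0, 27.0, PlateOffset(-1.0, 8.0), PlateOffset(9.0, 8.0)),
    CaseRecord(11, 24.0, 19.0, PlateOffset(-1.0, 0.0), PlateOffset(-3.0, 2.0)),
)


def mean_view_angle(series: tuple[CaseRecord, ...] = SIX_CASE_SERIES) -> float:
    """Mean view angle pooled over both stages of every case (degrees)."""
    angles = [a for c in series for a in (c.pre_view_angle_deg, c.post_view_angle_deg)]
    return float(np.mean(angles))


def offset_shifts(series: tuple[CaseRecord, ...] = SIX_CASE_SERIES) -> dict[int, dict]:
    """Per-case componentwise absolute plate-position shift (mm)."""
    return {c.case_id: offset_difference(c.pre_offset, c.post_offset) for c in series}


def max_shift_excluding(case_id: int, series: tuple[CaseRecord, ...] = SIX_CASE_SERIES) -> float:
    """Largest single-component shift over all cases except ``case_id``."""
    shifts = offset_shifts(series)
    return max(
        max(v["dv_diff"], v["cc_diff"]) for cid, v in shifts.items() if cid != case_id
    )
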