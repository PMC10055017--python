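"""Screw-length planning by trajectory-sphere truncation, plus plate metrics.

Each locking screw runs along a fixed trajectory in the plate.  Given the
humeral-head sphere estimate (in the marker frame), every proximal screw is
virtually truncated to a target tip-joint distance (TJD, default 5 mm): the
far intersection of the trajectory with the sphere is the articular exit
point, the continuous ("raw") length is the seat-to-exit distance minus the
target TJD, and the suggested length is that raw value rounded *down* to
the catalog — rounding down is the only direction consistent with joint-
perforation safety (a rounding-to-nearest mode exists for sensitivity
analysis, flagged in the report header).  The achieved TJD of the rounded
screw therefore always lies in [target, target + catalog increment).

The plate position relative to the anatomy is summarized by the plate
offset: the displacement of the head-center estimate from the central
screw trajectory, resolved along the plate's dorsal-ventral and
cranial-caudal axes (negative = ventral resp. caudal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidStatus, ParamError
from .geometry import Line3, Pose, Sphere, line_sphere_intersect, pose_compose
from .implant import ImplantGeometry, screw_trajectory


@dataclass(frozen=True)
class ScrewPlan:
    """Planning result for one screw (lengths/distances in mm, marker frame)."""

    label: str
    trajectory: Line3
    entry_point: np.ndarray | None
    exit_point: np.ndarray | None
    raw_length: float | None
    suggested_length: float | None
    achieved_tjd: float | None
    status: str  # "ok" | "out_of_head" | "no_catalog_fit"


@dataclass(frozen=True)
class PlateOffset:
    """Signed head-center offset from the central screw trajectory (mm)."""

    dv: float
    cc: float

    @property
    def is_plausible(self) -> bool:
        return abs(self.dv) < 60.0 and abs(self.cc) < 60.0


def _plate_to_world(implant: ImplantGeometry, plate_pose: Pose | None) -> Pose:
    if plate_pose is None:
        plate_pose = Pose.identity()
    return pose_compose(plate_pose, implant.plate_to_marker())


def plan_screws(
    sphere: Sphere,
    implant: ImplantGeometry,
    plate_pose: Pose | None = None,
    target_tjd_mm: float = 5.0,
    rounding: str = "down",
    continuous: bool = False,
) -> list[ScrewPlan]:
    """Suggest a length for every screw in the implant definition.

    ``plate_pose`` is the marker->world pose (identity when working in the
    marker frame, the usual case).  With ``continuous=True`` the catalog is
    ignored and the raw length is suggested as-is, so the achieved TJD
    equals the target exactly — used for precision studies.  Failure modes
    are carried in ``status`` rather than raised: ``out_of_head`` when the
    trajectory misses (or merely grazes) the sphere, ``no_catalog_fit``
    when the raw length falls below the shortest catalog entry.
    """
    if target_tjd_mm < 0:
        raise ParamError("target_tjd_mm must be >= 0")
    if rounding not in ("down", "nearest"):
        raise ParamError("rounding must be 'down' or 'nearest'")
    pose = _plate_to_world(implant, plate_pose)
    plans = []
    for spec in implant.screws:
        traj = screw_trajectory(implant, spec.label, pose)
        pts = line_sphere_intersect(traj, sphere)
        if len(pts) < 2:
            plans.append(
                ScrewPlan(spec.label, traj, None, None, None, None, None, "out_of_head")
            )
            continue
        entry, exit_ = pts[0], pts[1]
        exit_dist = float((exit_ - traj.origin) @ traj.direction)
        raw = exit_dist - target_tjd_mm
        if continuous:
            suggested = raw
        else:
            catalog = np.asarray(spec.available_lengths)
            if rounding == "down":
                fitting = catalog[catalog <= raw]
                suggested = float(fitting[-1]) if len(fitting) else None
            else:
                suggested = float(catalog[np.argmin(np.abs(catalog - raw))])
            if suggested is None:
                plans.append(
                    ScrewPlan(
                        spec.label, traj, entry, exit_, raw, None, None, "no_catalog_fit"
                    )
                )
                continue
        achieved = exit_dist - suggested
        plans.append(
            ScrewPlan(
                label=spec.label,
                trajectory=traj,
                entry_point=entry,
                exit_point=exit_,
                raw_length=raw,
                suggested_length=suggested,
                achieved_tjd=achieved,
                status="ok",
            )
        )
    return plans


def achieved_tjd(plan: ScrewPlan) -> float:
    """Distance along the trajectory from the screw tip to the exit point."""
    if plan.status != "ok":
        raise InvalidStatus(f"screw {plan.label}: no achieved TJD in status {plan.status!r}")
    return float(plan.achieved_tjd)


def tjd_abs_error(tjd_mm: float, target_mm: float) -> float:
    """Absolute deviation of an achieved tip-joint distance from its target."""
    return float(np.abs(np.asarray(tjd_mm) - np.asarray(target_mm)))


def length_difference(before_mm, after_mm):
    """Absolute screw-length change between two measurements (symmetric)."""
    return np.abs(np.asarray(after_mm, dtype=float) - np.asarray(before_mm, dtype=float))[()]


def plate_offset(
    sphere: Sphere, implant: ImplantGeometry, plate_pose: Pose | None = None
) -> PlateOffset:
    """Head-center offset from the central screw trajectory.

    The rejection of the center from the central trajectory is decomposed
    along the plate's dorsal-ventral and cranial-caudal axes (mapped into
    the working frame); signs follow the plate convention (negative =
    ventral / caudal).
    """
    pose = _plate_to_world(implant, plate_pose)
    central = implant.central_screw
    traj = screw_trajectory(implant, central.label, pose)
    u = sphere.center - traj.origin
    v = u - (u @ traj.direction) * traj.direction
    dv_axis = pose.rotate(implant.plate_axes[0])
    cc_axis = pose.rotate(implant.plate_axes[1])
    return PlateOffset(dv=float(v @ dv_axis), cc=float(v @ cc_axis))


def offset_difference(pre: PlateOffset, post: PlateOffset) -> dict:
    """Componentwise absolute plate-position change between two stages."""
    return {
        "dv_diff": float(abs(post.dv - pre.dv)),
        "cc_diff": float(abs(post.cc - pre.cc)),
    }
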