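"""End-to-end orchestration: features -> poses -> validity -> sphere -> plan.

The pipeline refuses to plan on an invalid image pair (view angle at or
below the threshold) unless explicitly forced, since a narrow angular
spread cannot triangulate the head and would silently produce wrong screw
lengths.  Every stage logs its parameters and residuals for traceability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometry, InvalidPair, ParamError
from .geometry import CArmCamera, Pose, view_angle
from .implant import ImplantGeometry, MarkerGeometry
from .planning import PlateOffset, ScrewPlan, plan_screws, plate_offset
from .reconstruct import (
    PairValidity,
    PoseEstimate,
    SphereFit,
    cone_from_silhouette,
    estimate_marker_pose,
    fit_sphere_two_views,
    marker_frame_camera,
    refine_two_view,
    validate_pair,
)
from .simulate import FeatureSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Planning run parameters (clinical defaults)."""

    implant_definition: str | None = None
    target_tjd: float = 5.0
    view_angle_threshold: float = 15.0
    rounding: str = "down"
    continuous: bool = False
    seed: int = 0
    force: bool = False
    interactive: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.target_tjd < 0:
            raise ParamError("target_tjd must be >= 0")
        if self.view_angle_threshold <= 0:
            raise ParamError("view_angle_threshold must be > 0")
        if self.rounding not in ("down", "nearest"):
            raise ParamError("rounding must be 'down' or 'nearest'")


@dataclass(frozen=True)
class PlanResult:
    poses: tuple[PoseEstimate, PoseEstimate]
    validity: PairValidity
    angle_at_center_deg: float
    sphere_fit: SphereFit
    plans: list[ScrewPlan]
    offset: PlateOffset
    config: RunConfig
    warnings: list[str] = field(default_factory=list)


def run_plan(
    features: tuple[FeatureSet, FeatureSet],
    cameras: tuple[CArmCamera, CArmCamera],
    marker: MarkerGeometry,
    implant: ImplantGeometry,
    config: RunConfig | None = None,
    plate_pose: Pose | None = None,
) -> PlanResult:
    """Run the full planning chain on one image pair (feature path).

    ``cameras`` are the calibrated projective models the features were
    measured on (any frame; the marker pose relative to each is estimated).
    Raises :class:`InvalidPair` when the view angle does not strictly
    exceed the configured threshold and ``config.force`` is not set.
    """
    config = config or RunConfig()
    if plate_pose is None:
        plate_pose = Pose.identity()
    warnings_: list[str] = []

    poses = tuple(
        estimate_marker_pose(fs, marker, cam) for fs, cam in zip(features, cameras)
    )
    for fs, p in zip(features, poses):
        logger.info("pose %s: rms %.4f px over %d features", fs.image_id, p.rms_residual, p.n_features)

    cones = tuple(
        cone_from_silhouette(cam, fs.head_circle, pose)
        for fs, cam, pose in zip(features, cameras, poses)
    )
    try:
        sphere_fit = fit_sphere_two_views(*cones)
        anchor = sphere_fit.sphere.center
    except DegenerateGeometry:
        sphere_fit = None
        anchor = None  # near-parallel views: anchor at the marker origin

    # validity is anchored at the head-center estimate when one exists
    validity = validate_pair(
        poses[0], poses[1], cameras[0], cameras[1], config.view_angle_threshold, anchor
    )
    logger.info(
        "pair view angle %.2f deg (threshold %.1f): %s",
        validity.angle_deg,
        config.view_angle_threshold,
        "valid" if validity.valid else "INVALID",
    )
    if not validity.valid:
        if not config.force:
            raise InvalidPair(
                f"view angle {validity.angle_deg:.1f} deg does not exceed "
                f"{config.view_angle_threshold:.1f} deg; refusing to plan (use force to override)",
                angle_deg=validity.angle_deg,
            )
        warnings_.append(
            f"planned on an INVALID pair ({validity.angle_deg:.1f} deg <= "
            f"{config.view_angle_threshold:.1f} deg) by operator override"
        )
    if sphere_fit is None:
        raise DegenerateGeometry(
            "view directions too close to parallel to triangulate the head"
        )
    poses, sphere_fit = refine_two_view(features, cameras, marker, poses, sphere_fit)
    logger.info(
        "sphere: center %s mm, radius %.2f mm, residual %.4f mm",
        np.round(sphere_fit.sphere.center, 2),
        sphere_fit.sphere.radius,
        sphere_fit.residual,
    )
    if not sphere_fit.sphere.is_plausible_head:
        warnings_.append(
            f"fitted head radius {sphere_fit.sphere.radius:.1f} mm outside the plausible 10-40 mm range"
        )

    # final view angle re-anchored at the head-center estimate
    marker_cams = tuple(marker_frame_camera(c, p) for c, p in zip(cameras, poses))
    angle_at_center = view_angle(marker_cams[0], marker_cams[1], sphere_fit.sphere.center)

    plans = plan_screws(
        sphere_fit.sphere,
        implant,
        plate_pose,
        target_tjd_mm=config.target_tjd,
        rounding=config.rounding,
        continuous=config.continuous,
    )
    offset = plate_offset(sphere_fit.sphere, implant, plate_pose)
    if not offset.is_plausible:
        warnings_.append("plate offset beyond 60 mm plausibility bound")
    return PlanResult(
        poses=poses,
        validity=validity,
        angle_at_center_deg=angle_at_center,
        sphere_fit=sphere_fit,
        plans=plans,
        offset=offset,
        config=config,
        warnings=warnings_,
    )
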