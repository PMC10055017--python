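"""Precision studies on synthetic scenes.

These routines quantify, over many independently seeded scenes, how
feature noise propagates through the estimator chain: the spread of the
marker-pose rotation error and the spread of the screw-length
determination error (reconstructed sphere versus ground-truth sphere,
continuous catalog so rounding does not mask sub-increment errors).  The
same routines back both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import Pose, camera_frame
from .pipeline import PlanResult, RunConfig, run_plan
from .planning import achieved_tjd, plan_screws
from .reconstruct import (
    PoseEstimate,
    SphereFit,
    cone_from_silhouette,
    estimate_marker_pose,
    fit_sphere_two_views,
    refine_two_view,
)
from .simulate import Scene, make_scene, render_features


@dataclass(frozen=True)
class SceneReconstruction:
    scene: Scene
    pose_estimates: tuple[PoseEstimate, PoseEstimate]
    true_poses: tuple[Pose, Pose]
    sphere_fit: SphereFit


def reconstruct_scene(
    scene: Scene, noise_sigma_px: float, seed: int
) -> SceneReconstruction:
    """Render features for both exposures and run the estimator chain.

    Cameras are handed to the estimator in their canonical own frames, so
    the recovered marker poses are the full, nontrivial marker-to-camera
    transforms (ground truth available from the scene construction).
    """
    poses, truths, cones, feats, cams = [], [], [], [], []
    for i in (0, 1):
        fs = render_features(scene, i, noise_sigma_px=noise_sigma_px, seed=seed)
        canonical, world_to_cam = camera_frame(scene.cameras[i])
        est = estimate_marker_pose(fs, scene.marker, canonical)
        poses.append(est)
        truths.append(world_to_cam)
        feats.append(fs)
        cams.append(canonical)
        cones.append(cone_from_silhouette(canonical, fs.head_circle, est))
    fit = fit_sphere_two_views(*cones)
    poses, fit = refine_two_view(feats, cams, scene.marker, poses, fit)
    return SceneReconstruction(
        scene=scene,
        pose_estimates=(poses[0], poses[1]),
        true_poses=(truths[0], truths[1]),
        sphere_fit=fit,
    )


def precision_study(
    n_scenes: int = 100,
    noise_sigma_px: float = 0.5,
    seed: int = 0,
    view_angle_deg: float = 30.0,
    target_tjd_mm: float = 5.0,
) -> dict:
    """One pass over seeded scenes yielding both precision metrics.

    Returns per-exposure marker-rotation errors (degrees), per-scene
    sphere-center/radius errors (mm) and pooled per-screw raw-length
    errors (reconstructed vs ground-truth sphere, continuous catalog, mm).
    """
    rot_errors, center_errors, radius_errors, length_errors = [], [], [], []
    for i in range(n_scenes):
        s = seed * 1_000_003 + i
        scene = make_scene(view_angle_deg=view_angle_deg, seed=s)
        rec = reconstruct_scene(scene, noise_sigma_px, seed=s)
        rot_errors.extend(
            rotation_error_deg(e, t) for e, t in zip(rec.pose_estimates, rec.true_poses)
        )
        center_errors.append(
            float(np.linalg.norm(rec.sphere_fit.sphere.center - scene.sphere.center))
        )
        radius_errors.append(rec.sphere_fit.sphere.radius - scene.sphere.radius)
        plans_rec = plan_screws(
            rec.sphere_fit.sphere, scene.implant, scene.plate_pose,
            target_tjd_mm=target_tjd_mm, continuous=True,
        )
        plans_true = plan_screws(
            scene.sphere, scene.implant, scene.plate_pose,
            target_tjd_mm=target_tjd_mm, continuous=True,
        )
        for pr, pt in zip(plans_rec, plans_true):
            if pr.status == "ok" and pt.status == "ok":
                length_errors.append(pr.raw_length - pt.raw_length)
    return {
        "rotation_errors_deg": np.asarray(rot_errors),
        "sphere_center_errors_mm": np.asarray(center_errors),
        "sphere_radius_errors_mm": np.asarray(radius_errors),
        "screw_length_errors_mm": np.asarray(length_errors),
    }


def rotation_error_deg(estimate: PoseEstimate, truth: Pose) -> float:
    dR = Rotation.from_matrix(estimate.pose.rotation @ truth.rotation.T)
    return float(np.degrees(dR.magnitude()))


def pose_rotation_errors(
    n_scenes: int = 100,
    noise_sigma_px: float = 0.5,
    seed: int = 0,
    view_angle_deg: float = 30.0,
) -> np.ndarray:
    """Per-exposure marker-rotation errors (degrees) over seeded scenes."""
    errors = []
    for i in range(n_scenes):
        scene = make_scene(view_angle_deg=view_angle_deg, seed=seed * 1_000_003 + i)
        rec = reconstruct_scene(scene, noise_sigma_px, seed=seed * 1_000_003 + i)
        errors.extend(
            rotation_error_deg(e, t) for e, t in zip(rec.pose_estimates, rec.true_poses)
        )
    return np.asarray(errors)


def screw_length_errors(
    n_scenes: int = 100,
    noise_sigma_px: float = 0.5,
    seed: int = 0,
    view_angle_deg: float = 30.0,
    target_tjd_mm: float = 5.0,
) -> np.ndarray:
    """Pooled per-screw raw-length errors (mm), reconstruction vs truth.

    Lengths are planned with a continuous catalog on both the
    reconstructed and the ground-truth sphere; screws planning ``ok`` under
    both are pooled.
    """
    errors = []
    for i in range(n_scenes):
        s = seed * 1_000_003 + i
        scene = make_scene(view_angle_deg=view_angle_deg, seed=s)
        rec = reconstruct_scene(scene, noise_sigma_px, seed=s)
        plans_rec = plan_screws(
            rec.sphere_fit.sphere, scene.implant, scene.plate_pose,
            target_tjd_mm=target_tjd_mm, continuous=True,
        )
        plans_true = plan_screws(
            scene.sphere, scene.implant, scene.plate_pose,
            target_tjd_mm=target_tjd_mm, continuous=True,
        )
        for pr, pt in zip(plans_rec, plans_true):
            if pr.status == "ok" and pt.status == "ok":
                errors.append(pr.raw_length - pt.raw_length)
    return np.asarray(errors)


def zero_noise_plan(seed: int = 0, target_tjd_mm: float = 5.0) -> PlanResult:
    """Noise-free end-to-end run with a continuous catalog on one scene."""
    scene = make_scene(seed=seed)
    cams_truths = [camera_frame(c) for c in scene.cameras]
    features = tuple(render_features(scene, i, noise_sigma_px=0.0, seed=seed) for i in (0, 1))
    return run_plan(
        features,
        tuple(c for c, _ in cams_truths),
        scene.marker,
        scene.implant,
        RunConfig(target_tjd=target_tjd_mm, continuous=True, seed=seed),
        plate_pose=scene.plate_pose,
    )


def zero_noise_achieved_tjds(seed: int = 0, target_tjd_mm: float = 5.0) -> np.ndarray:
    """Achieved TJD of every ok screw in the noise-free continuous run."""
    result = zero_noise_plan(seed=seed, target_tjd_mm=target_tjd_mm)
    return np.asarray([achieved_tjd(p) for p in result.plans if p.status == "ok"])
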