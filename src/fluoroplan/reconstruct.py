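"""Two-view reconstruction: marker pose, silhouette cones, sphere fit.

The estimator chain recovers everything *in the marker frame* — the marker
is the only tracked reference, so the output is directly "head relative to
implant" without any external tracker:

1. :func:`estimate_marker_pose` — per image, nonlinear least squares on the
   reprojection error of the six model hole-opening centers against the
   observed 2D hole features (axis-angle + translation parameterization,
   multi-start to escape the classic two-fold circle-pose ambiguity; the
   asymmetric three-hole pattern makes the global minimum unique).
2. :func:`cone_from_silhouette` — per image, the tangent cone of the head:
   apex at the X-ray source expressed in the marker frame, axis through the
   silhouette-circle center, half-angle from the backprojected boundary.
3. :func:`fit_sphere_two_views` — the sphere (center, radius) whose two
   tangency constraints best match both cones, solved by least squares from
   a closed-form initialization on the common perpendicular of the axes.
4. :func:`validate_pair` / :func:`select_best_pair` — the view-angle
   validity rule: a pair is usable only if the angular separation of the
   two viewpoints strictly exceeds the threshold (default 15 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    AmbiguousPose,
    DegenerateGeometry,
    GeometryError,
    InsufficientFeatures,
    NoConvergence,
    NoValidPair,
)
from .features import CircleCandidate
from .geometry import (
    CArmCamera,
    Line3,
    Pose,
    Sphere,
    backproject_ray,
    pose_invert,
    project_circle_centers,
    project_points,
    transform_camera,
    view_angle,
)
from .implant import MarkerGeometry
from .simulate import FeatureSet


@dataclass(frozen=True)
class PoseEstimate:
    """Marker pose relative to the frame the camera was expressed in."""

    pose: Pose
    rms_residual: float
    n_features: int


@dataclass(frozen=True)
class Cone:
    """Right-circular viewing cone in the marker frame."""

    apex: np.ndarray
    axis: np.ndarray
    half_angle: float

    def __post_init__(self):
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise GeometryError("cone axis must be nonzero")
        object.__setattr__(self, "axis", ax / n)
        ha = float(self.half_angle)
        if not (0.0 < ha < np.pi / 2):
            raise GeometryError("cone half-angle must be in (0, pi/2)")
        object.__setattr__(self, "half_angle", ha)


@dataclass(frozen=True)
class SphereFit:
    """Best sphere plus ranked alternative local minima (residuals in mm)."""

    sphere: Sphere
    residual: float
    candidates: tuple[tuple[Sphere, float], ...] = ()


@dataclass(frozen=True)
class PairValidity:
    valid: bool
    angle_deg: float


# --------------------------------------------------------------------------
# marker pose


def _model_and_observed(features: FeatureSet, marker: MarkerGeometry):
    """Collect model landmarks and their 2D observations.

    Two observation channels per opening: the projected opening center
    (matched to the exact point projection) and, when opening ellipses are
    supplied, the fitted ellipse center (matched to the exact center of the
    projected conic — an independently measured, hence noise-averaging,
    observation of nearly the same quantity).
    """
    if len(features.hole_features) < 3:
        raise InsufficientFeatures(
            f"pose estimation needs 3 hole features, got {len(features.hole_features)}"
        )
    model, obs, circles, ell_obs = [], [], [], []
    for hf in features.hole_features:
        try:
            hole = marker.hole(hf.hole_id)
        except KeyError as exc:
            raise InsufficientFeatures(f"feature hole id {hf.hole_id!r} not in marker") from exc
        entry3, exit3 = hole.opening_centers()
        for p3, p2, ell in (
            (entry3, hf.entry, hf.entry_ellipse),
            (exit3, hf.exit, hf.exit_ellipse),
        ):
            if p2 is None:
                raise InsufficientFeatures(f"hole {hf.hole_id} is missing an opening center")
            model.append(p3)
            obs.append(np.asarray(p2, dtype=float))
            if ell is not None:
                circles.append((p3, hole.axis, hole.radius))
                ell_obs.append(np.asarray(ell.center, dtype=float))
    circle_model = (
        (
            np.stack([c[0] for c in circles]),
            np.stack([c[1] for c in circles]),
            np.array([c[2] for c in circles]),
        )
        if circles
        else None
    )
    ell_obs_arr = np.stack(ell_obs) if ell_obs else None
    return np.stack(model), np.stack(obs), circle_model, ell_obs_arr


def _initial_starts(model: np.ndarray, obs: np.ndarray, cam: CArmCamera) -> list[np.ndarray]:
    """Multi-start seeds: scale-based depth plus 8 canonical orientations.

    The marker roughly faces the beam, but which face and with what in-plane
    spin is unknown a priori; circle-pose problems additionally have a
    two-fold flip ambiguity.  Starting from both facings x four in-plane
    spins reliably brackets the global minimum.
    """
    w = cam.normal
    # depth from perspective scale: magnification = SDD / depth
    pair_3d = np.array([np.linalg.norm(a - b) for a, b in combinations(model, 2)])
    obs_mm = obs * cam.pixel_spacing
    pair_2d = np.array([np.linalg.norm(a - b) for a, b in combinations(obs_mm, 2)])
    mag = np.median(pair_2d / np.maximum(pair_3d, 1e-9))
    depth = cam.source_detector_distance / max(mag, 1e-6)
    centroid_ray = backproject_ray(cam, obs.mean(axis=0))
    centroid_w = centroid_ray.point(depth / max(centroid_ray.direction @ w, 1e-6))

    model_centroid = model.mean(axis=0)
    starts = []
    base_u = np.cross(w, [0.0, 1.0, 0.0])
    if np.linalg.norm(base_u) < 1e-6:
        base_u = np.cross(w, [1.0, 0.0, 0.0])
    base_u = base_u / np.linalg.norm(base_u)
    base_v = np.cross(w, base_u)
    for facing in (1.0, -1.0):
        ez = facing * w
        R_align = np.column_stack([base_u, np.cross(ez, base_u), ez])
        for k in range(4):
            R_spin = Rotation.from_rotvec(w * (np.pi / 2) * k).as_matrix()
            R0 = R_spin @ R_align
            t0 = centroid_w - R0 @ model_centroid
            starts.append(np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0]))
    return starts


def estimate_marker_pose(
    features: FeatureSet, marker: MarkerGeometry, cam: CArmCamera
) -> PoseEstimate:
    """Marker pose from the six observed hole-opening centers.

    Minimizes the pixel reprojection error of the model opening points
    (from the marker definition) against the observed entry/exit centers,
    over axis-angle rotation + translation, with multi-start
    initialization.  With exact (zero-noise) features the residual reaches
    numerical zero and the pose matches ground truth to ~1e-7 rad.

    Raises :class:`AmbiguousPose` when two starts converge to residuals
    within 0.1 px of each other while the poses differ by more than 1
    degree (both poses attached), and :class:`InsufficientFeatures` when
    fewer than three complete hole features are supplied.
    """
    model, obs, circle_model, ell_obs = _model_and_observed(features, marker)

    def residual_points(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        pts = model @ R.T + x[3:]
        return (project_points(cam, pts) - obs).ravel()

    def residual_full(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        pts = model @ R.T + x[3:]
        parts = [(project_points(cam, pts) - obs).ravel()]
        if circle_model is not None:
            centers3, axes3, radii = circle_model
            pred = project_circle_centers(cam, centers3 @ R.T + x[3:], axes3 @ R.T, radii)
            parts.append((pred - ell_obs).ravel())
        return np.concatenate(parts)

    # phase 1: point-only solves from every start to locate the basins
    # (tight tolerances so runs landing in one basin coincide exactly)
    solutions = []
    for x0 in _initial_starts(model, obs, cam):
        try:
            res = least_squares(
                residual_points, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rms = float(np.sqrt(np.mean(res.fun**2)))
        solutions.append((rms, res.x))
    if not solutions:
        raise NoConvergence("no pose start converged")
    solutions.sort(key=lambda s: s[0])

    def to_pose(x) -> Pose:
        return Pose(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])

    best_rms, best_x = solutions[0]
    best_pose = to_pose(best_x)
    # ambiguity: a *distinct* basin whose point-model residual ties the winner.
    # A tie candidate is first polished to full convergence, since a start
    # that merely stalled on its way into the winning basin is not a second
    # solution.
    for rms, x in solutions[1:]:
        if rms - best_rms > 0.1:
            break
        try:
            rep = least_squares(
                residual_points, x, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000
            )
            if np.all(np.isfinite(rep.x)):
                rms, x = float(np.sqrt(np.mean(rep.fun**2))), rep.x
        except Exception:
            pass
        if rms - best_rms > 0.1:
            continue
        other = to_pose(x)
        dR = Rotation.from_matrix(other.rotation @ best_pose.rotation.T)
        sep = float(np.degrees(dR.magnitude()))
        if sep > 1.0:
            raise AmbiguousPose(
                f"two pose minima within 0.1 px (rms {best_rms:.3g} / {rms:.3g} px) "
                f"differ by {sep:.2f} deg",
                candidates=[
                    PoseEstimate(best_pose, best_rms, len(obs)),
                    PoseEstimate(other, rms, len(obs)),
                ],
            )

    # phase 2: polish the winner on the full observation model
    rms_out, pose_out = best_rms, best_pose
    try:
        polished = least_squares(
            residual_full, best_x, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400
        )
        if np.all(np.isfinite(polished.x)):
            rms_out = float(np.sqrt(np.mean(polished.fun**2)))
            pose_out = to_pose(polished.x)
    except Exception:
        pass
    return PoseEstimate(pose=pose_out, rms_residual=rms_out, n_features=len(obs))


# --------------------------------------------------------------------------
# silhouette cone


def cone_from_silhouette(
    cam: CArmCamera, circle: CircleCandidate, marker_pose: PoseEstimate | Pose
) -> Cone:
    """Tangent cone of the head, expressed in the marker frame.

    The rays from the source through the silhouette circle form the viewing
    cone of the head.  Its right-circular axis and half-angle are solved
    linearly from backprojected boundary directions d_i via d_i . w = 1
    (axis = w/|w|, cos half-angle = 1/|w|), which is exact for a circular
    cone and least-squares otherwise.  The result is mapped into the marker
    frame through the inverse of the estimated marker pose.
    """
    pose = marker_pose.pose if isinstance(marker_pose, PoseEstimate) else marker_pose
    if circle.radius <= 1e-9:
        raise GeometryError("silhouette circle radius must be positive")
    phi = np.linspace(0.0, 2 * np.pi, 36, endpoint=False)
    boundary = circle.center + circle.radius * np.stack([np.cos(phi), np.sin(phi)], axis=-1)
    dirs = np.stack([backproject_ray(cam, b).direction for b in boundary])
    w, *_ = np.linalg.lstsq(dirs, np.ones(len(dirs)), rcond=None)
    nw = np.linalg.norm(w)
    if nw < 1e-12 or 1.0 / nw >= 1.0:
        raise DegenerateGeometry("silhouette boundary does not span a cone")
    axis_cam = w / nw
    half = float(np.arccos(np.clip(1.0 / nw, -1.0, 1.0)))
    if axis_cam @ cam.normal < 0:
        axis_cam = -axis_cam
    cam_to_marker = pose_invert(pose)
    return Cone(
        apex=cam_to_marker.apply(cam.source),
        axis=cam_to_marker.rotate(axis_cam),
        half_angle=half,
    )


# --------------------------------------------------------------------------
# two-view sphere fit


def _common_perpendicular_midpoint(l1: Line3, l2: Line3) -> np.ndarray:
    d1, d2 = l1.direction, l2.direction
    r = l1.origin - l2.origin
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    d, e = d1 @ r, d2 @ r
    den = a * c - b * b
    if abs(den) < 1e-12:
        raise DegenerateGeometry("cone axes are parallel")
    t1 = (b * e - c * d) / den
    t2 = (a * e - b * d) / den
    return 0.5 * (l1.point(t1) + l2.point(t2))


def fit_sphere_two_views(cone_a: Cone, cone_b: Cone) -> SphereFit:
    """Sphere (center, radius) tangent to both viewing cones.

    Per cone two residuals are minimized: the angular off-axis deviation of
    the center (scaled by the apex distance, so it is commensurate in mm
    with the second term) and the tangency defect
    ``sin(half_angle) * |center - apex| - radius``.  Initialization is the
    midpoint of the common perpendicular of the two axes, with radius from
    the mean tangency relation; alternative starts are reported as ranked
    candidates.  Raises :class:`DegenerateGeometry` for near-parallel axes
    (below 1 degree) and :class:`NoConvergence` for a non-physical result.
    """
    axis_angle = np.degrees(
        np.arctan2(np.linalg.norm(np.cross(cone_a.axis, cone_b.axis)), cone_a.axis @ cone_b.axis)
    )
    if axis_angle < 1.0:
        raise DegenerateGeometry(
            f"cone axes nearly parallel ({axis_angle:.2f} deg): pair cannot triangulate"
        )
    la = Line3(cone_a.apex, cone_a.axis)
    lb = Line3(cone_b.apex, cone_b.axis)
    m = _common_perpendicular_midpoint(la, lb)
    r0 = float(
        np.mean(
            [
                np.sin(c.half_angle) * np.linalg.norm(m - c.apex)
                for c in (cone_a, cone_b)
            ]
        )
    )

    # per cone: off-axis deviation resolved into two perpendicular components
    # (mm at the center distance, so it is commensurate with the tangency
    # defect) plus the tangency defect itself -> 6 equations, 4 unknowns
    basis = []
    for cone in (cone_a, cone_b):
        p = np.cross(cone.axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(cone.axis, [0.0, 1.0, 0.0])
        p = p / np.linalg.norm(p)
        basis.append((p, np.cross(cone.axis, p)))

    def residual(x):
        c, r = x[:3], x[3]
        out = []
        for cone, (p, q) in zip((cone_a, cone_b), basis):
            u = c - cone.apex
            dist = np.linalg.norm(u)
            if dist < 1e-9:
                out.extend([1e6, 1e6, 1e6])
                continue
            out.append(u @ p)
            out.append(u @ q)
            out.append(np.sin(cone.half_angle) * dist - r)
        return np.array(out)

    minima: list[tuple[float, np.ndarray]] = []
    for scale in (1.0, 0.7, 1.3):
        x0 = np.concatenate([m, [max(r0 * scale, 1.0)]])
        try:
            res = least_squares(residual, x0, method="lm", xtol=1e-15, ftol=1e-15)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)) or res.x[3] <= 0:
            continue
        minima.append((float(np.sqrt(np.mean(res.fun**2))), res.x))
    if not minima:
        raise NoConvergence("sphere fit did not converge to a physical solution")
    # deduplicate coincident minima
    minima.sort(key=lambda s: s[0])
    distinct: list[tuple[float, np.ndarray]] = []
    for rms, x in minima:
        if any(np.linalg.norm(x[:3] - d[1][:3]) < 1e-6 for d in distinct):
            continue
        distinct.append((rms, x))
    candidates = tuple((Sphere(x[:3], x[3]), rms) for rms, x in distinct)
    best_sphere, best_rms = candidates[0]
    return SphereFit(sphere=best_sphere, residual=best_rms, candidates=candidates)


# --------------------------------------------------------------------------
# joint two-view refinement


def _cone_residual_mm(sphere: Sphere, cones) -> float:
    out = []
    for cone in cones:
        u = sphere.center - cone.apex
        dist = np.linalg.norm(u)
        lat = u - (u @ cone.axis) * cone.axis
        out.extend(lat)
        out.append(np.sin(cone.half_angle) * dist - sphere.radius)
    return float(np.sqrt(np.mean(np.square(out))))


def refine_two_view(
    features,
    cameras,
    marker: MarkerGeometry,
    pose_estimates,
    sphere_fit: SphereFit,
) -> tuple[tuple[PoseEstimate, PoseEstimate], SphereFit]:
    """Joint refinement of both marker poses and the sphere (bundle step).

    The two-stage chain (pose per image, then sphere from fixed poses) is
    statistically suboptimal: the head-silhouette observations also carry
    information about the poses through the shared 3D sphere.  This step
    minimizes *all* pixel residuals of both exposures — hole-opening
    centers, opening-ellipse centers and the silhouette circle (center and
    radius) — over the 16 joint parameters (2 x axis-angle pose + sphere
    center + radius), starting from the two-stage estimates.  With exact
    features the start is already the global zero-residual optimum and is
    returned unchanged.
    """
    from .simulate import silhouette_circle  # deferred: simulate imports features only

    per_view = [_model_and_observed(fs, marker) for fs in features]
    circ_obs = [
        np.concatenate([fs.head_circle.center, [fs.head_circle.radius]]) for fs in features
    ]

    x0 = np.concatenate(
        [
            np.concatenate(
                [Rotation.from_matrix(p.pose.rotation).as_rotvec(), p.pose.translation]
            )
            for p in pose_estimates
        ]
        + [sphere_fit.sphere.center, [sphere_fit.sphere.radius]]
    )

    def residual(x):
        parts = []
        c_m, r_s = x[12:15], x[15]
        if r_s <= 0:
            return np.full(6 * len(features) + 30, 1e6)
        for k, cam in enumerate(cameras):
            model, obs, circle_model, ell_obs = per_view[k]
            xk = x[6 * k : 6 * k + 6]
            R = Rotation.from_rotvec(xk[:3]).as_matrix()
            t = xk[3:]
            pts = model @ R.T + t
            parts.append((project_points(cam, pts) - obs).ravel())
            if circle_model is not None:
                centers3, axes3, radii = circle_model
                pred = project_circle_centers(cam, centers3 @ R.T + t, axes3 @ R.T, radii)
                parts.append((pred - ell_obs).ravel())
            try:
                circ = silhouette_circle(cam, Sphere(R @ c_m + t, r_s))
                pred_c = np.concatenate([circ.center, [circ.radius]])
            except Exception:
                pred_c = np.full(3, 1e6)
            parts.append(pred_c - circ_obs[k])
        return np.concatenate(parts)

    try:
        res = least_squares(residual, x0, method="lm", max_nfev=600)
    except Exception:
        return tuple(pose_estimates), sphere_fit
    if not np.all(np.isfinite(res.x)) or res.x[15] <= 0:
        return tuple(pose_estimates), sphere_fit

    new_poses = []
    for k, old in enumerate(pose_estimates):
        xk = res.x[6 * k : 6 * k + 6]
        pose = Pose(Rotation.from_rotvec(xk[:3]).as_matrix(), xk[3:])
        # per-view pixel rms over that view's hole observations
        model, obs, circle_model, ell_obs = per_view[k]
        pts = model @ pose.rotation.T + pose.translation
        r = [(project_points(cameras[k], pts) - obs).ravel()]
        if circle_model is not None:
            centers3, axes3, radii = circle_model
            r.append(
                (
                    project_circle_centers(
                        cameras[k],
                        centers3 @ pose.rotation.T + pose.translation,
                        axes3 @ pose.rotation.T,
                        radii,
                    )
                    - ell_obs
                ).ravel()
            )
        rms = float(np.sqrt(np.mean(np.concatenate(r) ** 2)))
        new_poses.append(PoseEstimate(pose=pose, rms_residual=rms, n_features=old.n_features))

    sphere = Sphere(res.x[12:15], float(res.x[15]))
    cones = tuple(
        cone_from_silhouette(cam, fs.head_circle, p)
        for cam, fs, p in zip(cameras, features, new_poses)
    )
    # alternative two-stage minima were already adjudicated before the joint
    # step; the refined solution supersedes them as the single candidate
    res_mm = _cone_residual_mm(sphere, cones)
    fit = SphereFit(sphere=sphere, residual=res_mm, candidates=((sphere, res_mm),))
    return (new_poses[0], new_poses[1]), fit


# --------------------------------------------------------------------------
# pair validity


def marker_frame_camera(cam: CArmCamera, pose: PoseEstimate | Pose) -> CArmCamera:
    """Express a camera in the marker frame via the estimated marker pose."""
    p = pose.pose if isinstance(pose, PoseEstimate) else pose
    return transform_camera(cam, pose_invert(p))


def validate_pair(
    pose_a: PoseEstimate | Pose,
    pose_b: PoseEstimate | Pose,
    cam_a: CArmCamera,
    cam_b: CArmCamera,
    threshold_deg: float = 15.0,
    reference=None,
) -> PairValidity:
    """View-angle validity of an image pair.

    The angle is measured in the marker frame between the two source
    directions seen from ``reference`` (the sphere-center estimate when
    available, else the marker origin).  A pair is valid only when the
    angle *strictly* exceeds the threshold — too narrow a spread cannot
    triangulate the head.
    """
    ma = marker_frame_camera(cam_a, pose_a)
    mb = marker_frame_camera(cam_b, pose_b)
    ref = np.zeros(3) if reference is None else np.asarray(reference, dtype=float)
    ang = view_angle(ma, mb, ref)
    return PairValidity(valid=bool(ang > threshold_deg), angle_deg=ang)


def select_best_pair(
    images: list[tuple[str, PoseEstimate | Pose, CArmCamera]],
    threshold_deg: float = 15.0,
    reference=None,
) -> tuple[str, str, PairValidity]:
    """Pick the valid pair with the largest view angle.

    ``images`` is a list of (image_id, pose, camera).  Ties break
    deterministically toward the lexicographically earlier image-id pair.
    Raises :class:`NoValidPair` when every pairwise angle is at or below
    the threshold (the clinical failure mode of a too-narrow spread).
    """
    if len(images) < 2:
        raise NoValidPair("need at least two images to form a pair")
    best: tuple[str, str, PairValidity] | None = None
    for (ida, pa, ca), (idb, pb, cb) in combinations(sorted(images, key=lambda im: im[0]), 2):
        v = validate_pair(pa, pb, ca, cb, threshold_deg, reference)
        if v.valid and (best is None or v.angle_deg > best[2].angle_deg):
            best = (ida, idb, v)
    if best is None:
        raise NoValidPair(f"no image pair exceeds {threshold_deg} deg")
    return best
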