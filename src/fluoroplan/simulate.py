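"""Synthetic C-arm scene generator with ground truth.

Stands in for cadaver and clinical imaging: a spherical humeral head, the
three-hole marker rigidly related to the plate, and two point-source
cameras separated by a configurable view angle (protocol default 30
degrees), both aimed at the head center as an operator would center the
anatomy.  Features (projected hole-opening centers, opening ellipses, head
silhouette circle) are rendered exactly and optionally perturbed with
i.i.d. Gaussian noise; an anti-aliased raster path feeds the image-based
extraction module.

Geometry defaults model a typical mobile C-arm: 1000 mm source-detector
distance, 600 mm source-object distance, 0.4 mm detector pixels on a
512x512 field.  The marker is viewed ~20 degrees obliquely so the
cylindrical holes project as distinct lens shapes, which is the operating
point of hole-projection tracking.  All randomness flows from explicit
integer seeds through independent substreams, so (params, seed) fully
determine every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BehindSource, ParamError
from .features import CircleCandidate, Ellipse, fit_circle, fit_ellipse
from .geometry import CArmCamera, Pose, Sphere, project_points, view_angle
from .implant import ImplantGeometry, MarkerGeometry, bundled_implant

_DEFAULT_SPHERE_RADIUS_RANGE = (20.0, 28.0)  # adult humeral head, mm
_NOMINAL_CENTER_PLATE = np.array([0.5, 1.0, 24.0])  # mm, plate frame


@dataclass(frozen=True)
class HoleFeature:
    """Per-hole 2D evidence: projected opening centers and opening ellipses."""

    hole_id: str
    entry: np.ndarray
    exit: np.ndarray
    entry_ellipse: Ellipse
    exit_ellipse: Ellipse


@dataclass(frozen=True)
class FeatureSet:
    """All 2D features of one exposure (pixel coordinates)."""

    image_id: str
    hole_features: tuple[HoleFeature, ...]
    head_circle: CircleCandidate
    noise_sigma: float = 0.0

    def __post_init__(self):
        if len(self.hole_features) != 3:
            raise ParamError("a FeatureSet carries exactly 3 hole features")
        if self.head_circle.radius <= 0:
            raise ParamError("head circle radius must be positive")


@dataclass(frozen=True)
class Scene:
    """Ground-truth synthetic scene.

    The marker frame is the world frame (``plate_pose`` is the identity by
    convention); cameras are posed in it.
    """

    marker: MarkerGeometry | None
    implant: ImplantGeometry | None
    plate_pose: Pose
    sphere: Sphere | None
    cameras: tuple[CArmCamera, CArmCamera]
    seed: int
    params: dict

    @property
    def view_angle_deg(self) -> float:
        """View angle of the camera pair at the scene anchor."""
        ref = self.sphere.center if self.sphere is not None else np.zeros(3)
        return view_angle(self.cameras[0], self.cameras[1], ref)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _make_camera(
    aim: np.ndarray,
    direction: np.ndarray,
    source_object: float,
    source_detector: float,
    pixel_spacing: float,
    image_size: tuple[int, int],
    roll_rad: float,
) -> CArmCamera:
    w = direction / np.linalg.norm(direction)
    source = aim - source_object * w
    det_center = source + source_detector * w
    u0 = np.cross([0.0, 1.0, 0.0], w)
    if np.linalg.norm(u0) < 1e-6:
        u0 = np.cross([1.0, 0.0, 0.0], w)
    u0 = u0 / np.linalg.norm(u0)
    v0 = np.cross(w, u0)
    u = _rotate_about(u0, w, roll_rad)
    v = _rotate_about(v0, w, roll_rad)
    rows, cols = image_size
    origin = det_center - (cols - 1) / 2 * pixel_spacing * u - (rows - 1) / 2 * pixel_spacing * v
    return CArmCamera(
        source=source,
        detector_origin=origin,
        detector_u=u,
        detector_v=v,
        pixel_spacing=pixel_spacing,
        image_size=image_size,
    )


def make_scene(
    view_angle_deg: float = 30.0,
    source_detector_mm: float = 1000.0,
    source_object_mm: float = 600.0,
    pixel_spacing: float = 0.4,
    image_size: tuple[int, int] = (512, 512),
    sphere_center=None,
    sphere_radius: float | None = None,
    marker_tilt_deg: float = 20.0,
    center_jitter_mm: float = 3.0,
    seed: int = 0,
    marker: MarkerGeometry | None = None,
    implant: ImplantGeometry | None = None,
) -> Scene:
    """Build a deterministic ground-truth scene.

    The two cameras are symmetric about the anteroposterior viewing
    direction, separated by ``view_angle_deg`` measured at the sphere
    center, and both aimed at it.  ``marker_tilt_deg`` cants the whole rig
    about the marker x-axis so the beam meets the hole axes obliquely.
    ``sphere_radius`` defaults to a uniform draw from 20-28 mm; the center
    defaults to the anatomical position medial of the plate's central hole,
    jittered by +-``center_jitter_mm`` per axis.
    """
    if view_angle_deg <= 0:
        raise ParamError("view_angle_deg must be > 0")
    if min(source_detector_mm, source_object_mm, pixel_spacing) <= 0:
        raise ParamError("distances and pixel spacing must be > 0")
    if source_object_mm >= source_detector_mm:
        raise ParamError("source_object_mm must be smaller than source_detector_mm")
    if marker is None or implant is None:
        default_marker, default_implant = bundled_implant()
        marker = marker if marker is not None else default_marker
        implant = implant if implant is not None else default_implant

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    lo, hi = _DEFAULT_SPHERE_RADIUS_RANGE
    radius = float(rng.uniform(lo, hi)) if sphere_radius is None else float(sphere_radius)
    if radius <= 0:
        raise ParamError("sphere_radius must be > 0")
    if sphere_center is None:
        c_plate = _NOMINAL_CENTER_PLATE + rng.uniform(-center_jitter_mm, center_jitter_mm, 3)
        center = implant.plate_to_marker().apply(c_plate)
    else:
        center = np.asarray(sphere_center, dtype=float)
    if np.linalg.norm(center) > 60.0:
        raise ParamError(
            "sphere center farther than 60 mm from the marker origin is anatomically implausible"
        )
    sphere = Sphere(center=center, radius=radius)

    tilt = np.deg2rad(marker_tilt_deg)
    w_ap = np.array([0.0, -np.sin(tilt), np.cos(tilt)])  # anteroposterior beam direction
    swing_axis = np.array([0.0, np.cos(tilt), np.sin(tilt)])  # perpendicular to w_ap
    half = np.deg2rad(view_angle_deg) / 2.0
    rolls = rng.uniform(-np.deg2rad(10.0), np.deg2rad(10.0), size=2)
    cams = tuple(
        _make_camera(
            aim=sphere.center,
            direction=_rotate_about(w_ap, swing_axis, sgn * half),
            source_object=source_object_mm,
            source_detector=source_detector_mm,
            pixel_spacing=pixel_spacing,
            image_size=image_size,
            roll_rad=float(roll),
        )
        for sgn, roll in zip((-1.0, 1.0), rolls)
    )
    params = {
        "view_angle_deg": view_angle_deg,
        "source_detector_mm": source_detector_mm,
        "source_object_mm": source_object_mm,
        "pixel_spacing": pixel_spacing,
        "image_size": list(image_size),
        "sphere_radius": radius,
        "sphere_center": center.tolist(),
        "marker_tilt_deg": marker_tilt_deg,
        "center_jitter_mm": center_jitter_mm,
    }
    return Scene(
        marker=marker,
        implant=implant,
        plate_pose=Pose.identity(),
        sphere=sphere,
        cameras=cams,
        seed=int(seed),
        params=params,
    )


# --------------------------------------------------------------------------
# feature rendering


def _check_in_front(cam: CArmCamera, points: np.ndarray, what: str) -> None:
    n = cam.normal
    if np.any((np.atleast_2d(points) - cam.source) @ n <= 0):
        raise BehindSource(f"{what} is not in front of the detector")


def _project_circle_3d(
    cam: CArmCamera, center: np.ndarray, axis: np.ndarray, radius: float, n: int = 72
) -> Ellipse:
    """Exact conic projection of a 3D circle, returned as a fitted ellipse.

    The central projection of a circle is an exact conic, so a conic fit
    through projected boundary samples reproduces it to machine precision.
    """
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts3 = center + radius * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
    _check_in_front(cam, pts3, "hole opening")
    return fit_ellipse(project_points(cam, pts3))


def silhouette_circle(cam: CArmCamera, sphere: Sphere, n: int = 72) -> CircleCandidate:
    """Best-fit circle to the exact sphere-silhouette conic.

    The silhouette of a sphere under point-source projection is the trace
    of the tangent cone on the detector: an ellipse in general, an exact
    circle when the camera is aimed at the sphere center.  The pipeline
    consumes circles (mirroring circle-based head segmentation), so the
    least-squares circle through exact silhouette samples is emitted; any
    residual eccentricity is absorbed as model error.
    """
    s = cam.source
    d = sphere.center - s
    dist = np.linalg.norm(d)
    if dist <= sphere.radius:
        raise BehindSource("source lies inside the head sphere")
    a = d / dist
    _check_in_front(cam, sphere.center, "head sphere")
    alpha = np.arcsin(sphere.radius / dist)
    p1 = np.cross(a, [1.0, 0.0, 0.0])
    if np.linalg.norm(p1) < 1e-6:
        p1 = np.cross(a, [0.0, 1.0, 0.0])
    p1 = p1 / np.linalg.norm(p1)
    p2 = np.cross(a, p1)
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    gens = np.cos(alpha) * a + np.sin(alpha) * (
        np.outer(np.cos(phi), p1) + np.outer(np.sin(phi), p2)
    )
    nrm = cam.normal
    if np.any(gens @ nrm <= 0):
        raise BehindSource("part of the head silhouette falls behind the source")
    pix = project_points(cam, s + gens)
    return fit_circle(pix)


def render_features(
    scene: Scene, camera_index: int, noise_sigma_px: float = 0.0, seed: int = 0
) -> FeatureSet:
    """Exact 2D features of one exposure, plus optional Gaussian noise.

    At ``noise_sigma_px = 0`` the opening centers equal the exact central
    projections of the 3D opening-circle centers, and ellipse/circle
    parameters are exact conic projections.  Noise is i.i.d. N(0, sigma)
    added to every emitted coordinate, semi-axis and radius (ellipse tilt
    is left untouched), drawn from a substream keyed by (seed,
    camera_index) so the two exposures are independently perturbed.
    """
    if scene.marker is None or scene.sphere is None:
        raise ParamError("render_features requires a scene with marker and sphere")
    cam = scene.cameras[camera_index]
    return _render_features_for_cam(scene, cam, camera_index, noise_sigma_px, seed)


def _render_features_for_cam(
    scene: Scene, cam: CArmCamera, camera_index: int, noise_sigma_px: float, seed: int
) -> FeatureSet:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, int(camera_index)]))
    sigma = float(noise_sigma_px)

    def jitter(x, n):
        return np.asarray(x, dtype=float) + (rng.normal(0.0, sigma, n) if sigma > 0 else 0.0)

    def jitter_scalar(x) -> float:
        return float(x) + (float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0)

    def jitter_ellipse(e: Ellipse) -> Ellipse:
        if sigma == 0:
            return e
        c = jitter(e.center, 2)
        a = max(jitter_scalar(e.a), 1e-3)
        b = max(jitter_scalar(e.b), 1e-3)
        if b > a:
            a, b = b, a
        return Ellipse(center=c, a=a, b=b, theta=e.theta, rms=e.rms)

    holes = []
    for h in scene.marker.holes:
        entry3, exit3 = h.opening_centers()
        _check_in_front(cam, np.stack([entry3, exit3]), f"hole {h.hole_id}")
        entry_px, exit_px = project_points(cam, np.stack([entry3, exit3]))
        e_entry = _project_circle_3d(cam, entry3, h.axis, h.radius)
        e_exit = _project_circle_3d(cam, exit3, h.axis, h.radius)
        holes.append(
            HoleFeature(
                hole_id=h.hole_id,
                entry=jitter(entry_px, 2),
                exit=jitter(exit_px, 2),
                entry_ellipse=jitter_ellipse(e_entry),
                exit_ellipse=jitter_ellipse(e_exit),
            )
        )
    circ = silhouette_circle(cam, scene.sphere)
    head = CircleCandidate(
        center=jitter(circ.center, 2),
        radius=max(jitter_scalar(circ.radius), 1e-3),
        score=1.0,
    )
    return FeatureSet(
        image_id=f"cam{camera_index}",
        hole_features=tuple(holes),
        head_circle=head,
        noise_sigma=sigma,
    )


# --------------------------------------------------------------------------
# raster rendering


def _ellipse_coverage(xx: np.ndarray, yy: np.ndarray, e: Ellipse) -> np.ndarray:
    """Approximate anti-aliased inside-coverage of an ellipse on a pixel grid."""
    ct, st = np.cos(e.theta), np.sin(e.theta)
    dx = xx - e.center[0]
    dy = yy - e.center[1]
    xr = (ct * dx + st * dy) / e.a
    yr = (-st * dx + ct * dy) / e.b
    rho = np.sqrt(xr**2 + yr**2)
    dist = (rho - 1.0) * min(e.a, e.b)  # approximate signed distance in px
    return np.clip(0.5 - dist, 0.0, 1.0)


def render_image(
    scene: Scene,
    camera_index: int,
    size: tuple[int, int] | None = None,
    intensity_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, FeatureSet | None]:
    """Anti-aliased grayscale raster of one exposure, plus ground truth.

    The head silhouette renders as a dark disk and each hole as the dark
    union of its two projected opening ellipses (their overlap - the lens -
    attenuates twice and reads darker).  Returns the image in [0, 1]
    together with the exact zero-noise :class:`FeatureSet` at the raster
    pixel scale, or None when the scene has no marker or sphere.
    ``intensity_noise`` adds white grayscale noise (same units as the
    image).  Identical inputs yield identical rasters.
    """
    cam = scene.cameras[camera_index]
    if size is not None and tuple(size) != cam.image_size:
        fr = cam.image_size[0] / size[0]
        fc = cam.image_size[1] / size[1]
        if abs(fr - fc) > 1e-9:
            raise ParamError("render size must preserve the detector aspect ratio")
        cam = CArmCamera(
            source=cam.source,
            detector_origin=cam.detector_origin,
            detector_u=cam.detector_u,
            detector_v=cam.detector_v,
            pixel_spacing=cam.pixel_spacing * fr,
            image_size=(int(size[0]), int(size[1])),
        )
    rows, cols = cam.image_size
    img = np.full((rows, cols), 0.85)
    xx, yy = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))

    gt: FeatureSet | None = None
    if scene.marker is not None and scene.sphere is not None:
        gt = _render_features_for_cam(scene, cam, camera_index, 0.0, seed)
    if scene.sphere is not None:
        circ = (
            gt.head_circle
            if gt is not None
            else silhouette_circle(cam, scene.sphere)
        )
        e = Ellipse(center=circ.center, a=circ.radius, b=circ.radius, theta=0.0)
        img *= 1.0 - 0.5 * _ellipse_coverage(xx, yy, e)
    if scene.marker is not None:
        if gt is not None:
            opening_ellipses = [
                e for hf in gt.hole_features for e in (hf.entry_ellipse, hf.exit_ellipse)
            ]
        else:
            opening_ellipses = []
            for h in scene.marker.holes:
                for c3 in h.opening_centers():
                    opening_ellipses.append(_project_circle_3d(cam, c3, h.axis, h.radius))
        for e in opening_ellipses:
            img *= 1.0 - 0.4 * _ellipse_coverage(xx, yy, e)
    if intensity_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3, int(camera_index)]))
        img = img + rng.normal(0.0, intensity_noise, img.shape)
    return np.clip(img, 0.0, 1.0), gt
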