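"""Rigid-body and projective-geometry primitives for C-arm scenes.

Conventions
-----------
* All lengths are millimetres; angles are exposed in degrees at the API
  surface and held in radians internally where noted.
* Pixels are 0-based with the origin at the top-left detector corner.
  ``x`` runs along ``detector_u`` (columns), ``y`` along ``detector_v``
  (rows), matching the raster order of DICOM pixel arrays.
* The marker frame doubles as the world frame.  A mobile C-arm is
  untracked, so only geometry *relative to the radiopaque marker* is ever
  recoverable; cameras are therefore posed relative to the marker.

Numerical tolerances: 1e-9 for algebraic identities (orthonormality,
round trips), 1e-6 px for projections.  Both leave ample double-precision
headroom at clinical scales (hundreds of mm, hundreds of px).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometry, GeometryError, RayParallelToDetector

_ORTHO_TOL = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError(f"{name} must be finite")
    return v


@dataclass(frozen=True)
class Pose:
    """Rigid transform mapping points from a source frame to a target frame.

    ``rotation`` is a 3x3 proper orthonormal matrix (checked to 1e-9),
    ``translation`` a 3-vector in mm:  ``p_target = R @ p_source + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(self.translation, "translation")
        if np.abs(R @ R.T - np.eye(3)).max() > _ORTHO_TOL:
            raise GeometryError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise GeometryError("rotation determinant is not +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one (3,) point or an (N, 3) stack."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T


def pose_compose(a: Pose, b: Pose) -> Pose:
    """``a ∘ b``: applying the result equals applying ``b`` then ``a``."""
    return Pose(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def pose_invert(p: Pose) -> Pose:
    return Pose(p.rotation.T, -p.rotation.T @ p.translation)


@dataclass(frozen=True)
class Line3:
    """Ray/line with unit direction.  ``point(t) = origin + t * direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = _as_vec3(self.origin, "origin")
        d = _as_vec3(self.direction, "direction")
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            if n < 1e-12:
                raise GeometryError("direction must be a unit vector, got zero")
            d = d / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    @staticmethod
    def through(a, b) -> "Line3":
        a = _as_vec3(a, "a")
        b = _as_vec3(b, "b")
        d = b - a
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise GeometryError("cannot build a line through coincident points")
        return Line3(a, d / n)

    def point(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Sphere:
    """Humeral-head estimate: center (mm, marker frame) and radius (mm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        c = _as_vec3(self.center, "center")
        r = float(self.radius)
        if not np.isfinite(r) or r <= 0:
            raise GeometryError("sphere radius must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "radius", r)

    @property
    def is_plausible_head(self) -> bool:
        """True when the radius is in the adult humeral-head range (10-40 mm)."""
        return 10.0 <= self.radius <= 40.0


@dataclass(frozen=True)
class CArmCamera:
    """Point-source + detector-plane projective model of one exposure.

    ``source`` is the X-ray focal spot, ``detector_origin`` the 3D position
    of pixel (0, 0); ``detector_u``/``detector_v`` are the orthonormal
    in-plane directions of increasing column and row.  ``image_size`` is
    (rows, cols).
    """

    source: np.ndarray
    detector_origin: np.ndarray
    detector_u: np.ndarray
    detector_v: np.ndarray
    pixel_spacing: float
    image_size: tuple[int, int]

    def __post_init__(self):
        s = _as_vec3(self.source, "source")
        o = _as_vec3(self.detector_origin, "detector_origin")
        u = _as_vec3(self.detector_u, "detector_u")
        v = _as_vec3(self.detector_v, "detector_v")
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if abs(nu - 1.0) > 1e-8 or abs(nv - 1.0) > 1e-8:
            raise GeometryError("detector_u and detector_v must be unit vectors")
        u, v = u / nu, v / nv
        if abs(u @ v) > 1e-8:
            raise GeometryError("detector_u and detector_v must be perpendicular")
        sp = float(self.pixel_spacing)
        if sp <= 0:
            raise GeometryError("pixel_spacing must be positive")
        size = (int(self.image_size[0]), int(self.image_size[1]))
        if size[0] <= 0 or size[1] <= 0:
            raise GeometryError("image_size must be positive")
        n = np.cross(u, v)
        if abs((s - o) @ n) < 1e-9:
            raise GeometryError("source must not lie on the detector plane")
        object.__setattr__(self, "source", s)
        object.__setattr__(self, "detector_origin", o)
        object.__setattr__(self, "detector_u", u)
        object.__setattr__(self, "detector_v", v)
        object.__setattr__(self, "pixel_spacing", sp)
        object.__setattr__(self, "image_size", size)

    @property
    def normal(self) -> np.ndarray:
        """Unit detector-plane normal, oriented from source toward detector."""
        n = np.cross(self.detector_u, self.detector_v)
        if (self.detector_origin - self.source) @ n < 0:
            n = -n
        return n

    @property
    def source_detector_distance(self) -> float:
        """Perpendicular source-to-detector distance (mm)."""
        return abs((self.source - self.detector_origin) @ np.cross(self.detector_u, self.detector_v))

    @property
    def principal_pixel(self) -> np.ndarray:
        """Pixel under the foot of the perpendicular from the source."""
        n = self.normal
        foot = self.source + ((self.detector_origin - self.source) @ n) * n
        d = foot - self.detector_origin
        return np.array([d @ self.detector_u, d @ self.detector_v]) / self.pixel_spacing

    def detector_point(self, pixel) -> np.ndarray:
        """3D position of a (x=col, y=row) pixel on the detector plane."""
        x, y = float(pixel[0]), float(pixel[1])
        return (
            self.detector_origin
            + x * self.pixel_spacing * self.detector_u
            + y * self.pixel_spacing * self.detector_v
        )


def project_point(cam: CArmCamera, p) -> np.ndarray:
    """Central projection of a 3D point onto the detector, in pixels.

    Follows the ray from the source through ``p`` to the detector plane and
    returns 0-based (x=col, y=row) pixel coordinates.
    """
    return project_points(cam, np.asarray(p, dtype=float).reshape(1, 3))[0]


def project_points(cam: CArmCamera, pts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`project_point` for an (N, 3) stack."""
    pts = np.asarray(pts, dtype=float)
    n = np.cross(cam.detector_u, cam.detector_v)
    d = pts - cam.source
    denom = d @ n
    scale = np.linalg.norm(d, axis=-1)
    if np.any(np.abs(denom) <= 1e-12 * np.maximum(scale, 1.0)):
        raise RayParallelToDetector("projection ray is parallel to the detector plane")
    t = ((cam.detector_origin - cam.source) @ n) / denom
    hit = cam.source + t[:, None] * d - cam.detector_origin
    return np.stack([hit @ cam.detector_u, hit @ cam.detector_v], axis=-1) / cam.pixel_spacing


def project_circle_centers(
    cam: CArmCamera, centers: np.ndarray, axes: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Exact centers of the projected conics of 3D circles, in pixels.

    The central projection of a circle is a conic whose center is *not*
    exactly the projection of the 3D circle center; this closed form
    evaluates the true conic center from the cone-plane intersection, so
    fitted-ellipse centers can serve as exact model observations.
    Vectorized over N circles; returns (N, 2).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    sp = cam.pixel_spacing
    a_vec = sp * cam.detector_u
    b_vec = sp * cam.detector_v
    w0 = cam.detector_origin - cam.source
    d = centers - cam.source  # (N, 3)
    beta = np.einsum("ij,ij->i", axes, d)
    g0 = axes @ w0
    g1 = axes @ a_vec
    g2 = axes @ b_vec
    h0 = d @ w0
    h1 = d @ a_vec
    h2 = d @ b_vec
    K = np.einsum("ij,ij->i", d, d) - radii**2
    sp2 = sp * sp
    A = beta**2 * sp2 - 2 * beta * h1 * g1 + K * g1**2
    B = -2 * beta * (h1 * g2 + h2 * g1) + 2 * K * g1 * g2
    C = beta**2 * sp2 - 2 * beta * h2 * g2 + K * g2**2
    D = 2 * beta**2 * (w0 @ a_vec) - 2 * beta * (h0 * g1 + h1 * g0) + 2 * K * g0 * g1
    E = 2 * beta**2 * (w0 @ b_vec) - 2 * beta * (h0 * g2 + h2 * g0) + 2 * K * g0 * g2
    det = 4 * A * C - B * B
    bad = np.abs(det) < 1e-300
    if np.any(bad):
        raise RayParallelToDetector("projected circle degenerates on the detector plane")
    x = (-2 * C * D + B * E) / det
    y = (-2 * A * E + B * D) / det
    return np.stack([x, y], axis=-1)


def backproject_ray(cam: CArmCamera, pixel) -> Line3:
    """Ray from the source through the detector point of ``pixel``.

    Out-of-bounds pixels are allowed (the math is unchanged) but warned
    about, since they cannot come from a real feature.
    """
    x, y = float(pixel[0]), float(pixel[1])
    rows, cols = cam.image_size
    if not (0 <= x <= cols - 1 and 0 <= y <= rows - 1):
        warnings.warn(f"pixel ({x:.1f}, {y:.1f}) outside image bounds {cam.image_size}", stacklevel=2)
    return Line3.through(cam.source, cam.detector_point((x, y)))


def line_sphere_intersect(line: Line3, s: Sphere) -> np.ndarray:
    """Real intersections of a line with a sphere, ordered by line parameter.

    Returns an (k, 3) array with k in {0, 1, 2}; a tangency (quadratic
    discriminant within 1e-9) yields the single tangent point.
    """
    oc = line.origin - s.center
    b = line.direction @ oc
    c = oc @ oc - s.radius**2
    disc = b * b - c
    if disc < -1e-9:
        return np.zeros((0, 3))
    if disc < 1e-9:
        return line.point(-b).reshape(1, 3)
    rt = np.sqrt(disc)
    return np.stack([line.point(-b - rt), line.point(-b + rt)])


def view_angle(cam_a: CArmCamera, cam_b: CArmCamera, reference) -> float:
    """Angular separation (degrees) of the two source directions.

    Measured at ``reference`` (the scene anchor: the sphere center when an
    estimate exists, else the marker origin) between the unit vectors from
    the reference toward each source.  Symmetric in the two cameras and
    invariant to scaling the source distances.
    """
    ref = _as_vec3(reference, "reference")
    va = cam_a.source - ref
    vb = cam_b.source - ref
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-9 or nb < 1e-9:
        raise DegenerateGeometry("a source coincides with the view-angle reference point")
    cross = np.linalg.norm(np.cross(va, vb))
    dot = va @ vb
    return float(np.degrees(np.arctan2(cross, dot)))


def transform_camera(cam: CArmCamera, pose: Pose) -> CArmCamera:
    """Express a camera in another frame (``pose``: current -> target)."""
    return CArmCamera(
        source=pose.apply(cam.source),
        detector_origin=pose.apply(cam.detector_origin),
        detector_u=pose.rotate(cam.detector_u),
        detector_v=pose.rotate(cam.detector_v),
        pixel_spacing=cam.pixel_spacing,
        image_size=cam.image_size,
    )


def camera_frame(cam: CArmCamera) -> tuple[CArmCamera, Pose]:
    """Canonical own-frame view of a camera.

    Returns the same camera expressed in its canonical frame (source at the
    origin, axes ``detector_u`` -> x, ``detector_v`` -> y) together with the
    :class:`Pose` mapping the frame ``cam`` was given in into that canonical
    frame.  Pixel coordinates of any projected point are identical in both
    representations.
    """
    n = np.cross(cam.detector_u, cam.detector_v)
    R = np.stack([cam.detector_u, cam.detector_v, n])
    world_to_cam = Pose(R, -R @ cam.source)
    canonical = CArmCamera(
        source=np.zeros(3),
        detector_origin=world_to_cam.apply(cam.detector_origin),
        detector_u=np.array([1.0, 0.0, 0.0]),
        detector_v=np.array([0.0, 1.0, 0.0]),
        pixel_spacing=cam.pixel_spacing,
        image_size=cam.image_size,
    )
    return canonical, world_to_cam
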