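"""Declarative geometry of the tracking marker and the locking plate.

The three-hole radiopaque marker clips onto the drill sleeve seated in the
plate's central hole, so a fixed rigid transform (``clip_to_plate``) relates
the marker frame to the plate frame.  The plate itself is described by its
screw catalog: per screw a seat point (where length is measured from), a
unit direction into the humeral head, and the commercially available
lengths.

The true vendor dimensions of clinical plates and markers are proprietary;
all geometry therefore lives in a versioned JSON definition file, and the
package ships a *synthetic*, plausibly scaled fixture (``philos_like.json``:
nine proximal screws on levels A-E with divergent trajectories, 2 mm length
increments) so that every algorithm is exercised geometry-file-relative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import GeometryError, SchemaError, UnknownScrew
from .geometry import Line3, Pose, pose_invert

_UNIT_TOL = 1e-6


# --------------------------------------------------------------------------
# runtime geometry objects


@dataclass(frozen=True)
class HoleSpec:
    """One cylindrical tracking hole: mid-axis center, axis, radius, depth."""

    hole_id: str
    center: np.ndarray
    axis: np.ndarray
    radius: float
    depth: float

    def opening_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centers of the two opening circles: (entry, exit).

        Entry is on the ``-axis`` side, exit on the ``+axis`` side; both lie
        ``depth/2`` from the mid-axis point.
        """
        half = 0.5 * self.depth * self.axis
        return self.center - half, self.center + half


@dataclass(frozen=True)
class MarkerGeometry:
    """Three-hole marker; the non-collinear pattern makes its pose unambiguous."""

    holes: tuple[HoleSpec, ...]
    name: str = "unnamed"
    version: str = "0"

    def hole(self, hole_id: str) -> HoleSpec:
        for h in self.holes:
            if h.hole_id == hole_id:
                return h
        raise KeyError(hole_id)


@dataclass(frozen=True)
class ScrewSpec:
    """One locking screw: seat (length origin), direction, catalog lengths."""

    label: str
    seat: np.ndarray
    direction: np.ndarray
    available_lengths: tuple[float, ...]
    central: bool = False


@dataclass(frozen=True)
class ImplantGeometry:
    """Plate screw catalog plus the marker-to-plate rigid transform.

    ``plate_axes`` are the dorsal-ventral and cranial-caudal unit directions
    in the plate frame (negative = ventral resp. caudal), both perpendicular
    to the central screw direction.
    """

    screws: tuple[ScrewSpec, ...]
    clip_to_plate: Pose
    plate_axes: tuple[np.ndarray, np.ndarray]

    def screw(self, label: str) -> ScrewSpec:
        for s in self.screws:
            if s.label == label:
                return s
        raise UnknownScrew(label)

    @property
    def central_screw(self) -> ScrewSpec:
        return next(s for s in self.screws if s.central)

    def plate_to_marker(self) -> Pose:
        """Pose mapping plate-frame points into the marker frame."""
        return pose_invert(self.clip_to_plate)


# --------------------------------------------------------------------------
# schema (structure errors -> SchemaError; invariant violations -> GeometryError)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _HoleDoc(_Strict):
    id: str
    center: list[float]
    axis: list[float]
    radius: float
    depth: float


class _MarkerDoc(_Strict):
    holes: list[_HoleDoc]


class _ScrewDoc(_Strict):
    label: str
    seat: list[float]
    direction: list[float]
    lengths: list[float]
    central: bool = False


class _PoseDoc(_Strict):
    rotation: list[list[float]]
    translation: list[float]


class _AxesDoc(_Strict):
    dv: list[float]
    cc: list[float]


class _ImplantDoc(_Strict):
    screws: list[_ScrewDoc]
    clip_to_plate: _PoseDoc
    plate_axes: _AxesDoc


class _DefinitionDoc(_Strict):
    name: str
    version: str
    marker: _MarkerDoc
    implant: _ImplantDoc


def _vec(values, n, what) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (n,):
        raise SchemaError(f"{what} must have {n} components")
    return v


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise GeometryError(f"{what} must be a unit vector (|v| = {n:.6g})")
    return v / n


def _nearest_rotation(R: np.ndarray, what: str) -> np.ndarray:
    err = np.abs(R @ R.T - np.eye(3)).max()
    if err > _UNIT_TOL or np.linalg.det(R) < 0:
        raise GeometryError(f"{what} must be a rigid (proper orthonormal) rotation")
    if err <= 1e-12:  # already rigid to full precision: keep bit-identical
        return R
    u, _, vt = np.linalg.svd(R)
    return u @ vt


# --------------------------------------------------------------------------
# loading / serialization


def load_implant_definition(document) -> tuple[MarkerGeometry, ImplantGeometry]:
    """Parse and validate a definition from a path, JSON string, or dict.

    Structural problems (missing/extra/mistyped fields) raise
    :class:`SchemaError`; violated geometric invariants raise
    :class:`GeometryError` naming the invariant.
    """
    if isinstance(document, (str, Path)) and (
        isinstance(document, Path) or not document.lstrip().startswith("{")
    ):
        with open(document, encoding="utf-8") as fh:
            raw = json.load(fh)
    elif isinstance(document, str):
        raw = json.loads(document)
    else:
        raw = document
    try:
        doc = _DefinitionDoc.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(str(exc)) from exc

    if len(doc.marker.holes) != 3:
        raise GeometryError(f"marker must have exactly 3 holes, got {len(doc.marker.holes)}")
    holes = []
    for h in doc.marker.holes:
        if h.radius <= 0:
            raise GeometryError(f"hole {h.id}: radius must be positive")
        if h.depth <= 0:
            raise GeometryError(f"hole {h.id}: depth must be positive")
        holes.append(
            HoleSpec(
                hole_id=h.id,
                center=_vec(h.center, 3, f"hole {h.id} center"),
                axis=_unit(_vec(h.axis, 3, f"hole {h.id} axis"), f"hole {h.id} axis"),
                radius=float(h.radius),
                depth=float(h.depth),
            )
        )
    centers = np.stack([h.center for h in holes])
    area = 0.5 * np.linalg.norm(np.cross(centers[1] - centers[0], centers[2] - centers[0]))
    if area <= 1.0:
        raise GeometryError(
            f"hole centers must be non-collinear (triangle area {area:.3g} mm^2 <= 1 mm^2)"
        )
    marker = MarkerGeometry(holes=tuple(holes), name=doc.name, version=doc.version)

    screws = []
    for s in doc.implant.screws:
        lengths = tuple(float(x) for x in s.lengths)
        if any(l <= 0 for l in lengths):
            raise GeometryError(f"screw {s.label}: available lengths must be positive")
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise GeometryError(f"screw {s.label}: available lengths must be strictly ascending")
        screws.append(
            ScrewSpec(
                label=s.label,
                seat=_vec(s.seat, 3, f"screw {s.label} seat"),
                direction=_unit(
                    _vec(s.direction, 3, f"screw {s.label} direction"),
                    f"screw {s.label} direction",
                ),
                available_lengths=lengths,
                central=bool(s.central),
            )
        )
    labels = [s.label for s in screws]
    if len(set(labels)) != len(labels):
        raise GeometryError("screw labels must be unique")
    n_central = sum(s.central for s in screws)
    if n_central == 0:
        # default: the plate's central hole (screw 7, D level) when present
        screws = [
            ScrewSpec(s.label, s.seat, s.direction, s.available_lengths, s.label == "D7")
            for s in screws
        ]
        n_central = sum(s.central for s in screws)
    if n_central != 1:
        raise GeometryError("exactly one screw must be flagged central")

    R = _nearest_rotation(
        np.asarray(doc.implant.clip_to_plate.rotation, dtype=float).reshape(3, 3),
        "clip_to_plate rotation",
    )
    clip_to_plate = Pose(R, _vec(doc.implant.clip_to_plate.translation, 3, "clip_to_plate translation"))

    dv = _unit(_vec(doc.implant.plate_axes.dv, 3, "plate_axes.dv"), "plate_axes.dv")
    cc = _unit(_vec(doc.implant.plate_axes.cc, 3, "plate_axes.cc"), "plate_axes.cc")
    if abs(dv @ cc) > _UNIT_TOL:
        raise GeometryError("plate_axes must be orthonormal")
    central_dir = next(s for s in screws if s.central).direction
    if abs(dv @ central_dir) > _UNIT_TOL or abs(cc @ central_dir) > _UNIT_TOL:
        raise GeometryError("plate_axes must be perpendicular to the central screw direction")

    implant = ImplantGeometry(screws=tuple(screws), clip_to_plate=clip_to_plate, plate_axes=(dv, cc))
    return marker, implant


def serialize_implant_definition(marker: MarkerGeometry, implant: ImplantGeometry) -> dict:
    """Inverse of :func:`load_implant_definition` (load -> serialize -> load round-trips)."""
    return {
        "name": marker.name,
        "version": marker.version,
        "marker": {
            "holes": [
                {
                    "id": h.hole_id,
                    "center": h.center.tolist(),
                    "axis": h.axis.tolist(),
                    "radius": h.radius,
                    "depth": h.depth,
                }
                for h in marker.holes
            ]
        },
        "implant": {
            "screws": [
                {
                    "label": s.label,
                    "seat": s.seat.tolist(),
                    "direction": s.direction.tolist(),
                    "lengths": list(s.available_lengths),
                    "central": s.central,
                }
                for s in implant.screws
            ],
            "clip_to_plate": {
                "rotation": implant.clip_to_plate.rotation.tolist(),
                "translation": implant.clip_to_plate.translation.tolist(),
            },
            "plate_axes": {
                "dv": implant.plate_axes[0].tolist(),
                "cc": implant.plate_axes[1].tolist(),
            },
        },
    }


def bundled_definition_path() -> Path:
    """Path of the synthetic plate/marker fixture shipped with the package."""
    return Path(resources.files("fluoroplan").joinpath("data/philos_like.json"))


def bundled_implant() -> tuple[MarkerGeometry, ImplantGeometry]:
    return load_implant_definition(bundled_definition_path())


# --------------------------------------------------------------------------
# geometric queries


def screw_trajectory(implant: ImplantGeometry, label: str, pose: Pose) -> Line3:
    """Screw line under a rigid transform of the *plate frame*.

    ``pose`` maps plate-frame coordinates into the target frame; with the
    identity pose, seat and direction are returned verbatim from the
    definition.  Use :func:`screw_trajectory_in_marker` for marker-frame
    trajectories (the frame reconstruction works in).
    """
    s = implant.screw(label)
    return Line3(pose.apply(s.seat), pose.rotate(s.direction))


def screw_trajectory_in_marker(
    implant: ImplantGeometry, label: str, plate_pose: Pose | None = None
) -> Line3:
    """Screw line in the world (marker) frame.

    ``plate_pose`` is the marker->world pose (identity by convention when
    the marker frame *is* the world frame); the fixed ``clip_to_plate``
    transform is chained in automatically.
    """
    from .geometry import pose_compose  # local import to avoid cycle noise

    if plate_pose is None:
        plate_pose = Pose.identity()
    return screw_trajectory(implant, label, pose_compose(plate_pose, implant.plate_to_marker()))


def hole_opening_points(marker: MarkerGeometry) -> list[tuple[str, str, np.ndarray]]:
    """The six opening-circle centers as (hole_id, 'entry'|'exit', point).

    Entry is deterministically the ``-axis`` side of each hole.  These six
    points are the model landmarks the pose estimator matches against
    observed hole projections.
    """
    out: list[tuple[str, str, np.ndarray]] = []
    for h in marker.holes:
        entry, exit_ = h.opening_centers()
        out.append((h.hole_id, "entry", entry))
        out.append((h.hole_id, "exit", exit_))
    return out
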