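"""JSON (de)serialization for scenes, features and results.

Feature-level JSON is the lingua franca between the CLI stages: the
simulator writes it, the extractor emits the identical schema from rasters,
and the planner consumes it.  Every feature file can embed the camera it
was measured on (expressed in the camera's canonical own frame, since the
true pose relative to the marker is exactly what reconstruction recovers).
All numbers are mm / pixels / degrees as documented on the fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import SchemaError
from .features import CircleCandidate, Ellipse
from .geometry import CArmCamera, Pose
from .implant import load_implant_definition, serialize_implant_definition
from .simulate import FeatureSet, HoleFeature, Scene


def pose_to_dict(p: Pose) -> dict:
    return {"rotation": p.rotation.tolist(), "translation": p.translation.tolist()}


def pose_from_dict(d: dict) -> Pose:
    return Pose(np.asarray(d["rotation"], dtype=float), np.asarray(d["translation"], dtype=float))


def camera_to_dict(cam: CArmCamera) -> dict:
    return {
        "source": cam.source.tolist(),
        "detector_origin": cam.detector_origin.tolist(),
        "detector_u": cam.detector_u.tolist(),
        "detector_v": cam.detector_v.tolist(),
        "pixel_spacing": cam.pixel_spacing,
        "image_size": list(cam.image_size),
    }


def camera_from_dict(d: dict) -> CArmCamera:
    try:
        return CArmCamera(
            source=np.asarray(d["source"], dtype=float),
            detector_origin=np.asarray(d["detector_origin"], dtype=float),
            detector_u=np.asarray(d["detector_u"], dtype=float),
            detector_v=np.asarray(d["detector_v"], dtype=float),
            pixel_spacing=float(d["pixel_spacing"]),
            image_size=tuple(d["image_size"]),
        )
    except KeyError as exc:
        raise SchemaError(f"camera document missing field {exc}") from exc


def _ellipse_to_dict(e: Ellipse) -> dict:
    return {
        "center": e.center.tolist(),
        "a": e.a,
        "b": e.b,
        "theta": e.theta,
        "rms": e.rms,
    }


def _ellipse_from_dict(d: dict) -> Ellipse:
    return Ellipse(
        center=np.asarray(d["center"], dtype=float),
        a=float(d["a"]),
        b=float(d["b"]),
        theta=float(d["theta"]),
        rms=float(d.get("rms", 0.0)),
    )


def _circle_to_dict(c: CircleCandidate) -> dict:
    return {"center": c.center.tolist(), "radius": c.radius, "score": c.score}


def _circle_from_dict(d: dict) -> CircleCandidate:
    return CircleCandidate(
        center=np.asarray(d["center"], dtype=float),
        radius=float(d["radius"]),
        score=float(d.get("score", 1.0)),
    )


def featureset_to_dict(fs: FeatureSet, camera: CArmCamera | None = None) -> dict:
    doc = {
        "image_id": fs.image_id,
        "noise_sigma": fs.noise_sigma,
        "hole_features": [
            {
                "hole_id": hf.hole_id,
                "entry": hf.entry.tolist(),
                "exit": hf.exit.tolist(),
                "entry_ellipse": _ellipse_to_dict(hf.entry_ellipse),
                "exit_ellipse": _ellipse_to_dict(hf.exit_ellipse),
            }
            for hf in fs.hole_features
        ],
        "head_circle": _circle_to_dict(fs.head_circle),
    }
    if camera is not None:
        doc["camera"] = camera_to_dict(camera)
    return doc


def featureset_from_dict(d: dict) -> tuple[FeatureSet, CArmCamera | None]:
    try:
        fs = FeatureSet(
            image_id=str(d["image_id"]),
            hole_features=tuple(
                HoleFeature(
                    hole_id=str(h["hole_id"]),
                    entry=np.asarray(h["entry"], dtype=float),
                    exit=np.asarray(h["exit"], dtype=float),
                    entry_ellipse=_ellipse_from_dict(h["entry_ellipse"]),
                    exit_ellipse=_ellipse_from_dict(h["exit_ellipse"]),
                )
                for h in d["hole_features"]
            ),
            head_circle=_circle_from_dict(d["head_circle"]),
            noise_sigma=float(d.get("noise_sigma", 0.0)),
        )
    except KeyError as exc:
        raise SchemaError(f"feature document missing field {exc}") from exc
    cam = camera_from_dict(d["camera"]) if "camera" in d else None
    return fs, cam


def scene_to_dict(scene: Scene) -> dict:
    doc = {
        "seed": scene.seed,
        "params": scene.params,
        "plate_pose": pose_to_dict(scene.plate_pose),
        "cameras": [camera_to_dict(c) for c in scene.cameras],
        "view_angle_deg": scene.view_angle_deg if scene.sphere is not None else None,
    }
    if scene.sphere is not None:
        doc["sphere"] = {"center": scene.sphere.center.tolist(), "radius": scene.sphere.radius}
    if scene.marker is not None and scene.implant is not None:
        doc["definition"] = serialize_implant_definition(scene.marker, scene.implant)
    return doc


def scene_from_dict(d: dict) -> Scene:
    from .geometry import Sphere

    marker = implant = None
    if "definition" in d:
        marker, implant = load_implant_definition(d["definition"])
    sphere = None
    if "sphere" in d:
        sphere = Sphere(np.asarray(d["sphere"]["center"], dtype=float), float(d["sphere"]["radius"]))
    return Scene(
        marker=marker,
        implant=implant,
        plate_pose=pose_from_dict(d["plate_pose"]),
        sphere=sphere,
        cameras=tuple(camera_from_dict(c) for c in d["cameras"]),
        seed=int(d.get("seed", 0)),
        params=dict(d.get("params", {})),
    )


def dump_json(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n", encoding="utf-8")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
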