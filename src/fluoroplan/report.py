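"""Stable, reproducible planning reports (JSON and aligned text)."""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .pipeline import PlanResult


def _implant_hash(path: str | None) -> str | None:
    if path is None or not Path(path).is_file():
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def report_to_dict(result: PlanResult) -> dict:
    """Serializable report with stable field order; embeds config and version."""
    return {
        "software_version": __version__,
        "config": {
            **asdict(result.config),
            "implant_definition_sha256_16": _implant_hash(result.config.implant_definition),
        },
        "pair": {
            "valid": result.validity.valid,
            "view_angle_deg": round(result.validity.angle_deg, 4),
            "view_angle_at_head_center_deg": round(result.angle_at_center_deg, 4),
            "pose_rms_px": [round(p.rms_residual, 6) for p in result.poses],
        },
        "sphere": {
            "center_mm": [round(x, 4) for x in result.sphere_fit.sphere.center.tolist()],
            "radius_mm": round(result.sphere_fit.sphere.radius, 4),
            "residual_mm": round(result.sphere_fit.residual, 6),
            "n_candidates": len(result.sphere_fit.candidates),
        },
        "plate_offset_mm": {"dv": round(result.offset.dv, 3), "cc": round(result.offset.cc, 3)},
        "screws": [
            {
                "label": p.label,
                "status": p.status,
                "raw_length_mm": None if p.raw_length is None else round(p.raw_length, 3),
                "suggested_length_mm": None
                if p.suggested_length is None
                else round(p.suggested_length, 3),
                "achieved_tjd_mm": None if p.achieved_tjd is None else round(p.achieved_tjd, 3),
            }
            for p in result.plans
        ],
        "warnings": list(result.warnings),
    }


def write_report(result: PlanResult, fmt: str = "json") -> str:
    """Render a report document; byte-identical for identical results."""
    doc = report_to_dict(result)
    if fmt == "json":
        import json

        return json.dumps(doc, indent=1) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = [
        f"fluoroplan {doc['software_version']} screw plan",
        f"  rounding: {doc['config']['rounding']} "
        "(rounded DOWN to the catalog unless configured otherwise; "
        "down is the joint-perforation-safe direction)",
        f"  pair: view angle {doc['pair']['view_angle_deg']:.2f} deg "
        f"({'valid' if doc['pair']['valid'] else 'INVALID'})",
        f"  head: radius {doc['sphere']['radius_mm']:.1f} mm, "
        f"center {doc['sphere']['center_mm']} mm, "
        f"fit residual {doc['sphere']['residual_mm']:.3f} mm",
        f"  plate offset: D-V {doc['plate_offset_mm']['dv']:+.1f} mm, "
        f"C-C {doc['plate_offset_mm']['cc']:+.1f} mm",
        "",
        f"  {'screw':<6} {'length [mm]':>12} {'TJD [mm]':>9}  status",
    ]
    for s in doc["screws"]:
        length = "-" if s["suggested_length_mm"] is None else f"{s['suggested_length_mm']:.0f}"
        tjd = "-" if s["achieved_tjd_mm"] is None else f"{s['achieved_tjd_mm']:.1f}"
        lines.append(f"  {s['label']:<6} {length:>12} {tjd:>9}  {s['status']}")
    for w in doc["warnings"]:
        lines.append(f"  WARNING: {w}")
    return "\n".join(lines) + "\n"
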