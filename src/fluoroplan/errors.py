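"""Exception hierarchy.

Every error raised by this package derives from :class:`FluoroplanError` so
callers (and the CLI) can map failures onto exit codes per stage.
"""

from __future__ import annotations


class FluoroplanError(Exception):
    """Base class for all package errors."""


class GeometryError(FluoroplanError):
    """A geometric invariant was violated; the message names the invariant."""


class SchemaError(FluoroplanError):
    """A structured document has missing, extra or mistyped fields."""


class ParamError(FluoroplanError):
    """Non-physical simulation or configuration parameter."""


class RayParallelToDetector(GeometryError):
    """The projection ray does not intersect the detector plane."""


class DegenerateGeometry(GeometryError):
    """Geometry too degenerate to solve (coincident sources, parallel axes)."""


class UnknownScrew(FluoroplanError, KeyError):
    """Requested screw label not present in the implant definition."""


class InsufficientFeatures(FluoroplanError):
    """Fewer hole features than the pose estimator requires."""


class AmbiguousPose(FluoroplanError):
    """Two distinct pose minima with near-identical residuals.

    Both candidate poses are attached as ``candidates`` (best first).
    """

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class HoleNotFound(FluoroplanError):
    """No hole component detected near a hint; carries ``hole_index``."""

    def __init__(self, hole_index: int, message: str | None = None):
        super().__init__(message or f"no hole component near hint {hole_index}")
        self.hole_index = hole_index


class NoCandidate(FluoroplanError):
    """Head segmentation produced no circle candidate above the score floor."""


class DegenerateInput(FluoroplanError):
    """Input point set too small or collinear for a conic fit."""


class BehindSource(FluoroplanError):
    """A scene object lies behind the X-ray source and cannot be projected."""


class NoValidPair(FluoroplanError):
    """No image pair exceeds the view-angle validity threshold."""


class InvalidPair(FluoroplanError):
    """The selected image pair fails the view-angle validity rule."""

    def __init__(self, message: str, angle_deg: float | None = None):
        super().__init__(message)
        self.angle_deg = angle_deg


class NoConvergence(FluoroplanError):
    """An iterative fit failed to converge to a physical solution."""


class InvalidStatus(FluoroplanError):
    """Operation requested on a screw plan whose status does not allow it."""


class NotDicom(FluoroplanError):
    """File is not a readable DICOM object."""


class MissingPixelSpacing(FluoroplanError):
    """DICOM object lacks pixel-spacing metadata (load-bearing for planning)."""
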