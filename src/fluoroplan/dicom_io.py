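"""Reading intraoperative DICOM exposures.

Pixel spacing is load-bearing (all planning math is metric), so a missing
spacing tag is a hard error rather than a default.  Orientation flags are
frequently not transmitted by C-arm interfaces; when absent they are logged
as unknown so the operator can check laterality manually.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import MissingPixelSpacing, NotDicom

logger = logging.getLogger(__name__)


def read_dicom(path) -> dict:
    """Load a grayscale DICOM exposure.

    Returns ``{"pixels", "pixel_spacing", "image_id", "metadata"}`` with
    pixels as a 2D float array and spacing in mm/px.  Raises
    :class:`NotDicom` for unreadable files and :class:`MissingPixelSpacing`
    when neither PixelSpacing nor ImagerPixelSpacing is present.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, ValueError, EOFError, PermissionError) as exc:
        raise NotDicom(f"{path} is not a readable DICOM file: {exc}") from exc
    try:
        pixels = np.asarray(ds.pixel_array, dtype=float)
    except Exception as exc:
        raise NotDicom(f"{path} carries no decodable pixel data: {exc}") from exc
    if pixels.ndim == 3:  # collapse RGB secondary captures
        pixels = pixels.mean(axis=-1)

    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise MissingPixelSpacing(
            f"{path}: no PixelSpacing/ImagerPixelSpacing tag; metric planning is impossible"
        )
    sp_row, sp_col = (float(spacing[0]), float(spacing[1]))
    if abs(sp_row - sp_col) > 1e-9:
        logger.warning("%s: anisotropic pixel spacing %s; using row spacing", path, spacing)

    for flag in ("PatientOrientation", "ImageLaterality", "FieldOfViewRotation"):
        if not getattr(ds, flag, None):
            logger.info("%s: orientation flag %s unknown (not transmitted)", path, flag)

    return {
        "pixels": pixels,
        "pixel_spacing": sp_row,
        "image_id": str(getattr(ds, "SOPInstanceUID", path.stem)),
        "metadata": {
            "rows": int(getattr(ds, "Rows", pixels.shape[0])),
            "columns": int(getattr(ds, "Columns", pixels.shape[1])),
            "modality": str(getattr(ds, "Modality", "")),
            "acquisition_time": str(getattr(ds, "AcquisitionTime", "")),
        },
    }
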