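"""Single-image layer: loading, tag access and elementary pixel transforms.

An :class:`ImageRecord` holds one 2D image together with its provenance
(filename, path, acquisition date, a sequential number) and, for DICOM
sources, a flat map of the header attributes the framework cares about.
DICOM is the prevalent format in medical imaging, so it gets dedicated
read/write-tag support; ordinary raster formats (bmp/png/jpg/gif/tiff)
are accepted as well and carry an empty tag map.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
from PIL import Image

from .errors import FormatError, TagMissingError

IMAGE_CLASS_VERSION = "1.0"

#: DICOM keywords copied into ImageRecord.tags when present in the header.
DICOM_TAG_KEYWORDS = (
    "EchoTime",
    "SliceLocation",
    "MagneticFieldStrength",
    "PatientName",
    "AcquisitionTime",
    "AcquisitionDate",
    "InstanceNumber",
)

RASTER_EXTENSIONS = {".bmp", ".png", ".jpg", ".jpeg", ".gif", ".tif", ".tiff"}


@dataclasses.dataclass
class ImageRecord:
    """One 2D image with provenance tags and a type label."""

    pixel_data: np.ndarray
    filename: str = ""
    path: str = ""
    acquisition_date: str = ""
    sequence_number: int = 0
    class_version: str = IMAGE_CLASS_VERSION
    image_type: str = ""
    tags: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixel_data = np.asarray(self.pixel_data)
        if self.pixel_data.ndim != 2 or self.pixel_data.size < 1:
            raise FormatError(
                f"pixel_data must be a non-empty 2D array, got shape "
                f"{self.pixel_data.shape}"
            )


def _plain(value: Any) -> Any:
    """Convert a pydicom element value to a plain number or string."""
    if isinstance(value, (int, float, str)):
        return value
    if isinstance(value, pydicom.valuerep.PersonName):
        return str(value)
    try:
        return float(value)
    except (TypeError, ValueError):
        return str(value)


def read_dicom(path: str | Path, image_type: str) -> ImageRecord:
    """Read a single-frame DICOM file into an :class:`ImageRecord`.

    Rescale slope/intercept are applied when present, so pixel values are
    in the modality's output units; otherwise the stored dtype is kept.

    Parameters
    ----------
    path:
        Path of the DICOM file.
    image_type:
        Label identifying the kind of image (e.g. ``"Real"``,
        ``"Imaginary"``, ``"T1 weighted"``); stored on the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        ds = pydicom.dcmread(str(path))
    except pydicom.errors.InvalidDicomError as exc:
        raise FormatError(f"not a DICOM file: {path} ({exc})") from exc
    if "PixelData" not in ds:
        raise FormatError(f"DICOM file has no pixel data: {path}")

    data = ds.pixel_array
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        data = data.astype(np.float64) * slope + intercept
    if data.ndim != 2:
        raise FormatError(f"expected a single-frame 2D image: {path}")

    tags: dict[str, Any] = {}
    for kw in DICOM_TAG_KEYWORDS:
        if kw in ds:
            tags[kw] = _plain(ds[kw].value)
    return ImageRecord(
        pixel_data=data,
        filename=path.name,
        path=str(path.parent),
        acquisition_date=str(getattr(ds, "AcquisitionDate", "")),
        image_type=image_type,
        tags=tags,
    )


def read_raster(path: str | Path, image_type: str,
                sequence_number: int = 0) -> ImageRecord:
    """Read a bmp/png/jpg/gif/tiff image; multi-channel input is reduced
    to grayscale by the unweighted channel mean."""
    path = Path(path)
    if path.suffix.lower() not in RASTER_EXTENSIONS:
        raise FormatError(
            f"unsupported raster extension {path.suffix!r} for {path}; "
            f"expected one of {sorted(RASTER_EXTENSIONS)}"
        )
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    data = np.asarray(Image.open(path))
    if data.ndim == 3:
        data = data.mean(axis=2)
    return ImageRecord(
        pixel_data=data,
        filename=path.name,
        path=str(path.parent),
        sequence_number=sequence_number,
        image_type=image_type,
    )


def get_tag(record: ImageRecord, name: str) -> Any:
    """Return the value of tag ``name``; absent tag raises TagMissingError."""
    try:
        return record.tags[name]
    except KeyError:
        raise TagMissingError(f"tag {name!r} not present on {record.filename or 'record'}") from None


def set_tag(record: ImageRecord, name: str, value: Any) -> ImageRecord:
    """Set tag ``name`` to ``value`` and return the record."""
    record.tags[name] = value
    return record


def scale2(data: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine rescale so min(data) maps to ``lo`` and max(data) to ``hi``.

    A constant input maps to all ``lo`` (the range is degenerate and the
    map would otherwise divide by zero).
    """
    if hi <= lo:
        raise ValueError(f"scale2 requires hi > lo, got lo={lo}, hi={hi}")
    data = np.asarray(data, dtype=np.float64)
    dmin = data.min()
    dmax = data.max()
    if dmax == dmin:
        return np.full_like(data, lo)
    return lo + (data - dmin) * ((hi - lo) / (dmax - dmin))


def conv2RGB(record: ImageRecord) -> np.ndarray:
    """Convert a grayscale record to an RGB array of shape (rows, cols, 3).

    Each channel is the pixel data rescaled to [0, 1] with :func:`scale2`.
    """
    if record.pixel_data.ndim != 2:
        raise FormatError("conv2RGB expects single-channel pixel data")
    chan = scale2(record.pixel_data, 0.0, 1.0)
    return np.dstack([chan, chan, chan])
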