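"""Reading HRCT input into calibrated Hounsfield-unit slices.

Supports single-frame CT DICOM files (rescale slope/intercept applied) and
plain-text numeric grids that already contain HU values.  All downstream
modules consume the :class:`HUSlice` container produced here and share its
coordinate convention: (row, col), 0-based, row 0 at the top of the image.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

logger = logging.getLogger(__name__)

#: Valid HU range for 12-bit CT data; everything is clamped into it on load.
HU_MIN = -1024
HU_MAX = 3071

#: Sentinel stored in pixels excluded by a region-of-interest mask.  It lies
#: outside the clamp range, so no HU band can ever match it.
EXCLUDED_HU = -32768

#: Pixel spacing (mm) assumed when a DICOM file lacks the PixelSpacing tag:
#: a 35 cm field of view over a 768 x 768 matrix.
DEFAULT_SPACING_MM = 0.4557


@dataclass(frozen=True)
class HUSlice:
    """A calibrated 2-D Hounsfield-unit grid with acquisition metadata.

    Parameters
    ----------
    values
        Integer HU grid, shape (rows, cols).  Values are clamped to
        [-1024, 3071]; the ROI sentinel :data:`EXCLUDED_HU` is also admitted.
    pixel_spacing_mm
        (row spacing, col spacing) in millimetres, both strictly positive.
    acquisition_date
        Calendar date of the scan.
    subject_id, series_id
        Opaque identifiers carried through to output tables.
    """

    values: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)
    acquisition_date: _dt.date = field(default_factory=_dt.date.today)
    subject_id: str = ""
    series_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("HU grid must be 2-D and non-empty")
        if not np.issubdtype(values.dtype, np.integer):
            values = np.rint(values).astype(np.int32)
        else:
            values = values.astype(np.int32, copy=False)
        in_range = (values >= HU_MIN) & (values <= HU_MAX)
        if not np.all(in_range | (values == EXCLUDED_HU)):
            raise ValueError(
                f"HU values must lie in [{HU_MIN}, {HU_MAX}] or equal the "
                f"ROI sentinel {EXCLUDED_HU}"
            )
        object.__setattr__(self, "values", values)
        rs, cs = self.pixel_spacing_mm
        if not (math.isfinite(rs) and math.isfinite(cs) and rs > 0 and cs > 0):
            raise ValueError("pixel spacings must be strictly positive and finite")
        object.__setattr__(self, "pixel_spacing_mm", (float(rs), float(cs)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask, same shape as its slice."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError("ROI mask must be 2-D and non-empty")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_rectangle(
        cls, shape: tuple[int, int], origin: tuple[int, int], size: tuple[int, int]
    ) -> "ROIMask":
        """Rectangular ROI given as (row, col) origin and (height, width)."""
        mask = np.zeros(shape, dtype=bool)
        r0, c0 = origin
        h, w = size
        mask[r0 : r0 + h, c0 : c0 + w] = True
        return cls(mask)


def hu_from_stored(raw: Union[int, float], slope: float, intercept: float) -> int:
    """Convert a stored DICOM pixel value to a clamped Hounsfield unit.

    Applies the standard linear rescale ``HU = raw * slope + intercept``,
    rounds to the nearest integer and clamps to [-1024, 3071].
    """
    if not (math.isfinite(raw) and math.isfinite(slope) and math.isfinite(intercept)):
        raise ValueError("raw, slope and intercept must all be finite")
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    hu = round(raw * slope + intercept)
    return int(min(max(hu, HU_MIN), HU_MAX))


def _hu_from_stored_array(
    raw: np.ndarray, slope: float, intercept: float
) -> np.ndarray:
    if not (math.isfinite(slope) and math.isfinite(intercept)) or slope == 0:
        raise ValueError("rescale slope must be finite and nonzero")
    hu = np.rint(raw.astype(np.float64) * slope + intercept)
    return np.clip(hu, HU_MIN, HU_MAX).astype(np.int32)


def _parse_dicom_date(value: str) -> Optional[_dt.date]:
    try:
        return _dt.datetime.strptime(str(value), "%Y%m%d").date()
    except (TypeError, ValueError):
        return None


def _load_dicom(path: Path) -> HUSlice:
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    raw = ds.pixel_array
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame 2-D CT image")

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        logger.warning("%s: missing rescale tags, assuming slope=1 intercept=0", path)

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        logger.warning(
            "%s: missing PixelSpacing, assuming %.4f mm (35 cm FOV / 768 matrix)",
            path,
            DEFAULT_SPACING_MM,
        )
        spacing_mm = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)
    else:
        spacing_mm = (float(spacing[0]), float(spacing[1]))

    date = _parse_dicom_date(
        getattr(ds, "AcquisitionDate", "") or getattr(ds, "StudyDate", "")
    )
    return HUSlice(
        values=_hu_from_stored_array(raw, slope, intercept),
        pixel_spacing_mm=spacing_mm,
        acquisition_date=date or _dt.date.today(),
        subject_id=str(getattr(ds, "PatientID", "")),
        series_id=str(getattr(ds, "SeriesInstanceUID", "")),
    )


def _load_grid(path: Path) -> HUSlice:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    values = np.clip(np.rint(values), HU_MIN, HU_MAX).astype(np.int32)
    return HUSlice(values=values)


def load_slice(path: Union[str, Path], kind: Optional[str] = None) -> HUSlice:
    """Load an HRCT slice from a DICOM file or a plain-text HU grid.

    Parameters
    ----------
    path
        Input file.  DICOM pixels are passed through the rescale transform;
        text grids are treated as already-calibrated HU values.
    kind
        ``"dicom"`` or ``"grid"``.  When omitted, ``.dcm``/``.dicom``
        extensions select DICOM and everything else is read as a grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind is None:
        kind = "dicom" if path.suffix.lower() in {".dcm", ".dicom"} else "grid"
    if kind == "dicom":
        return _load_dicom(path)
    if kind == "grid":
        return _load_grid(path)
    raise ValueError(f"unknown input kind {kind!r}; expected 'dicom' or 'grid'")


def apply_roi(hu_slice: HUSlice, roi: ROIMask) -> HUSlice:
    """Mask a slice to a region of interest.

    Pixels outside the mask are replaced by the sentinel :data:`EXCLUDED_HU`,
    which no HU band matches, so they vanish from every downstream band
    layer.  Pixels inside the mask are untouched and keep their coordinates,
    so longitudinal comparisons of the same anatomical window stay aligned.
    """
    if roi.mask.shape != hu_slice.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match slice shape {hu_slice.shape}"
        )
    if not roi.mask.any():
        raise ValueError("ROI mask selects no pixels")
    values = hu_slice.values.copy()
    values[~roi.mask] = EXCLUDED_HU
    return HUSlice(
        values=values,
        pixel_spacing_mm=hu_slice.pixel_spacing_mm,
        acquisition_date=hu_slice.acquisition_date,
        subject_id=hu_slice.subject_id,
        series_id=hu_slice.series_id,
    )
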