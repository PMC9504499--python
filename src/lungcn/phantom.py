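"""Synthetic 2-D HU lung-slice phantoms with ground-truth lesion masks.

The phantom emulates an axial HRCT window at the study geometry
(0.4557 mm/px, i.e. a 35 cm field of view over a 768 matrix): an elliptical
lung field of aerated parenchyma over a soft-tissue border, populated with
parameterized lesions whose attenuation places them in a known HU band:

* ``emphysema_blob`` / ``cyst`` lumina around -1000 HU (band E),
* ``ggo_patch`` around -800 HU (band GGO),
* ``reticulation_line`` / ``consolidation_disk`` / ``nodule_string`` around
  -50 HU (band C),
* ``honeycomb_cluster`` — packed cyst rings whose lumina land in band E and
  walls in band C, the end-stage fibrosis pattern.

The default background of -880 HU sits inside the GGO band, as healthy
parenchyma does on real CT; pass an out-of-band background (e.g. -1000 for
GGO studies) for clean detectability experiments.  Longitudinal growth
rescales each lesion's linear size by (1 + annual_growth)^t and advances the
acquisition date, providing ground truth for progression-speed recovery.

All randomness flows from an explicit integer seed; identical inputs give
bit-identical integer HU grids.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .image_io import DEFAULT_SPACING_MM, HU_MAX, HU_MIN, HUSlice

logger = logging.getLogger(__name__)

LESION_KINDS = (
    "emphysema_blob",
    "cyst",
    "ggo_patch",
    "reticulation_line",
    "consolidation_disk",
    "honeycomb_cluster",
    "nodule_string",
)

#: Default mean attenuation per lesion kind, placing it in its intended band.
DEFAULT_HU_MEAN = {
    "emphysema_blob": -1000,  # band E
    "cyst": -1000,  # lumen, band E (wall at -50, band C)
    "ggo_patch": -800,  # band GGO
    "reticulation_line": -50,  # band C
    "consolidation_disk": -50,  # band C
    "honeycomb_cluster": -1000,  # lumina, band E (walls at -50)
    "nodule_string": -50,  # band C
}

DEFAULT_BACKGROUND = (-880.0, 20.0)
SOFT_TISSUE_HU = 40
DEFAULT_DATE = _dt.date(2020, 1, 1)


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic lesion: kind, position, linear size and attenuation.

    ``size_mm`` is the characteristic linear size — the diameter for disks,
    blobs and cysts, total length for lines and nodule strings, the cluster
    diameter for honeycombing.  ``extra`` carries kind-specific parameters
    (cyst wall HU, honeycomb cyst count, ...).
    """

    kind: str
    center: tuple[float, float]
    size_mm: float
    hu_mean: Optional[int] = None
    hu_sd: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if self.hu_sd < 0:
            raise ValueError("hu_sd must be non-negative")
        if self.hu_mean is None:
            object.__setattr__(self, "hu_mean", DEFAULT_HU_MEAN[self.kind])
        if not (HU_MIN <= self.hu_mean <= HU_MAX):
            raise ValueError(f"hu_mean {self.hu_mean} outside [{HU_MIN}, {HU_MAX}]")


@dataclass(frozen=True)
class PhantomTruth:
    """A generated slice plus everything needed to audit or regenerate it."""

    slice: HUSlice
    lesion_masks: list[np.ndarray]
    background_mask: np.ndarray
    seed: int
    lesions: tuple[LesionSpec, ...]
    background_hu: tuple[float, float]


def honeycomb_cluster(
    center: tuple[float, float],
    n_cysts: int,
    cyst_diameter_mm: float,
    wall_hu: int = -50,
    lumen_hu: int = -1000,
) -> LesionSpec:
    """A packed cluster of thick-walled cysts (honeycombing).

    Lumina (``lumen_hu``) fall in band E and walls (``wall_hu``) in band C
    within the same neighbourhood.  ``size_mm`` of the returned spec is the
    approximate cluster diameter.
    """
    if n_cysts < 1:
        raise ValueError("n_cysts must be >= 1")
    rings = 1 if n_cysts == 1 else (2 if n_cysts <= 7 else 3)
    return LesionSpec(
        kind="honeycomb_cluster",
        center=center,
        size_mm=cyst_diameter_mm * (2 * rings - 1),
        hu_mean=lumen_hu,
        extra={
            "n_cysts": int(n_cysts),
            "cyst_diameter_mm": float(cyst_diameter_mm),
            "wall_hu": int(wall_hu),
        },
    )


# --- rasterizers -----------------------------------------------------------
# A pixel belongs to a shape when its centre (integer coordinates) is inside;
# geometric assertions downstream allow 1 px of rasterization error.


def _grid_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), indexing="ij", copy=False
    )


def _disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius_px: float
) -> np.ndarray:
    rr, cc = _grid_coords(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _ring_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    inner_px: float,
    outer_px: float,
) -> np.ndarray:
    rr, cc = _grid_coords(shape)
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 > inner_px**2) & (d2 <= outer_px**2)


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    # irregular rounded polygon: radius modulated by low-order harmonics
    amp = rng.uniform(0.05, 0.20, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    rr, cc = _grid_coords(shape)
    dr, dc = rr - center[0], cc - center[1]
    theta = np.arctan2(dc, dr)
    mod = 1.0 + sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase))
    )
    return dr**2 + dc**2 <= (radius_px * mod) ** 2


def _segment_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    length_px: float,
    angle: float,
    half_width_px: float = 0.71,
) -> np.ndarray:
    # pixels whose centre lies within half_width of the segment
    rr, cc = _grid_coords(shape)
    ur, uc = np.cos(angle), np.sin(angle)
    dr, dc = rr - center[0], cc - center[1]
    along = dr * ur + dc * uc
    along_clamped = np.clip(along, -length_px / 2, length_px / 2)
    dist2 = (dr - along_clamped * ur) ** 2 + (dc - along_clamped * uc) ** 2
    return dist2 <= half_width_px**2


def _honeycomb_centers(
    center: tuple[float, float], n_cysts: int, spacing_px: float
) -> list[tuple[float, float]]:
    # hexagonal packing: centre first, then concentric rings of 6k
    centers = [center]
    ring = 1
    while len(centers) < n_cysts:
        count = 6 * ring
        for k in range(count):
            ang = 2 * np.pi * k / count
            centers.append(
                (
                    center[0] + ring * spacing_px * np.cos(ang),
                    center[1] + ring * spacing_px * np.sin(ang),
                )
            )
            if len(centers) == n_cysts:
                break
        ring += 1
    return centers


def _rasterize_lesion(
    spec: LesionSpec,
    shape: tuple[int, int],
    spacing_mm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask, hu_values) for one lesion; hu_values is a full grid with
    meaningful entries only inside the mask."""
    radius_px = (spec.size_mm / 2.0) / spacing_mm
    hu = np.full(shape, float(spec.hu_mean))

    if spec.kind in ("ggo_patch", "consolidation_disk"):
        mask = _disk_mask(shape, spec.center, radius_px)
    elif spec.kind == "emphysema_blob":
        mask = _blob_mask(shape, spec.center, radius_px, rng)
    elif spec.kind == "cyst":
        wall_hu = spec.extra.get("wall_hu", -50)
        wall_px = spec.extra.get("wall_px", 1.5)
        lumen = _disk_mask(shape, spec.center, radius_px)
        wall = _ring_mask(shape, spec.center, radius_px, radius_px + wall_px)
        hu[wall] = float(wall_hu)
        mask = lumen | wall
    elif spec.kind == "reticulation_line":
        angle = spec.extra.get("angle", rng.uniform(0, np.pi))
        mask = _segment_mask(shape, spec.center, spec.size_mm / spacing_mm, angle)
    elif spec.kind == "nodule_string":
        angle = spec.extra.get("angle", rng.uniform(0, np.pi))
        nodule_r = spec.extra.get("nodule_radius_px", 1.0)
        step_px = spec.extra.get("step_px", 3.0)
        length_px = spec.size_mm / spacing_mm
        n = max(2, int(length_px // step_px) + 1)
        ur, uc = np.cos(angle), np.sin(angle)
        mask = np.zeros(shape, dtype=bool)
        for k in range(n):
            off = (k - (n - 1) / 2) * step_px
            mask |= _disk_mask(
                shape, (spec.center[0] + off * ur, spec.center[1] + off * uc), nodule_r
            )
    elif spec.kind == "honeycomb_cluster":
        n_cysts = spec.extra.get("n_cysts", 7)
        cyst_d_mm = spec.extra.get("cyst_diameter_mm", spec.size_mm / 3)
        wall_hu = spec.extra.get("wall_hu", -50)
        wall_px = spec.extra.get("wall_px", 1.5)
        lumen_r = (cyst_d_mm / 2.0) / spacing_mm
        spacing_px = 2 * lumen_r + 2 * wall_px + 1.0  # lumina stay disconnected
        lumina = np.zeros(shape, dtype=bool)
        walls = np.zeros(shape, dtype=bool)
        for cyst_center in _honeycomb_centers(spec.center, n_cysts, spacing_px):
            lumina |= _disk_mask(shape, cyst_center, lumen_r)
            walls |= _ring_mask(shape, cyst_center, lumen_r, lumen_r + wall_px)
        walls &= ~lumina  # a lumen always wins over a neighbouring cyst's wall
        hu[lumina] = float(spec.hu_mean)
        hu[walls] = float(wall_hu)
        mask = lumina | walls
    else:  # pragma: no cover - guarded by LesionSpec validation
        raise ValueError(spec.kind)

    if spec.hu_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_sd, size=shape)
    return mask, hu


def _honeycomb_lumina(
    shape: tuple[int, int], spec: LesionSpec, spacing_mm: float
) -> np.ndarray:
    n_cysts = spec.extra.get("n_cysts", 7)
    cyst_d_mm = spec.extra.get("cyst_diameter_mm", spec.size_mm / 3)
    wall_px = spec.extra.get("wall_px", 1.5)
    lumen_r = (cyst_d_mm / 2.0) / spacing_mm
    spacing_px = 2 * lumen_r + 2 * wall_px + 1.0
    lumina = np.zeros(shape, dtype=bool)
    for c in _honeycomb_centers(spec.center, n_cysts, spacing_px):
        lumina |= _disk_mask(shape, c, lumen_r)
    return lumina


def honeycomb_lumen_mask(
    truth: PhantomTruth, lesion_index: int
) -> np.ndarray:
    """Ground-truth lumen-only mask of a honeycomb lesion (band E part)."""
    spec = truth.lesions[lesion_index]
    if spec.kind != "honeycomb_cluster":
        raise ValueError("lesion is not a honeycomb cluster")
    return _honeycomb_lumina(
        truth.slice.shape, spec, truth.slice.pixel_spacing_mm[0]
    ) & truth.background_mask


# --- generation ------------------------------------------------------------


def generate_slice(
    shape: tuple[int, int] = (256, 256),
    spacing_mm: float = DEFAULT_SPACING_MM,
    background_hu: tuple[float, float] = DEFAULT_BACKGROUND,
    lesions: Sequence[LesionSpec] = (),
    seed: int = 0,
    acquisition_date: _dt.date = DEFAULT_DATE,
    subject_id: str = "phantom",
    series_id: str = "t0",
) -> PhantomTruth:
    """Generate a synthetic axial HU slice with ground-truth lesion masks.

    The lung field is an ellipse inscribed in the grid (semi-axes 0.45 of
    each dimension) filled with rounded-Gaussian parenchymal noise at
    ``background_hu`` = (mean, sd); outside the field lies soft tissue at
    +40 HU.  Lesions are rasterized in list order — later lesions overwrite
    earlier ones — and clipped to the lung field with a warning if they
    protrude.  Deterministic for fixed arguments and seed.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)

    rr, cc = _grid_coords(shape)
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    lung = (
        ((rr - center[0]) / (0.45 * rows)) ** 2
        + ((cc - center[1]) / (0.45 * cols)) ** 2
    ) <= 1.0

    mean, sd = background_hu
    values = np.full(shape, float(SOFT_TISSUE_HU))
    if sd > 0:
        values[lung] = mean + rng.normal(0.0, sd, size=int(lung.sum()))
    else:
        values[lung] = mean

    masks: list[np.ndarray] = []
    for spec in lesions:
        mask, hu = _rasterize_lesion(spec, shape, spacing_mm, rng)
        outside = mask & ~lung
        if outside.any():
            warnings.warn(
                f"lesion {spec.kind} at {spec.center} extends outside the lung "
                f"field; clipped ({int(outside.sum())} px)",
                stacklevel=2,
            )
        mask = mask & lung
        values[mask] = hu[mask]
        masks.append(mask)

    values = np.clip(np.rint(values), HU_MIN, HU_MAX).astype(np.int32)
    return PhantomTruth(
        slice=HUSlice(
            values=values,
            pixel_spacing_mm=(spacing_mm, spacing_mm),
            acquisition_date=acquisition_date,
            subject_id=subject_id,
            series_id=series_id,
        ),
        lesion_masks=masks,
        background_mask=lung,
        seed=int(seed),
        lesions=tuple(lesions),
        background_hu=(float(mean), float(sd)),
    )


def grow_lesions(
    truth: PhantomTruth,
    annual_growth: float,
    t_years: float,
    seed: int,
) -> PhantomTruth:
    """Simulate a follow-up scan after ``t_years`` of lesion growth.

    Every lesion's linear size is scaled by (1 + annual_growth)^t_years (so
    areas scale with the square); background noise is regenerated from the
    new seed, and the acquisition date advances by round(365 * t_years) days.
    """
    if annual_growth <= -1:
        raise ValueError("annual_growth must exceed -1")
    factor = (1.0 + annual_growth) ** t_years
    grown = tuple(
        replace(spec, size_mm=spec.size_mm * factor) for spec in truth.lesions
    )
    new_date = truth.slice.acquisition_date + _dt.timedelta(
        days=round(365 * t_years)
    )
    return generate_slice(
        shape=truth.slice.shape,
        spacing_mm=truth.slice.pixel_spacing_mm[0],
        background_hu=truth.background_hu,
        lesions=grown,
        seed=seed,
        acquisition_date=new_date,
        subject_id=truth.slice.subject_id,
        series_id=f"{truth.slice.series_id}+{t_years:g}y",
    )


# --- output ----------------------------------------------------------------


def write_grid(truth: PhantomTruth, path: Union[str, Path]) -> None:
    """Write the HU grid as whitespace-delimited plain text."""
    np.savetxt(path, truth.slice.values, fmt="%d")


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a boolean mask as a 0/1 text grid."""
    np.savetxt(path, mask.astype(np.int8), fmt="%d")


def write_manifest(truth: PhantomTruth, path: Union[str, Path]) -> None:
    """Write a JSON manifest: seed, lesion specs, geometry, date."""
    manifest = {
        "seed": truth.seed,
        "shape": list(truth.slice.shape),
        "pixel_spacing_mm": list(truth.slice.pixel_spacing_mm),
        "acquisition_date": truth.slice.acquisition_date.isoformat(),
        "background_hu": list(truth.background_hu),
        "lesions": [
            {
                "kind": s.kind,
                "center": list(s.center),
                "size_mm": s.size_mm,
                "hu_mean": s.hu_mean,
                "hu_sd": s.hu_sd,
                "extra": s.extra,
            }
            for s in truth.lesions
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def write_dicom(truth: PhantomTruth, path: Union[str, Path]) -> None:
    """Write the phantom as a minimal single-frame CT DICOM file.

    Stored values are HU + 1024 with RescaleSlope 1 / RescaleIntercept -1024,
    so a round trip through the DICOM reader reproduces the HU grid exactly.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = truth.slice.subject_id
    ds.SeriesInstanceUID = generate_uid()
    ds.AcquisitionDate = truth.slice.acquisition_date.strftime("%Y%m%d")
    ds.StudyDate = ds.AcquisitionDate
    ds.Rows, ds.Columns = truth.slice.shape
    ds.PixelSpacing = [str(truth.slice.pixel_spacing_mm[0]),
                       str(truth.slice.pixel_spacing_mm[1])]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned stored values
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    stored = (truth.slice.values.astype(np.int32) + 1024).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
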