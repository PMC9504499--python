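"""Splitting an HU slice into pathologically relevant band layers.

Three half-open HU intervals cover the lesion types of interest on lung HRCT:

* **E** [-1024, -977): emphysema and cyst lumina (very low attenuation),
* **GGO** [-977, -703): ground-glass opacity (hazy increased attenuation),
* **C** [-100, 5): consolidation and reticulation (soft-tissue density).

Pixels falling in no band — including the gap [-703, -100) between normal
parenchyma and dense lesions, anything >= 5 HU, and ROI-excluded pixels —
are discarded before network construction.  The band set is configurable;
the defaults above are scanner-calibrated values for the study geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .image_io import HUSlice


@dataclass(frozen=True)
class BandDefinition:
    """A named half-open HU interval [lower_hu, upper_hu)."""

    name: str
    lower_hu: int
    upper_hu: int

    def __post_init__(self) -> None:
        if self.lower_hu >= self.upper_hu:
            raise ValueError(
                f"band {self.name!r}: lower bound {self.lower_hu} must be "
                f"below upper bound {self.upper_hu}"
            )

    def contains(self, hu: Union[int, np.ndarray]):
        return (hu >= self.lower_hu) & (hu < self.upper_hu)


@dataclass(frozen=True)
class BandLayer:
    """The pixels of one slice whose HU falls inside one band.

    ``rows``, ``cols`` and ``hus`` are parallel 1-D arrays; coordinates are
    unique within a layer.  ``source_shape`` and ``pixel_spacing_mm`` are
    inherited from the source slice so geometry is preserved.
    """

    band: BandDefinition
    rows: np.ndarray
    cols: np.ndarray
    hus: np.ndarray
    source_shape: tuple[int, int]
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.int64)
        cols = np.asarray(self.cols, dtype=np.int64)
        hus = np.asarray(self.hus, dtype=np.int32)
        if not (rows.shape == cols.shape == hus.shape) or rows.ndim != 1:
            raise ValueError("rows, cols, hus must be parallel 1-D arrays")
        if rows.size and not np.all(self.band.contains(hus)):
            raise ValueError(f"layer contains HU values outside band {self.band.name}")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)
        object.__setattr__(self, "hus", hus)

    @property
    def pixel_count(self) -> int:
        return int(self.rows.size)

    def pixels(self) -> Iterable[tuple[int, int, int]]:
        """Iterate (row, col, hu) triples."""
        return zip(self.rows.tolist(), self.cols.tolist(), self.hus.tolist())

    def to_csv(self, path: Union[str, Path]) -> None:
        """Export the layer as sparse CSV with columns row, col, hu."""
        with open(path, "w") as fh:
            fh.write("row,col,hu\n")
            for r, c, h in self.pixels():
                fh.write(f"{r},{c},{h}\n")


def default_bands() -> list[BandDefinition]:
    """The three scanner-calibrated HU bands: E, GGO and C."""
    return [
        BandDefinition("E", -1024, -977),
        BandDefinition("GGO", -977, -703),
        BandDefinition("C", -100, 5),
    ]


def _check_disjoint(bands: Sequence[BandDefinition]) -> None:
    ordered = sorted(bands, key=lambda b: b.lower_hu)
    for a, b in zip(ordered, ordered[1:]):
        if b.lower_hu < a.upper_hu:
            raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")


def split_bands(
    hu_slice: HUSlice, bands: Sequence[BandDefinition] | None = None
) -> list[BandLayer]:
    """Split a slice into one :class:`BandLayer` per band.

    Pixels whose HU lies in no band (interval gaps, out-of-range values,
    ROI-excluded sentinels) appear in no layer.  Bands must be pairwise
    disjoint, so with the defaults the layers partition the retained pixels.
    """
    if bands is None:
        bands = default_bands()
    _check_disjoint(bands)
    layers = []
    for band in bands:
        rr, cc = np.nonzero(band.contains(hu_slice.values))
        layers.append(
            BandLayer(
                band=band,
                rows=rr,
                cols=cc,
                hus=hu_slice.values[rr, cc],
                source_shape=hu_slice.shape,
                pixel_spacing_mm=hu_slice.pixel_spacing_mm,
            )
        )
    return layers


def bands_from_config(entries: Iterable[dict]) -> list[BandDefinition]:
    """Build a band set from config mappings with keys name/lower_hu/upper_hu."""
    bands = [
        BandDefinition(str(e["name"]), int(e["lower_hu"]), int(e["upper_hu"]))
        for e in entries
    ]
    _check_disjoint(bands)
    return bands
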