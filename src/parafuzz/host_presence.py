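"""Host/host-crop presence masking.

The parasitoid is assumed to persist only where its host (the tomato
pinworm) can occur and where the host's crops grow. Operationally the model
domain is the set of pixels where (i) the host habitat-suitability
probability exceeds a threshold (default 0.2 — the host is resilient over
a wide temperature range, so a permissive cutoff is used) and (ii) the
land-use/land-cover class is cropland. The comparison is strictly greater
than the threshold: a pixel at exactly 0.2 is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import GeometryError, Raster

__all__ = [
    "SuitabilitySurface",
    "LandCoverGrid",
    "PresenceMask",
    "presence_mask",
    "DEFAULT_SUITABILITY_THRESHOLD",
]

DEFAULT_SUITABILITY_THRESHOLD = 0.2
MASK_NODATA = 255  # uint8 sentinel in mask grids


@dataclass(frozen=True)
class SuitabilitySurface:
    """Habitat-suitability probabilities in [0, 1] (niche-model output contract)."""

    raster: Raster

    def __post_init__(self) -> None:
        vals = self.raster.valid_values()
        if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass(frozen=True)
class LandCoverGrid:
    """Categorical land-use/land-cover codes with a legend and cropland codes."""

    raster: Raster
    legend: dict[int, str]
    cropland_codes: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cropland_codes", frozenset(self.cropland_codes))
        codes = np.unique(self.raster.valid_values())
        unknown = set(int(c) for c in codes) - set(self.legend)
        if unknown:
            raise ValueError(f"LULC codes missing from legend: {sorted(unknown)}")
        if not self.cropland_codes <= set(self.legend):
            raise ValueError("cropland codes must appear in the legend")


@dataclass(frozen=True)
class PresenceMask:
    """Boolean evaluation domain stored as uint8 (1 present, 0 absent, 255 nodata)."""

    raster: Raster

    def to_bool(self) -> np.ndarray:
        """True where present; nodata pixels are False."""
        return self.raster.data == 1

    def count(self) -> int:
        return int(self.to_bool().sum())

    def nodata_mask(self) -> np.ndarray:
        return self.raster.nodata_mask()


def presence_mask(
    s: SuitabilitySurface,
    l: LandCoverGrid,
    threshold: float = DEFAULT_SUITABILITY_THRESHOLD,
    cropland_codes: set[int] | None = None,
) -> PresenceMask:
    """Pixels where suitability > threshold (strict) AND the class is cropland.

    Nodata in either input propagates to nodata in the mask. Inputs must
    share grid geometry exactly (resample first if they do not).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not s.raster.geometry.same_as(l.raster.geometry):
        raise GeometryError("suitability and land-cover grids are not aligned")
    codes = l.cropland_codes if cropland_codes is None else frozenset(cropland_codes)
    nodata = s.raster.nodata_mask() | l.raster.nodata_mask()
    present = (s.raster.data > threshold) & np.isin(l.raster.data, list(codes))
    out = np.where(nodata, MASK_NODATA, present.astype(np.uint8)).astype(np.uint8)
    return PresenceMask(Raster(out, s.raster.geometry, nodata=MASK_NODATA))
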