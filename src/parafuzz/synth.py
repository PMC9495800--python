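"""Synthetic landscape generator: every input the pipeline needs.

Emulates a six-region tomato-growing landscape with the published
1991-2021 monthly mean-temperature climatology per region (Western,
Nyanza, Rift Valley, Central, Eastern, Coast). Regions are laid out as
contiguous vertical bands by areal fraction — the simplest geometry with
exact expected counts for conservation checks. Per pixel:

* monthly temperature = the region's monthly mean + seeded Gaussian noise;
* host habitat suitability = a logistic function of the pixel's annual
  mean temperature plus noise, clipped to [0, 1] — a stand-in, synthetic
  surrogate for a niche-model probability surface, preserving the only
  contract downstream code uses (a probability grid correlated with
  climate);
* land cover = cropland with a per-region probability, the remainder
  split among grassland / forest / bareland.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .host_presence import LandCoverGrid, SuitabilitySurface
from .pipeline import MONTHS, TemperatureStack
from .raster import GridGeometry, Raster, write_raster

__all__ = [
    "RegionClimate",
    "SyntheticLandscapeSpec",
    "SyntheticLandscape",
    "REGIONAL_CLIMATOLOGY",
    "DEFAULT_LEGEND",
    "DEFAULT_CROPLAND_CODES",
    "default_spec",
    "generate",
    "write_bundle",
]

# 1991-2021 monthly mean temperatures (degC) per tomato-growing region,
# January -> December.
REGIONAL_CLIMATOLOGY: dict[str, tuple[float, ...]] = {
    "Western": (21.0, 21.9, 21.6, 20.5, 19.5, 18.6,
                18.2, 18.3, 19.0, 19.7, 19.8, 20.2),
    "Nyanza": (23.6, 24.6, 23.9, 22.8, 22.5, 22.4,
               22.5, 22.7, 23.2, 23.2, 22.7, 22.9),
    "Rift Valley": (18.9, 19.5, 19.3, 18.1, 17.2, 16.4,
                    16.1, 16.5, 17.5, 18.3, 17.7, 18.1),
    "Central": (19.3, 20.0, 19.8, 18.6, 17.7, 16.8,
                16.3, 16.7, 17.9, 18.6, 17.8, 18.2),
    "Eastern": (19.6, 20.5, 20.4, 19.5, 18.7, 17.8,
                17.2, 17.6, 18.8, 19.6, 18.7, 18.7),
    "Coast": (27.9, 28.1, 28.7, 28.1, 26.6, 25.9,
              25.4, 25.5, 26.2, 26.8, 27.2, 27.7),
}

DEFAULT_LEGEND = {1: "cropland", 2: "grassland", 3: "forest", 4: "bareland"}
DEFAULT_CROPLAND_CODES = frozenset({1})
_NONCROP_CODES = (2, 3, 4)
_NONCROP_WEIGHTS = (0.75, 0.15, 0.10)  # grass-dominated landscape


@dataclass(frozen=True)
class RegionClimate:
    """One region: name, 12 monthly mean temperatures, areal and cropland fractions."""

    name: str
    monthly_temps: tuple[float, ...]
    areal_fraction: float
    cropland_fraction: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "monthly_temps", tuple(float(t) for t in self.monthly_temps))
        if len(self.monthly_temps) != 12:
            raise ValueError(f"{self.name}: need 12 monthly temperatures")
        if not (0.0 <= self.areal_fraction <= 1.0):
            raise ValueError(f"{self.name}: areal fraction outside [0, 1]")
        if not (0.0 <= self.cropland_fraction <= 1.0):
            raise ValueError(f"{self.name}: cropland fraction outside [0, 1]")

    def month(self, name_or_number: str | int) -> float:
        if isinstance(name_or_number, int):
            return self.monthly_temps[name_or_number - 1]
        return self.monthly_temps[MONTHS.index(name_or_number)]


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Landscape recipe: grid size, regional climate, noise and suitability model.

    temp_noise_sd: pixel-level spatial scatter around the regional monthly
    mean (degC). suit_midpoint/suit_slope: logistic linking annual mean
    temperature to host suitability (probability 0.5 at the midpoint,
    slope per degC). suit_noise_sd: probability-scale noise before clipping.
    """

    nrows: int = 200
    ncols: int = 200
    regions: tuple[RegionClimate, ...] = ()
    temp_noise_sd: float = 0.5
    suit_midpoint: float = 18.0
    suit_slope: float = 0.8
    suit_noise_sd: float = 0.05
    pixel_size: float = 1000.0  # metres
    crs: str = "EPSG:3857"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.regions:
            raise ValueError("spec needs at least one region")
        total = sum(r.areal_fraction for r in self.regions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"areal fractions must sum to 1, got {total}")
        for sd in (self.temp_noise_sd, self.suit_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")

    def region(self, name: str) -> RegionClimate:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def geometry(self) -> GridGeometry:
        return GridGeometry(
            nrows=self.nrows, ncols=self.ncols,
            origin_x=0.0, origin_y=float(self.nrows) * self.pixel_size,
            pixel_width=self.pixel_size, pixel_height=-self.pixel_size,
            crs=self.crs,
        )

    def with_overrides(self, **kwargs) -> "SyntheticLandscapeSpec":
        """Copy with scalar fields replaced (regions stay unless given)."""
        return replace(self, **kwargs)

    def summary(self) -> dict:
        return {
            "nrows": self.nrows, "ncols": self.ncols,
            "regions": [r.name for r in self.regions],
            "temp_noise_sd": self.temp_noise_sd,
            "suit_midpoint": self.suit_midpoint,
            "suit_slope": self.suit_slope,
            "suit_noise_sd": self.suit_noise_sd,
        }

    def to_yaml(self, path) -> None:
        doc = {
            "nrows": self.nrows, "ncols": self.ncols,
            "temp_noise_sd": self.temp_noise_sd,
            "suit_midpoint": self.suit_midpoint,
            "suit_slope": self.suit_slope,
            "suit_noise_sd": self.suit_noise_sd,
            "pixel_size": self.pixel_size,
            "crs": self.crs,
            "regions": [
                {"name": r.name, "monthly_temps": list(r.monthly_temps),
                 "areal_fraction": r.areal_fraction,
                 "cropland_fraction": r.cropland_fraction}
                for r in self.regions
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticLandscapeSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        regions = tuple(
            RegionClimate(r["name"], tuple(r["monthly_temps"]),
                          r["areal_fraction"], r.get("cropland_fraction", 0.4))
            for r in doc.pop("regions")
        )
        return cls(regions=regions, **doc)


def default_spec() -> SyntheticLandscapeSpec:
    """Six regions with the published climatology, equal areal fractions.

    Cropland fraction defaults to 0.4 per region (the landscape is
    grass-dominated with roughly a third to two-fifths cropland), pixel
    temperature scatter 0.5 degC, and a logistic suitability surrogate
    centred at 18 degC annual mean.
    """
    n = len(REGIONAL_CLIMATOLOGY)
    regions = tuple(
        RegionClimate(name, temps, areal_fraction=1.0 / n)
        for name, temps in REGIONAL_CLIMATOLOGY.items()
    )
    return SyntheticLandscapeSpec(regions=regions)


@dataclass(frozen=True)
class SyntheticLandscape:
    """Generated input bundle for one seed."""

    temperatures: TemperatureStack
    suitability: SuitabilitySurface
    landcover: LandCoverGrid
    regions: Raster
    region_names: dict[int, str]
    spec: SyntheticLandscapeSpec
    seed: int


def _region_grid(spec: SyntheticLandscapeSpec, geom: GridGeometry) -> np.ndarray:
    """Vertical-band region codes (1-based) from cumulative areal fractions."""
    fractions = np.array([r.areal_fraction for r in spec.regions])
    edges = np.round(np.cumsum(fractions) * spec.ncols).astype(int)
    codes = np.zeros(spec.ncols, dtype=np.int16)
    start = 0
    for i, stop in enumerate(edges, start=1):
        codes[start:stop] = i
        start = stop
    codes[start:] = len(spec.regions)  # guard against rounding shortfall
    return np.broadcast_to(codes, (spec.nrows, spec.ncols)).copy()


def generate(spec: SyntheticLandscapeSpec, seed: int) -> SyntheticLandscape:
    """Draw one landscape: temperature stack, suitability, LULC, region grid."""
    rng = np.random.default_rng(int(seed))
    geom = spec.geometry()
    region_codes = _region_grid(spec, geom)

    mean_by_month = np.array([r.monthly_temps for r in spec.regions])  # (R, 12)
    layers = []
    annual_sum = np.zeros((spec.nrows, spec.ncols))
    for m in range(12):
        base = mean_by_month[region_codes - 1, m]
        noise = (rng.normal(0.0, spec.temp_noise_sd, size=base.shape)
                 if spec.temp_noise_sd > 0 else 0.0)
        grid = base + noise
        annual_sum += grid
        layers.append(Raster(grid.astype(np.float32), geom, nodata=np.nan))
    temps = TemperatureStack(tuple(layers))

    annual_mean = annual_sum / 12.0
    logistic = 1.0 / (1.0 + np.exp(-spec.suit_slope * (annual_mean - spec.suit_midpoint)))
    if spec.suit_noise_sd > 0:
        logistic = logistic + rng.normal(0.0, spec.suit_noise_sd, size=logistic.shape)
    suit = SuitabilitySurface(
        Raster(np.clip(logistic, 0.0, 1.0).astype(np.float32), geom, nodata=np.nan)
    )

    crop_frac = np.array([r.cropland_fraction for r in spec.regions])
    u = rng.random(size=(spec.nrows, spec.ncols))
    is_crop = u < crop_frac[region_codes - 1]
    others = rng.choice(_NONCROP_CODES, size=(spec.nrows, spec.ncols),
                        p=_NONCROP_WEIGHTS)
    codes = np.where(is_crop, 1, others).astype(np.int16)
    lulc = LandCoverGrid(Raster(codes, geom, nodata=-1),
                         dict(DEFAULT_LEGEND), DEFAULT_CROPLAND_CODES)

    region_names = {i + 1: r.name for i, r in enumerate(spec.regions)}
    return SyntheticLandscape(
        temperatures=temps,
        suitability=suit,
        landcover=lulc,
        regions=Raster(region_codes, geom, nodata=-1),
        region_names=region_names,
        spec=spec,
        seed=int(seed),
    )


def write_bundle(land: SyntheticLandscape, outdir) -> dict:
    """Write the landscape in the formats the pipeline reads; returns the
    ``inputs`` mapping a PipelineConfig can consume directly."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    temp_paths = []
    for m, lay in enumerate(land.temperatures.layers, start=1):
        p = out / f"temp_{m:02d}.tif"
        write_raster(lay, p)
        temp_paths.append(str(p))
    write_raster(land.suitability.raster, out / "suitability.tif")
    write_raster(land.landcover.raster, out / "landcover.tif")
    write_raster(land.regions, out / "regions.tif")
    land.spec.to_yaml(out / "landscape_spec.yaml")
    inputs = {
        "temperature": temp_paths,
        "suitability": str(out / "suitability.tif"),
        "landcover": str(out / "landcover.tif"),
        "regions": str(out / "regions.tif"),
        "legend": {int(k): v for k, v in land.landcover.legend.items()},
        "cropland_codes": sorted(int(c) for c in land.landcover.cropland_codes),
        "region_names": {int(k): v for k, v in land.region_names.items()},
    }
    with open(out / "inputs.yaml", "w") as fh:
        yaml.safe_dump(inputs, fh, sort_keys=False)
    return inputs
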