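"""Spatio-temporal application of the calibrated fuzzy system.

For each calendar month the calibrated Mamdani system is evaluated on the
monthly mean-temperature grid, restricted to the host/host-crop presence
mask, giving a continuous net-reproductive-rate (R0) surface plus a
categorical performance class per pixel. A climate scenario is a uniform
temperature shift of the whole monthly stack (default +2 degC for the
mid-century future case). Per-region pixel counts of each performance class
per month summarize the maps.

Performance classes are lower-inclusive bins on R0 with an open-ended top
class; the defaults put "very-poor" below replacement (R0 < 1) and
"optimal" at R0 >= 10, bracketing the laboratory optimum of 14-15
daughters/female.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    CalibrationResult,
    default_calibration_table,
    fit,
    load_calibration_csv,
    metrics_dict,
)
from .fuzzy import InferenceConfig, RuleBase, load_rule_base, predict_r0_many, save_rule_base
from .host_presence import (
    LandCoverGrid,
    PresenceMask,
    SuitabilitySurface,
    presence_mask,
)
from .raster import GeometryError, GridGeometry, Raster, read_raster, write_raster

__all__ = [
    "MONTHS",
    "TemperatureStack",
    "ClassScheme",
    "ScenarioConfig",
    "PerformanceMap",
    "PipelineConfig",
    "PipelineResult",
    "default_scheme",
    "predict_month",
    "classify",
    "apply_scenario",
    "pixel_counts",
    "run_pipeline",
]

MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)

CLASS_NODATA = 255


@dataclass(frozen=True)
class TemperatureStack:
    """Twelve monthly mean-temperature grids (degC), January to December."""

    layers: tuple[Raster, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) != 12:
            raise ValueError(f"expected 12 monthly layers, got {len(self.layers)}")
        geom = self.layers[0].geometry
        for i, lay in enumerate(self.layers):
            if not lay.geometry.same_as(geom):
                raise GeometryError(f"layer {i + 1} geometry differs from January")
        for i, lay in enumerate(self.layers):
            vals = lay.valid_values()
            if vals.size and (vals.min() < -20.0 or vals.max() > 60.0):
                warnings.warn(
                    f"{MONTHS[i]} temperatures outside -20..60 degC",
                    stacklevel=2,
                )

    @property
    def geometry(self) -> GridGeometry:
        return self.layers[0].geometry

    def month(self, number: int) -> Raster:
        """1-based calendar month."""
        return self.layers[number - 1]


@dataclass(frozen=True)
class ClassScheme:
    """Ordered performance classes with lower-inclusive R0 boundaries.

    ``lower_bounds`` must start at 0 and increase strictly; the last class
    is open-ended, so the scheme is exhaustive over [0, inf).
    """

    labels: tuple[str, ...] = ("very-poor", "poor", "good", "optimal")
    lower_bounds: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "lower_bounds", tuple(float(b) for b in self.lower_bounds))
        if len(self.labels) != len(self.lower_bounds):
            raise ValueError("one lower bound per class label required")
        if self.lower_bounds[0] != 0.0:
            raise ValueError("first class must start at 0")
        if np.any(np.diff(self.lower_bounds) <= 0):
            raise ValueError("class boundaries must increase strictly")

    def classify_values(self, r0: np.ndarray) -> np.ndarray:
        """R0 values -> integer class codes 0..k-1 (lower-inclusive bins)."""
        return (np.digitize(r0, self.lower_bounds[1:], right=False)
                .astype(np.uint8))


def default_scheme() -> ClassScheme:
    return ClassScheme()


@dataclass(frozen=True)
class ScenarioConfig:
    """Named uniform temperature shift; 'current' is delta_T = 0."""

    scenario: str = "current"
    delta_t: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_t):
            raise ValueError("delta_t must be finite")
        if not self.label:
            object.__setattr__(self, "label", self.scenario)


@dataclass(frozen=True)
class PerformanceMap:
    """One month's continuous R0 surface plus its class grid."""

    month: int  # 1..12
    r0: Raster
    classes: Raster


def predict_month(
    rb: RuleBase,
    cfg: InferenceConfig,
    temp_grid: Raster,
    mask: PresenceMask,
) -> Raster:
    """Per-pixel crisp R0 on the masked domain; elsewhere nodata (NaN).

    Identical to calling the scalar predictor pixel by pixel (same kernel,
    vectorized); pixels where no rule fires get R0 = 0.
    """
    if not temp_grid.geometry.same_as(mask.raster.geometry):
        raise GeometryError("temperature grid and presence mask are not aligned")
    domain = mask.to_bool() & ~temp_grid.nodata_mask()
    out = np.full(temp_grid.data.shape, np.nan, dtype=np.float64)
    temps = temp_grid.data[domain].astype(float)
    if temps.size:
        r0, _ = predict_r0_many(rb, cfg, temps)
        out[domain] = r0
    return Raster(out.astype(np.float32), temp_grid.geometry, nodata=np.nan)


def classify(r0_grid: Raster, scheme: ClassScheme) -> Raster:
    """Class-code grid (uint8) from an R0 grid; nodata propagates as 255."""
    nodata = r0_grid.nodata_mask()
    codes = scheme.classify_values(np.nan_to_num(r0_grid.data, nan=0.0))
    codes = np.where(nodata, CLASS_NODATA, codes).astype(np.uint8)
    return Raster(codes, r0_grid.geometry, nodata=CLASS_NODATA)


def apply_scenario(ts: TemperatureStack, sc: ScenarioConfig) -> TemperatureStack:
    """Uniform shift of every defined pixel by delta_T; zero shift is identity."""
    if sc.delta_t == 0.0:
        return ts
    shifted = []
    for lay in ts.layers:
        nodata = lay.nodata_mask()
        data = np.where(nodata, lay.data, lay.data + sc.delta_t)
        shifted.append(Raster(data, lay.geometry, nodata=lay.nodata))
    return TemperatureStack(tuple(shifted))


def pixel_counts(
    class_maps: Sequence[Raster],
    regions: Raster,
    scheme: ClassScheme,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Exact class-pixel tallies per region x month x class.

    Rows are complete (zero counts included) and sorted, so the table is
    byte-stable across runs. Only pixels with a defined class (i.e. inside
    the presence mask and with valid inputs) are counted.
    """
    geom = regions.geometry
    region_nod = regions.nodata_mask()
    codes = np.unique(regions.data[~region_nod]).astype(int)
    names = {int(c): (region_names or {}).get(int(c), f"region_{int(c)}")
             for c in codes}
    rows = []
    for m, cmap in enumerate(class_maps, start=1):
        if not cmap.geometry.same_as(geom):
            raise GeometryError(f"class map {m} not aligned with region grid")
        valid = ~cmap.nodata_mask() & ~region_nod
        for rc in codes:
            in_region = valid & (regions.data == rc)
            cls = cmap.data[in_region]
            binc = np.bincount(cls.astype(int), minlength=len(scheme.labels))
            for ci, label in enumerate(scheme.labels):
                rows.append(
                    {"region": names[int(rc)], "month": m, "class": label,
                     "pixel_count": int(binc[ci])}
                )
    df = pd.DataFrame(rows, columns=["region", "month", "class", "pixel_count"])
    return df.sort_values(["region", "month", "class"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end run


_CONFIG_KEYS = {
    "out_dir", "seed", "synthetic", "inputs", "rules_path", "calibration_csv",
    "suitability_threshold", "delta_t", "class_labels", "class_bounds",
    "output_grid", "defuzz_method",
}


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs.

    Inputs come either from the synthetic landscape generator (``synthetic``:
    keyword overrides for SyntheticLandscapeSpec, may be empty) or from files
    (``inputs``: paths for temperature (12 TIFFs), suitability, landcover,
    regions, plus legend/cropland codes and region names).
    """

    out_dir: str
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    rules_path: str | None = None
    calibration_csv: str | None = None
    suitability_threshold: float = 0.2
    delta_t: float = 2.0
    class_labels: tuple[str, ...] = ("very-poor", "poor", "good", "optimal")
    class_bounds: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0)
    output_grid: int = 501
    defuzz_method: str = "centroid"

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            self.synthetic = {}
        if self.synthetic is not None and self.inputs is not None:
            raise ValueError("give either synthetic overrides or input paths, not both")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def scheme(self) -> ClassScheme:
        return ClassScheme(tuple(self.class_labels), tuple(self.class_bounds))

    def inference(self) -> InferenceConfig:
        return InferenceConfig(output_grid=self.output_grid,
                               defuzz_method=self.defuzz_method)


@dataclass
class PipelineResult:
    """Maps, summaries and metrics of one end-to-end run."""

    current_maps: list[PerformanceMap]
    future_maps: list[PerformanceMap]
    current_summary: pd.DataFrame
    future_summary: pd.DataFrame
    mask: PresenceMask
    rule_base: RuleBase
    calibration: CalibrationResult | None
    metrics: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_file_inputs(inputs: dict):
    from .synth import DEFAULT_LEGEND, DEFAULT_CROPLAND_CODES

    temps = TemperatureStack(tuple(read_raster(p) for p in inputs["temperature"]))
    suit = SuitabilitySurface(read_raster(inputs["suitability"]))
    legend = {int(k): v for k, v in inputs.get("legend", DEFAULT_LEGEND).items()}
    crop = frozenset(inputs.get("cropland_codes", sorted(DEFAULT_CROPLAND_CODES)))
    lulc = LandCoverGrid(read_raster(inputs["landcover"]), legend, crop)
    regions = read_raster(inputs["regions"])
    region_names = {int(k): v for k, v in inputs.get("region_names", {}).items()}
    return temps, suit, lulc, regions, region_names


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Calibrate (or load) the fuzzy system, mask the landscape, and map
    current and future performance with per-region class summaries.

    Deterministic for fixed inputs and seed; writes GeoTIFF maps, two
    summary CSVs, a metrics JSON and a provenance log under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.inference()
    scheme = config.scheme()
    provenance: dict = {"seed": int(config.seed), "stage": []}

    # --- calibration stage
    try:
        calres: CalibrationResult | None = None
        if config.rules_path is not None:
            rb = load_rule_base(config.rules_path)
            provenance["rules_sha256"] = _sha256(Path(config.rules_path))
        else:
            points = (load_calibration_csv(config.calibration_csv)
                      if config.calibration_csv else default_calibration_table())
            calres = fit(points, cfg=cfg, seed=config.seed)
            rb = calres.rule_base
            save_rule_base(rb, out / "rules_fitted.yaml")
        provenance["stage"].append("calibration")
    except Exception as exc:
        raise RuntimeError(f"[calibration] {exc}") from exc

    # --- input stage
    try:
        if config.synthetic is not None:
            from .synth import SyntheticLandscapeSpec, default_spec, generate

            spec = (default_spec() if not config.synthetic
                    else default_spec().with_overrides(**config.synthetic))
            land = generate(spec, seed=config.seed)
            temps, suit, lulc = land.temperatures, land.suitability, land.landcover
            regions, region_names = land.regions, land.region_names
            provenance["synthetic_spec"] = spec.summary()
        else:
            temps, suit, lulc, regions, region_names = _load_file_inputs(config.inputs)
            provenance["input_sha256"] = {
                k: (_sha256(Path(v)) if isinstance(v, str) else
                    [_sha256(Path(p)) for p in v])
                for k, v in config.inputs.items()
                if k in ("temperature", "suitability", "landcover", "regions")
            }
        provenance["stage"].append("inputs")
    except Exception as exc:
        raise RuntimeError(f"[inputs] {exc}") from exc

    # --- masking stage
    try:
        mask = presence_mask(suit, lulc, threshold=config.suitability_threshold)
        provenance["stage"].append("mask")
    except Exception as exc:
        raise RuntimeError(f"[mask] {exc}") from exc

    # --- mapping stage
    try:
        scenarios = {
            "current": ScenarioConfig("current", 0.0),
            "future": ScenarioConfig("future", float(config.delta_t)),
        }
        maps: dict[str, list[PerformanceMap]] = {}
        summaries: dict[str, pd.DataFrame] = {}
        for name, sc in scenarios.items():
            stack = apply_scenario(temps, sc)
            month_maps = []
            for m in range(1, 13):
                r0 = predict_month(rb, cfg, stack.month(m), mask)
                cl = classify(r0, scheme)
                month_maps.append(PerformanceMap(m, r0, cl))
                write_raster(r0, out / f"r0_{name}_{m:02d}.tif")
                write_raster(cl, out / f"class_{name}_{m:02d}.tif")
            maps[name] = month_maps
            summary = pixel_counts([pm.classes for pm in month_maps],
                                   regions, scheme, region_names)
            summary.to_csv(out / f"summary_{name}.csv", index=False)
            summaries[name] = summary
        provenance["stage"].append("maps")
    except Exception as exc:
        raise RuntimeError(f"[maps] {exc}") from exc

    masked_total = mask.count()
    metrics = {
        "masked_pixels": masked_total,
        "delta_t_future": float(config.delta_t),
        "suitability_threshold": float(config.suitability_threshold),
        "calibration": metrics_dict(calres) if calres is not None else None,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    provenance.update({
        "config": {k: v for k, v in asdict(config).items()},
        "package": "parafuzz",
        "summary_sha256": {n: _sha256(out / f"summary_{n}.csv") for n in scenarios},
    })
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    return PipelineResult(
        current_maps=maps["current"],
        future_maps=maps["future"],
        current_summary=summaries["current"],
        future_summary=summaries["future"],
        mask=mask,
        rule_base=rb,
        calibration=calres,
        metrics=metrics,
        out_dir=out,
    )
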