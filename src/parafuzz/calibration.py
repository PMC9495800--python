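"""Fit fuzzy-system breakpoints to laboratory temperature-R0 data.

The rule base is anchored to the laboratory thermal-performance table for
the parasitoid: three temperature regimes (suboptimal low 10-15 degC,
optimal 20-25 degC, suboptimal high 30-35 degC) each map to an R0 regime.
Where the original system was tuned by expert knowledge, this module
formalizes the tuning as seeded, constrained least squares: free trapezoid
breakpoints are optimized by differential evolution followed by a
Nelder-Mead polish, minimizing the RMSE between the Mamdani prediction and
the observed R0 at the calibration temperatures, subject to a <= b <= c <= d
per set and coverage of the temperature universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .fuzzy import (
    FuzzyConfigError,
    FuzzyPartition,
    InferenceConfig,
    MembershipFunction,
    RuleBase,
    _mamdani_core,
    default_rule_base,
)

__all__ = [
    "CalibrationPoint",
    "CalibrationResult",
    "FreeParameter",
    "FitTemplate",
    "default_calibration_table",
    "default_template",
    "fit",
    "rmse",
    "r_squared",
    "load_calibration_csv",
    "save_calibration_csv",
    "metrics_dict",
]

_BP_INDEX = {"a": 0, "b": 1, "c": 2, "d": 3}
_PENALTY = 1.0e3


@dataclass(frozen=True)
class CalibrationPoint:
    """One laboratory (temperature degC, observed R0) pair."""

    temperature: float
    r0_observed: float

    def __post_init__(self) -> None:
        if self.r0_observed < 0:
            raise ValueError("observed R0 must be >= 0")


def default_calibration_table() -> list[CalibrationPoint]:
    """The six laboratory endpoints of the parasitoid thermal-response table.

    R0 collapses toward zero at both thermal extremes (0.13 at 10 degC,
    0.06 at 35 degC) and peaks at 14-15 daughters/female on the 20-25 degC
    optimum.
    """
    pairs = [(10.0, 0.13), (15.0, 1.55), (20.0, 15.0),
             (25.0, 14.0), (30.0, 2.18), (35.0, 0.06)]
    return [CalibrationPoint(t, r) for t, r in pairs]


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root mean square error, same units as the observations."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError(f"shape mismatch or empty: {p.shape} vs {o.shape}")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about mean(obs))."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("need >= 2 points with matching shapes")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observations have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((p - o) ** 2)) / ss_tot


@dataclass(frozen=True)
class FreeParameter:
    """One free breakpoint: which partition/set/corner, and its search bounds."""

    partition: str  # 'temperature' or 'r0'
    set_name: str
    breakpoint: str  # 'a' | 'b' | 'c' | 'd'
    bounds: tuple[float, float]


@dataclass(frozen=True)
class FitTemplate:
    """A base rule base plus the list of breakpoints the optimizer may move.

    Breakpoints not listed stay at their base values (anchors: the optimal
    temperature plateau, universe-edge shoulders).
    """

    base: RuleBase
    free: tuple[FreeParameter, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "free", tuple(self.free))
        for fp in self.free:
            part = (self.base.temp_partition if fp.partition == "temperature"
                    else self.base.r0_partition if fp.partition == "r0" else None)
            if part is None:
                raise FuzzyConfigError(f"unknown partition {fp.partition!r}")
            part[fp.set_name]  # raises KeyError if missing
            if fp.breakpoint not in _BP_INDEX:
                raise FuzzyConfigError(f"unknown breakpoint {fp.breakpoint!r}")
            lo, hi = fp.bounds
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise FuzzyConfigError(f"infeasible bounds {fp.bounds}")

    def bounds(self) -> list[tuple[float, float]]:
        return [fp.bounds for fp in self.free]

    def theta0(self) -> np.ndarray:
        """Base-rule-base values of the free breakpoints (clipped to bounds)."""
        vals = []
        for fp in self.free:
            part = (self.base.temp_partition if fp.partition == "temperature"
                    else self.base.r0_partition)
            v = part[fp.set_name].breakpoints[_BP_INDEX[fp.breakpoint]]
            lo, hi = fp.bounds
            vals.append(min(max(v, lo), hi))
        return np.array(vals)

    def _matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Substitute theta into copies of the two breakpoint matrices."""
        tb = self.base.temp_partition.breakpoint_matrix().copy()
        rb_ = self.base.r0_partition.breakpoint_matrix().copy()
        t_names = self.base.temp_partition.names
        r_names = self.base.r0_partition.names
        for fp, v in zip(self.free, theta):
            if fp.partition == "temperature":
                tb[t_names.index(fp.set_name), _BP_INDEX[fp.breakpoint]] = v
            else:
                rb_[r_names.index(fp.set_name), _BP_INDEX[fp.breakpoint]] = v
        return tb, rb_

    def build(self, theta: np.ndarray) -> RuleBase:
        """Materialize a validated RuleBase at parameter vector ``theta``."""
        tb, rbm = self._matrices(np.asarray(theta, dtype=float))
        temp = FuzzyPartition(
            universe=self.base.temp_partition.universe,
            units=self.base.temp_partition.units,
            sets=tuple(
                MembershipFunction(n, *row)
                for n, row in zip(self.base.temp_partition.names, tb)
            ),
        )
        r0 = FuzzyPartition(
            universe=self.base.r0_partition.universe,
            units=self.base.r0_partition.units,
            sets=tuple(
                MembershipFunction(n, *row)
                for n, row in zip(self.base.r0_partition.names, rbm)
            ),
        )
        return RuleBase(temp, r0, self.base.rules)


def default_template() -> FitTemplate:
    """Default free-parameter layout over the three-rule base.

    Anchored: the optimal temperature plateau at [20, 25] degC, the low
    set's left shoulder at the 10 degC universe edge, the high set's right
    shoulder at the 35 degC edge, and the near-zero left edges of the
    suboptimal R0 sets. Free: every remaining shoulder/plateau breakpoint.
    """
    base = default_rule_base()
    free = (
        FreeParameter("temperature", "suboptimal_low", "c", (10.0, 20.0)),
        FreeParameter("temperature", "suboptimal_low", "d", (10.0, 25.0)),
        FreeParameter("temperature", "optimal", "a", (10.0, 20.0)),
        FreeParameter("temperature", "optimal", "d", (25.0, 35.0)),
        FreeParameter("temperature", "suboptimal_high", "a", (20.0, 35.0)),
        FreeParameter("temperature", "suboptimal_high", "b", (20.0, 35.0)),
        FreeParameter("r0", "low_r0", "c", (0.0, 6.0)),
        FreeParameter("r0", "low_r0", "d", (0.0, 10.0)),
        FreeParameter("r0", "optimal_r0", "a", (5.0, 15.0)),
        FreeParameter("r0", "optimal_r0", "b", (10.0, 15.0)),
        FreeParameter("r0", "optimal_r0", "c", (14.0, 20.0)),
        FreeParameter("r0", "optimal_r0", "d", (14.0, 20.0)),
        FreeParameter("r0", "high_side_r0", "c", (0.0, 6.0)),
        FreeParameter("r0", "high_side_r0", "d", (0.0, 10.0)),
    )
    return FitTemplate(base, free)


@dataclass
class CalibrationResult:
    """Fitted rule base with in-sample accuracy metrics."""

    rule_base: RuleBase
    rmse: float
    r_squared: float
    residuals: np.ndarray  # predicted - observed, per point
    predictions: np.ndarray
    theta: np.ndarray
    history: list[float] = field(default_factory=list)  # best RMSE per iteration


def _make_objective(
    template: FitTemplate,
    cfg: InferenceConfig,
    temps: np.ndarray,
    obs: np.ndarray,
):
    """Fast penalized-RMSE objective operating on raw breakpoint matrices."""
    base_t = template.base.temp_partition
    base_r = template.base.r0_partition
    t_names, r_names = base_t.names, base_r.names
    ant_rows = [t_names.index(r.antecedent) for r in template.base.rules]
    cons_rows = [r_names.index(r.consequent) for r in template.base.rules]
    y = cfg.y_grid(base_r)
    probes = np.linspace(*base_t.universe, 257)

    def objective(theta: np.ndarray) -> float:
        tb, rbm = template._matrices(theta)
        viol = 0.0
        for m in (tb, rbm):
            diffs = np.diff(m, axis=1)
            viol += float(np.sum(np.maximum(-diffs, 0.0)))
        if viol > 0:
            return _PENALTY + viol
        # coverage of the temperature universe: every probe must fire a rule
        from .fuzzy import _trapezoid_degrees

        cover = _trapezoid_degrees(tb, probes).max(axis=1)
        uncovered = float(np.mean(cover <= 0.0))
        if uncovered > 0:
            return _PENALTY * (1.0 + uncovered)
        agg, _ = _mamdani_core(
            tb[ant_rows], rbm[cons_rows], base_t.universe, y, temps,
            cfg.out_of_range_policy,
        )
        total = agg.sum(axis=1)
        pred = np.where(total > 0, (agg @ y) / np.where(total > 0, total, 1.0), 0.0)
        return float(np.sqrt(np.mean((pred - obs) ** 2)))

    return objective


def fit(
    points: Sequence[CalibrationPoint],
    template: FitTemplate | None = None,
    cfg: InferenceConfig | None = None,
    seed: int = 0,
    maxiter: int = 300,
    popsize: int = 16,
) -> CalibrationResult:
    """Constrained least-squares fit of the free breakpoints.

    Global stage: differential evolution (seeded, elitist, hence a
    monotonically non-increasing best-RMSE history). Local stage:
    Nelder-Mead polish from the global best, accepted only if it improves.
    Deterministic for a fixed seed.
    """
    if template is None:
        template = default_template()
    if cfg is None:
        cfg = InferenceConfig()
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    if cfg.defuzz_method != "centroid":
        raise FuzzyConfigError("fitting currently supports centroid defuzzification")
    temps = np.array([p.temperature for p in points], dtype=float)
    obs = np.array([p.r0_observed for p in points], dtype=float)
    objective = _make_objective(template, cfg, temps, obs)
    bounds = template.bounds()

    history: list[float] = []

    def record(xk, convergence=None):  # DE best-so-far; elitist => monotone
        history.append(float(objective(xk)))

    result = differential_evolution(
        objective,
        bounds=bounds,
        seed=int(seed) % (2**31),
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-10,
        mutation=(0.3, 0.9),
        recombination=0.8,
        polish=False,
        updating="immediate",
        workers=1,
        callback=record,
        init="sobol",
    )
    theta, best = np.asarray(result.x), float(result.fun)

    polish = minimize(
        objective, theta, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000,
                 "maxfev": 40000},
    )
    if polish.fun <= best and np.all(
        [lo <= v <= hi for v, (lo, hi) in zip(polish.x, bounds)]
    ):
        theta, best = np.asarray(polish.x), float(polish.fun)
    history.append(best)

    fitted = template.build(theta)
    from .fuzzy import predict_r0_many

    pred, _ = predict_r0_many(fitted, cfg, temps)
    return CalibrationResult(
        rule_base=fitted,
        rmse=rmse(pred, obs),
        r_squared=r_squared(pred, obs),
        residuals=pred - obs,
        predictions=pred,
        theta=theta,
        history=history,
    )


# ---------------------------------------------------------------------------
# I/O


def load_calibration_csv(path) -> list[CalibrationPoint]:
    """Read a calibration table (columns: temperature_C, r0)."""
    df = pd.read_csv(path)
    missing = {"temperature_C", "r0"} - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    return [CalibrationPoint(float(t), float(r))
            for t, r in zip(df["temperature_C"], df["r0"])]


def save_calibration_csv(points: Sequence[CalibrationPoint], path) -> None:
    pd.DataFrame(
        {"temperature_C": [p.temperature for p in points],
         "r0": [p.r0_observed for p in points]}
    ).to_csv(path, index=False)


def metrics_dict(res: CalibrationResult) -> dict:
    """JSON-ready accuracy report."""
    return {
        "rmse": res.rmse,
        "r_squared": res.r_squared,
        "n_points": int(res.residuals.size),
        "residuals": [float(r) for r in res.residuals],
    }
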