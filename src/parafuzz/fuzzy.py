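"""Mamdani fuzzy inference over trapezoidal membership functions.

The engine predicts a parasitoid's net reproductive rate (R0, daughters per
female) from temperature through a small rule base of the form

    IF temperature is M_i THEN R0 is N_i

using the generalized modus ponens with max-min composition: a crisp
temperature x (singleton fuzzifier) fires rule i with strength
w_i = M_i(x); the rule output is the consequent clipped at w_i,
min(w_i, N_i(y)); the fired consequents are aggregated pointwise by max
over a discretized R0 universe; and a crisp R0 is recovered by centroid
(default) or mean-of-maxima defuzzification.

All set shapes are trapezoids (a, b, c, d): membership rises linearly on
(a, b), is 1 on the plateau [b, c], falls linearly on (c, d) and is 0
outside. Degenerate a == b or c == d gives a vertical edge with the
plateau taking precedence at the shared point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "MembershipFunction",
    "FuzzyPartition",
    "FuzzyRule",
    "RuleBase",
    "InferenceConfig",
    "membership_degree",
    "fuzzify",
    "infer",
    "defuzzify",
    "predict_r0",
    "predict_r0_detailed",
    "predict_r0_many",
    "default_rule_base",
    "rule_base_to_dict",
    "rule_base_from_dict",
    "save_rule_base",
    "load_rule_base",
]


class FuzzyConfigError(ValueError):
    """Invalid fuzzy-system configuration (breakpoints, names, rules)."""


def _trapezoid_degrees(bps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate trapezoid memberships for breakpoint rows ``bps`` at ``x``.

    bps has shape (k, 4) with rows (a, b, c, d); x has shape (n,).
    Returns shape (n, k). Plateau [b, c] takes precedence at degenerate
    vertical edges.
    """
    a, b, c, d = bps[:, 0], bps[:, 1], bps[:, 2], bps[:, 3]
    x = x[:, None]
    deg = np.zeros((x.shape[0], bps.shape[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = np.where(b > a, (x - a) / np.where(b > a, b - a, 1.0), 0.0)
        fall = np.where(d > c, (d - x) / np.where(d > c, d - c, 1.0), 0.0)
    deg = np.where((x > a) & (x < b), rise, deg)
    deg = np.where((x > c) & (x < d), fall, deg)
    deg = np.where((x >= b) & (x <= c), 1.0, deg)
    return np.clip(deg, 0.0, 1.0)


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoidal fuzzy set with breakpoints a <= b <= c <= d."""

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.a, self.b, self.c, self.d])):
            raise FuzzyConfigError(f"set {self.name!r}: non-finite breakpoints")
        if not (self.a <= self.b <= self.c <= self.d):
            raise FuzzyConfigError(
                f"set {self.name!r}: breakpoints must satisfy a <= b <= c <= d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    @property
    def breakpoints(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def degree(self, x: float | np.ndarray) -> float | np.ndarray:
        """Membership degree of ``x``, vectorized; always in [0, 1]."""
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        out = _trapezoid_degrees(np.array([self.breakpoints]), arr)[:, 0]
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    @property
    def support(self) -> tuple[float, float]:
        """Closure of {x : degree(x) > 0}."""
        return (self.a, self.d)


def membership_degree(mf: MembershipFunction, x: float) -> float:
    """Crisp value -> membership degree in [0, 1] (total function)."""
    return float(mf.degree(float(x)))


@dataclass(frozen=True)
class FuzzyPartition:
    """Named universe with an ordered list of trapezoidal sets.

    ``universe`` is (lo, hi) in ``units``; set names must be unique.
    ``covers_universe()`` reports whether every point of [lo, hi] belongs to
    at least one set with positive degree — required of antecedent
    partitions (so every in-range input fires a rule) and checked at
    RuleBase construction.
    """

    universe: tuple[float, float]
    sets: tuple[MembershipFunction, ...]
    units: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise FuzzyConfigError(f"invalid universe {self.universe}")
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise FuzzyConfigError(f"duplicate set names in partition: {names}")

    def __getitem__(self, name: str) -> MembershipFunction:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    def breakpoint_matrix(self) -> np.ndarray:
        return np.array([s.breakpoints for s in self.sets], dtype=float)

    def covers_universe(self, n_probe: int = 2001) -> bool:
        lo, hi = self.universe
        probes = np.linspace(lo, hi, n_probe)
        deg = _trapezoid_degrees(self.breakpoint_matrix(), probes)
        return bool(np.all(deg.max(axis=1) > 0.0))


@dataclass(frozen=True)
class FuzzyRule:
    """Single-antecedent rule: IF x is ``antecedent`` THEN y is ``consequent``."""

    antecedent: str
    consequent: str


@dataclass(frozen=True)
class RuleBase:
    """Temperature and R0 partitions plus the IF-THEN rules linking them."""

    temp_partition: FuzzyPartition
    r0_partition: FuzzyPartition
    rules: tuple[FuzzyRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if len(self.rules) == 0:
            raise FuzzyConfigError("rule base must contain at least one rule")
        for r in self.rules:
            if r.antecedent not in self.temp_partition.names:
                raise FuzzyConfigError(f"unknown antecedent set {r.antecedent!r}")
            if r.consequent not in self.r0_partition.names:
                raise FuzzyConfigError(f"unknown consequent set {r.consequent!r}")
        if not self.temp_partition.covers_universe():
            raise FuzzyConfigError(
                "temperature partition does not cover its universe; "
                "some in-range temperatures would fire no rule"
            )

    def antecedent_matrix(self) -> np.ndarray:
        """(n_rules, 4) breakpoints of each rule's temperature set."""
        return np.array(
            [self.temp_partition[r.antecedent].breakpoints for r in self.rules]
        )

    def consequent_matrix(self) -> np.ndarray:
        """(n_rules, 4) breakpoints of each rule's R0 set."""
        return np.array(
            [self.r0_partition[r.consequent].breakpoints for r in self.rules]
        )


@dataclass(frozen=True)
class InferenceConfig:
    """Numerical settings for inference.

    output_grid: points discretizing the R0 universe (uniform, >= 3).
    defuzz_method: 'centroid' (sum y*agg / sum agg) or 'mom' (mean of maxima).
    out_of_range_policy: 'zero' (temperatures outside the universe fire no
    rule) or 'clamp' (evaluate at the nearest universe bound).
    """

    output_grid: int = 501
    defuzz_method: Literal["centroid", "mom"] = "centroid"
    out_of_range_policy: Literal["zero", "clamp"] = "zero"

    def __post_init__(self) -> None:
        if self.output_grid < 3:
            raise FuzzyConfigError("output_grid must be >= 3")
        if self.defuzz_method not in ("centroid", "mom"):
            raise FuzzyConfigError(f"unknown defuzz method {self.defuzz_method!r}")
        if self.out_of_range_policy not in ("zero", "clamp"):
            raise FuzzyConfigError(
                f"unknown out-of-range policy {self.out_of_range_policy!r}"
            )

    def y_grid(self, r0_partition: FuzzyPartition) -> np.ndarray:
        lo, hi = r0_partition.universe
        return np.linspace(lo, hi, self.output_grid)


def fuzzify(
    partition: FuzzyPartition,
    x: float,
    policy: Literal["zero", "clamp"] = "zero",
) -> dict[str, float]:
    """Crisp value -> {set name: degree} across a partition.

    Out-of-universe x follows ``policy``: 'clamp' evaluates at the nearest
    bound, 'zero' returns all-zero degrees.
    """
    if not np.isfinite(x):
        raise ValueError(f"cannot fuzzify non-finite value {x!r}")
    lo, hi = partition.universe
    if x < lo or x > hi:
        if policy == "zero":
            return {name: 0.0 for name in partition.names}
        x = min(max(x, lo), hi)
    deg = _trapezoid_degrees(partition.breakpoint_matrix(), np.array([float(x)]))[0]
    return dict(zip(partition.names, deg.tolist()))


def _firing_strengths(
    ant_bps: np.ndarray,
    universe: tuple[float, float],
    temps: np.ndarray,
    policy: str,
) -> np.ndarray:
    """Rule firing strengths, shape (n_temps, n_rules); singleton fuzzifier."""
    lo, hi = universe
    t = np.asarray(temps, dtype=float)
    out_of_range = (t < lo) | (t > hi)
    if policy == "clamp":
        t = np.clip(t, lo, hi)
    w = _trapezoid_degrees(ant_bps, t)
    if policy == "zero":
        w[out_of_range, :] = 0.0
    return w


def _mamdani_core(
    ant_bps: np.ndarray,
    cons_bps: np.ndarray,
    universe: tuple[float, float],
    y_grid: np.ndarray,
    temps: np.ndarray,
    policy: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared max-min inference kernel.

    Returns (agg, w): agg is (n_temps, n_grid) aggregated output membership,
    w is (n_temps, n_rules) firing strengths. Used by both scalar inference
    and the vectorized raster/calibration paths so they are one code path.
    """
    w = _firing_strengths(ant_bps, universe, temps, policy)
    cons = _trapezoid_degrees(cons_bps, y_grid).T  # (n_rules, n_grid)
    # min(w_i, N_i(y_j)) then max over rules i
    agg = np.minimum(w[:, :, None], cons[None, :, :]).max(axis=1)
    return agg, w


def infer(rb: RuleBase, cfg: InferenceConfig, x: float) -> np.ndarray:
    """Aggregated output membership over the discretized R0 universe.

    Implements max-min composition with a singleton fuzzifier: for each rule
    the consequent set is clipped at the rule's firing strength and the
    clipped sets are combined pointwise by max.
    """
    if not np.isfinite(x):
        raise ValueError(f"cannot infer from non-finite input {x!r}")
    y = cfg.y_grid(rb.r0_partition)
    agg, _ = _mamdani_core(
        rb.antecedent_matrix(),
        rb.consequent_matrix(),
        rb.temp_partition.universe,
        y,
        np.array([float(x)]),
        cfg.out_of_range_policy,
    )
    return agg[0]


def defuzzify(
    agg: np.ndarray, cfg: InferenceConfig, y_grid: np.ndarray
) -> tuple[float, bool]:
    """Crisp R0 from an aggregated membership vector.

    Returns (value, fired). An all-zero aggregate means no rule fired; the
    fallback is (0.0, False) rather than an error so raster application
    never aborts on extreme pixels.
    """
    agg = np.asarray(agg, dtype=float)
    total = agg.sum()
    if total <= 0.0:
        return 0.0, False
    if cfg.defuzz_method == "centroid":
        return float((y_grid * agg).sum() / total), True
    peak = agg.max()
    at_max = y_grid[agg >= peak - 1e-12]
    return float(at_max.mean()), True


def predict_r0_detailed(
    rb: RuleBase, cfg: InferenceConfig, x: float
) -> tuple[float, bool]:
    """(crisp R0, fired flag) for one temperature."""
    agg = infer(rb, cfg, x)
    return defuzzify(agg, cfg, cfg.y_grid(rb.r0_partition))


def predict_r0(rb: RuleBase, cfg: InferenceConfig, x: float) -> float:
    """Crisp R0 (individuals/female) for one temperature (0 if no rule fires)."""
    return predict_r0_detailed(rb, cfg, x)[0]


def predict_r0_many(
    rb: RuleBase,
    cfg: InferenceConfig,
    temps: np.ndarray,
    chunk: int = 8192,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized predict_r0 over a 1-D temperature array.

    Identical math to the scalar path (same kernel); chunked to bound the
    (n, n_rules, n_grid) intermediate. Returns (r0 array, fired bool array).
    """
    temps = np.asarray(temps, dtype=float).ravel()
    if temps.size and not np.all(np.isfinite(temps)):
        raise ValueError("non-finite temperatures in input")
    y = cfg.y_grid(rb.r0_partition)
    ant = rb.antecedent_matrix()
    cons = rb.consequent_matrix()
    r0 = np.zeros(temps.shape)
    fired = np.zeros(temps.shape, dtype=bool)
    if cfg.defuzz_method != "centroid":
        for i, t in enumerate(temps):  # mean-of-maxima: scalar fallback
            r0[i], fired[i] = predict_r0_detailed(rb, cfg, float(t))
        return r0, fired
    for start in range(0, temps.size, chunk):
        sl = slice(start, start + chunk)
        agg, _ = _mamdani_core(
            ant, cons, rb.temp_partition.universe, y, temps[sl],
            cfg.out_of_range_policy,
        )
        total = agg.sum(axis=1)
        ok = total > 0.0
        fired[sl] = ok
        num = agg @ y
        r0[sl] = np.where(ok, num / np.where(ok, total, 1.0), 0.0)
    return r0, fired


# ---------------------------------------------------------------------------
# Default system and serialization


def default_rule_base() -> RuleBase:
    """Uncalibrated three-rule template.

    Temperature universe [10, 35] degC with suboptimal-low / optimal /
    suboptimal-high sets; the optimal plateau spans 20-25 degC. R0 universe
    [0, 20] daughters/female. Shoulder breakpoints are placeholders meant to
    be fitted against laboratory data (see parafuzz.calibration).
    """
    temp = FuzzyPartition(
        universe=(10.0, 35.0),
        units="degC",
        sets=(
            MembershipFunction("suboptimal_low", 10.0, 10.0, 14.0, 21.0),
            MembershipFunction("optimal", 15.0, 20.0, 25.0, 31.0),
            MembershipFunction("suboptimal_high", 26.0, 30.0, 35.0, 35.0),
        ),
    )
    r0 = FuzzyPartition(
        universe=(0.0, 20.0),
        units="individuals/female",
        sets=(
            MembershipFunction("low_r0", 0.0, 0.0, 1.0, 3.0),
            MembershipFunction("optimal_r0", 10.0, 14.0, 15.0, 17.0),
            MembershipFunction("high_side_r0", 0.0, 0.0, 1.0, 3.0),
        ),
    )
    rules = (
        FuzzyRule("suboptimal_low", "low_r0"),
        FuzzyRule("optimal", "optimal_r0"),
        FuzzyRule("suboptimal_high", "high_side_r0"),
    )
    return RuleBase(temp, r0, rules)


def _partition_to_dict(p: FuzzyPartition) -> dict:
    return {
        "universe": [float(p.universe[0]), float(p.universe[1])],
        "units": p.units,
        "sets": [
            {"name": s.name, "a": float(s.a), "b": float(s.b),
             "c": float(s.c), "d": float(s.d)}
            for s in p.sets
        ],
    }


def _partition_from_dict(d: dict) -> FuzzyPartition:
    return FuzzyPartition(
        universe=(float(d["universe"][0]), float(d["universe"][1])),
        units=d.get("units", ""),
        sets=tuple(
            MembershipFunction(s["name"], s["a"], s["b"], s["c"], s["d"])
            for s in d["sets"]
        ),
    )


def rule_base_to_dict(rb: RuleBase) -> dict:
    return {
        "temperature": _partition_to_dict(rb.temp_partition),
        "r0": _partition_to_dict(rb.r0_partition),
        "rules": [
            {"if": r.antecedent, "then": r.consequent} for r in rb.rules
        ],
    }


def rule_base_from_dict(d: dict) -> RuleBase:
    return RuleBase(
        temp_partition=_partition_from_dict(d["temperature"]),
        r0_partition=_partition_from_dict(d["r0"]),
        rules=tuple(FuzzyRule(r["if"], r["then"]) for r in d["rules"]),
    )


def save_rule_base(rb: RuleBase, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rule_base_to_dict(rb), fh, sort_keys=False)


def load_rule_base(path) -> RuleBase:
    with open(path) as fh:
        return rule_base_from_dict(yaml.safe_load(fh))
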