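# Methods

## Model

The core model is a single-input Mamdani fuzzy inference system linking
mean air temperature (°C) to the net reproductive rate R₀ of a parasitoid
(daughters per female per lifetime). The temperature universe [10, 35] °C
is partitioned into three trapezoidal sets — a suboptimal-low regime, an
optimal regime whose plateau is fixed at [20, 25] °C, and a
suboptimal-high regime — and the R₀ universe [0, 20] into three
consequent sets. Three single-antecedent rules connect them. Inference is
max–min composition with a singleton fuzzifier: a crisp temperature x
fires rule i with strength wᵢ = Mᵢ(x); the aggregated output membership is
N′(y) = maxᵢ min(wᵢ, Nᵢ(y)), evaluated on a uniform grid over the R₀
universe; the crisp output is the discrete centroid
∑ yⱼ N′(yⱼ) / ∑ N′(yⱼ) (mean-of-maxima is selectable).

Assumptions inherited from the underlying biology:

* the parasitoid persists wherever its host can persist, so the model
  domain is the host's suitable area;
* cropland pixels proxy the availability of the host's primary (tomato)
  and secondary (solanaceous) host plants;
* host presence is taken as suitability probability strictly greater
  than 0.2 (the host tolerates a wide thermal range, hence the permissive
  cutoff);
* parasitoid performance depends on temperature alone; other climatic
  drivers are treated as being at optimal levels.

## Trapezoid semantics and degenerate cases

A set (a, b, c, d) rises linearly on (a, b), is 1 on [b, c], falls on
(c, d) and is 0 outside; membership at x ≤ a and x ≥ d is exactly 0 and
the plateau is closed. When a = b (or c = d) the edge is vertical and the
plateau takes precedence at the shared point, so universe-edge shoulder
sets evaluate to 1 at the universe bound. All degrees are clipped to
[0, 1]; scalar, raster and calibration paths share one vectorized kernel,
so their results are identical to the last bit.

## Calibration

Laboratory data supply six (temperature, R₀) endpoint pairs over
10–35 °C. Rather than hand-tuning set shapes, the package treats the
shoulder and consequent breakpoints as free parameters and minimizes the
RMSE between the system's prediction and the observed R₀ at the
calibration temperatures, subject to a ≤ b ≤ c ≤ d per set and coverage
of the temperature universe (every in-range temperature must fire at
least one rule; violations are penalized and the final rule base is
re-validated). Anchored by design: the [20, 25] °C optimal plateau, the
10 °C and 35 °C universe-edge shoulders, and the left edges of the two
near-zero suboptimal R₀ sets. Free: the remaining 14 breakpoints, each
within explicit bounds.

The optimizer is two-stage and fully seeded: differential evolution
(Sobol initialization, immediate updating, population 16, up to 300
generations) followed by a Nelder–Mead polish accepted only when it
improves the objective and stays in bounds. Differential evolution is
elitist, so the recorded best-RMSE history is monotonically
non-increasing; a fixed seed reproduces the fit exactly. On the six-point
laboratory table the fitted system attains RMSE on the order of 10⁻³ or
below and R² ≈ 1.0 (seeds vary the last digits, never the conclusion).

Two structural points are worth making explicit:

* A centroid always lies strictly inside its aggregate's support, so R₀
  plateaus *anchored at the observed interval endpoints* (e.g. a low set
  with plateau [0.13, 1.55]) could never reproduce the endpoint values
  themselves; the consequent breakpoints are therefore fitted, and the
  calibrated suboptimal R₀ sets come out as narrow spikes near zero.
* The observed pairs give R₀(20) = 15 but R₀(25) = 14, so a system that
  reproduces the table cannot be constant across the whole optimal
  plateau: the fitted suboptimal-high temperature set overlaps the upper
  plateau, bending the output from 15 down to 14. Plateau constancy holds
  exactly on the sub-interval where only the optimal rule fires, and is
  tested there.
* Output-side (R₀) partition coverage of [0, 20] is not enforced:
  consequent coverage plays no role in Mamdani inference, and the
  calibrated consequents necessarily leave gaps. Antecedent coverage is
  enforced at rule-base construction. `FuzzyPartition.covers_universe()`
  lets callers check either partition explicitly.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| temperature universe | [10, 35] | °C | span of the laboratory trials |
| R₀ universe | [0, 20] | daughters/female | headroom above the observed max (15) avoids centroid truncation |
| output grid | 501 points | — | centroid error ≪ data precision; configurable ≥ 3 |
| defuzzification | centroid | — | standard Mamdani default; mean-of-maxima selectable |
| out-of-range policy | zero | — | no extrapolation beyond the trials: no rule fires, R₀ = 0, flagged |
| suitability threshold | 0.2 (strict >) | probability | permissive host cutoff; boundary pixels excluded by the strict inequality |
| future shift | +2.0 | °C | stated mid-century warming expectation; any uniform shift or user-supplied future rasters can substitute |
| class bounds | 1, 5, 10 | R₀ | very-poor = below replacement (R₀ < 1); optimal covers the laboratory optimum; fully configurable |

Classes are lower-inclusive with an open-ended top class, so every
non-negative R₀ maps to exactly one class and boundary pixels are
deterministic.

## Numerical and degenerate-input choices

* All-zero aggregates (no rule fired) defuzzify to R₀ = 0 with an
  explicit no-fire flag instead of raising, so raster application never
  aborts on extreme pixels.
* Mean-of-maxima averages all grid points within 10⁻¹² of the maximum.
* Engine-vs-brute-force agreement is asserted to 10⁻¹² (the computation
  is pure max/min/linear arithmetic).
* Grid geometries compare with a 10⁻⁹ coordinate tolerance; misaligned
  inputs are an error, with explicit nearest (categorical) / bilinear
  (continuous) resampling available. Bilinear never crosses nodata;
  categorical grids are never interpolated.
* Nodata propagates as the union of input nodata everywhere (mask,
  prediction, classing, zonal counts).

## Synthetic landscape

The generator emulates a six-region tomato-growing landscape carrying the
published 1991–2021 monthly mean-temperature climatology per region.
Regions are contiguous vertical bands sized by areal fraction (default:
equal sixths of a 200×200 grid of 1 km pixels) — the simplest geometry
with exact expected counts for conservation checks. Per pixel:

* monthly temperature = regional monthly mean + N(0, 0.5 °C) spatial
  noise (0.5 °C is a modest within-region spread; zero noise reproduces
  the climatology exactly and gives closed-form downstream checks);
* suitability = logistic(annual mean temperature; midpoint 18 °C, slope
  0.8 /°C) + N(0, 0.05), clipped to [0, 1] — a synthetic surrogate for a
  niche-model probability surface that preserves the one contract
  downstream code uses: a [0, 1] grid positively correlated with climate;
* land cover = cropland with probability 0.4 per region (a realistic
  cropland share for these mixed agricultural landscapes), the remainder
  grassland/forest/bareland at 0.75/0.15/0.10.

What the surrogate does **not** emulate: real geography (elevation
gradients, coastlines, spatial autocorrelation of land cover), observed
host-occurrence structure, or classification error in the land-cover
map. Passing tests therefore demonstrate the correctness and determinism
of the inference chain on inputs honouring the same contracts as the real
products — not the cartographic accuracy of any published map. Region-level
temperature contrasts (cool Rift Valley/Central vs hot Coast) are real,
so the qualitative scenario conclusions (warming helps on the rising
limb, hurts past the optimum) are meaningful.

## Problem sizes

Tests and the analysis drivers use the 200×200 default landscape
(40 000 pixels, ≈ 16 000 masked) for pipeline-level checks and smaller
grids (10×10 – 120×120) for statistical and fixture tests; the
brute-force inference oracle runs 1000 random systems on output grids of
3–51 points. These sizes give exact integer conservation checks and
tight Monte-Carlo bounds while keeping a full run in minutes on one CPU.

## Known limitations

* Temperature is the only climatic driver; humidity, rainfall and host
  population dynamics are outside the model.
* The future scenario is a uniform shift, not a downscaled climate
  projection; spatially varying futures can be supplied as rasters.
* Performance-class boundaries are a reporting convention, not a
  biological threshold; zonal counts depend on them.
* The calibration is in-sample over six points; no uncertainty is
  propagated onto the fitted breakpoints.
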