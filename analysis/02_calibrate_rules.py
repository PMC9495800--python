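"""Calibrate the fuzzy system against the laboratory thermal-response table.

Fits the free trapezoid breakpoints to the six (temperature, R0) pairs,
reports RMSE and R^2, and saves the fitted rule base for the mapping steps.
"""

import argparse
import json
from pathlib import Path

from parafuzz.calibration import default_calibration_table, fit, metrics_dict
from parafuzz.fuzzy import save_rule_base

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    points = default_calibration_table()
    res = fit(points, seed=args.seed)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    save_rule_base(res.rule_base, results / "rules_fitted.yaml")
    (results / "calibration_metrics.json").write_text(
        json.dumps(metrics_dict(res), indent=2))

    print("calibration against the 6-point laboratory table:")
    for p, pred in zip(points, res.predictions):
        print(f"  {p.temperature:5.1f} degC  observed R0 {p.r0_observed:6.2f}"
              f"  predicted {pred:6.2f}")
    print(f"RMSE = {res.rmse:.3g} daughters/female, R^2 = {res.r_squared:.4f}")
    print(f"rules -> {results / 'rules_fitted.yaml'}")


if __name__ == "__main__":
    main()
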