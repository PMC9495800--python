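"""Compare parasitoid performance between the current and +2 degC scenarios.

Reads the two summary tables written by 03_map_performance.py and reports,
per region, how the share of optimal-class pixels shifts under warming —
the tabular analogue of the monthly class-count charts.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def optimal_share(df: pd.DataFrame) -> pd.Series:
    totals = df.groupby("region")["pixel_count"].sum()
    optimal = (df[df["class"] == "optimal"]
               .groupby("region")["pixel_count"].sum())
    return (optimal / totals).fillna(0.0)


def main() -> None:
    results = ROOT / "results"
    current = pd.read_csv(results / "summary_current.csv")
    future = pd.read_csv(results / "summary_future.csv")

    cur_share, fut_share = optimal_share(current), optimal_share(future)
    table = pd.DataFrame({
        "optimal_share_current": cur_share.round(3),
        "optimal_share_future": fut_share.round(3),
        "change": (fut_share - cur_share).round(3),
    }).reset_index()
    table.to_csv(results / "scenario_comparison.csv", index=False)

    print("share of masked pixel-months in the optimal class (R0 >= 10):")
    print(table.to_string(index=False))
    improving = table[table["change"] > 0]["region"].tolist()
    declining = table[table["change"] < 0]["region"].tolist()
    print(f"\nwarming improves performance in: {', '.join(improving) or 'none'}")
    print(f"warming reduces performance in: {', '.join(declining) or 'none'}")
    print(f"table -> {results / 'scenario_comparison.csv'}")


if __name__ == "__main__":
    main()
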