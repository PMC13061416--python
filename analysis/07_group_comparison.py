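#!/usr/bin/env python
"""Genotype comparison of larval sleep metrics.

Compares the control and mutant cohorts scored by 02_score_larval_sleep.py
with Mann-Whitney U tests and Bonferroni correction over the declared
family (total sleep + wake speed = 2 comparisons), and writes
results/sleep_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from larvasleep.config import RunConfig
from larvasleep.pipeline import run_compare

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    groups = {}
    for name in ("control", "mutant"):
        path = RESULTS / f"metrics_{name}.csv"
        if not path.exists():
            raise SystemExit("run 02_score_larval_sleep.py first")
        groups[name] = pd.read_csv(path)
    frames = []
    for column in ("total_sleep_s", "wake_speed_mm_s"):
        df = run_compare(RunConfig(), groups, column=column, family_size=2)
        df.insert(0, "metric", column)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(RESULTS / "sleep_comparison.csv", index=False)
    for _, row in out.iterrows():
        print(f"{row['metric']}: control median {row['median_a']:.2f} "
              f"(Q1-Q3 {row['q1_a']:.2f}-{row['q3_a']:.2f}) vs mutant "
              f"{row['median_b']:.2f} ({row['q1_b']:.2f}-{row['q3_b']:.2f}); "
              f"U={row['U']:.0f}, p_adj={row['p_adj']:.3g}")


if __name__ == "__main__":
    main()
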