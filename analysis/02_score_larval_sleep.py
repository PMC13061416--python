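#!/usr/bin/env python
"""Score the simulated larval cohorts.

Runs pixel-change classification, 12-frame bout calling and wake-gated
locomotion on each cohort from 01_simulate_cohorts.py, writes per-animal
metrics to results/, and reports how well the scored sleep matches the
programmed ground truth.
"""

from pathlib import Path

from larvasleep.config import RunConfig
from larvasleep.pipeline import run_score_larva, score_against_truth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"
SEEDS = {"control": 11, "mutant": 22}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for name, seed in SEEDS.items():
        cfg = RunConfig(seed=seed)
        bundle = SCRATCH / name
        if not bundle.exists():
            raise SystemExit("run 01_simulate_cohorts.py first")
        df = run_score_larva(cfg, bundle, out_csv=RESULTS / f"metrics_{name}.csv")
        acc = score_against_truth(cfg, bundle)
        frac = df["total_sleep_s"].sum() / df["window_s"].sum()
        print(f"{name}: n={len(df)}, median total sleep "
              f"{df['total_sleep_s'].median():.0f} s, cohort sleep fraction "
              f"{frac:.3f}, frame accuracy vs truth {acc:.3f}, median wake "
              f"speed {df['wake_speed_mm_s'].median():.3f} mm/s")


if __name__ == "__main__":
    main()
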