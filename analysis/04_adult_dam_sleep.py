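#!/usr/bin/env python
"""Adult DAM sleep scoring on the simulated monitor file.

Parses the DAM2 text written by 01_simulate_cohorts.py, scores sleep with
the 5-min immobility criterion, splits it by the 9AM-9PM light cycle, and
writes results/adult_sleep.csv.
"""

from pathlib import Path

from larvasleep.config import RunConfig
from larvasleep.pipeline import run_score_adult

ROOT = Path(__file__).resolve().parents[1]
DAM = ROOT / "scratch" / "cohorts" / "control" / "dam" / "monitor01.txt"
RESULTS = ROOT / "results"


def main() -> None:
    if not DAM.exists():
        raise SystemExit("run 01_simulate_cohorts.py first")
    RESULTS.mkdir(exist_ok=True)
    df = run_score_adult(RunConfig(), DAM, out_csv=RESULTS / "adult_sleep.csv")
    ch1 = df.iloc[0]
    print(f"channel 1: total sleep {ch1['total_sleep_min']:.0f} min over two "
          f"days (programmed 420), day {ch1['day_sleep_min']:.0f} / night "
          f"{ch1['night_sleep_min']:.0f} min, {int(ch1['bout_count'])} bouts")


if __name__ == "__main__":
    main()
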