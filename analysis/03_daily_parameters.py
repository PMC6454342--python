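#!/usr/bin/env python
"""Compute the seven daily parameters from episode sequences.

Reads ``episodes.csv`` (from 02_extract_episodes.py), computes F, D, PF,
PD, RMSSD, SI and CI per user-day and writes ``daily_params.csv``.
Undefined values (degenerate days) are empty cells, not zeros.
"""

import argparse
from pathlib import Path

import pandas as pd

from screenuse import (
    StudyConfig,
    daily_parameters_table,
    days_from_frame,
    write_daily_parameters,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--episodes", type=Path, default=Path("results/episodes.csv"))
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--out", type=Path, default=Path("results/daily_params.csv"))
    args = parser.parse_args()

    config = StudyConfig.from_toml(args.config) if args.config else StudyConfig()
    frame = pd.read_csv(args.episodes)
    days = days_from_frame(frame)
    daily = daily_parameters_table(days, config)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_daily_parameters(daily, args.out)

    m = daily[["F", "D", "PF", "PD"]].mean()
    print(
        f"{len(daily)} user-days: mean F {m['F']:.1f}/day, "
        f"D {m['D'] / 3600:.2f} h/day, proactive {100 * m['PF'] / m['F']:.0f}% of "
        f"episodes and {100 * m['PD'] / m['D']:.0f}% of duration"
    )
    undef = daily[["RMSSD", "SI", "CI"]].isna().sum()
    print(f"undefined days - RMSSD: {undef['RMSSD']}, SI: {undef['SI']}, CI: {undef['CI']}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
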