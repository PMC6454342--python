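#!/usr/bin/env python
"""Segment raw events into daily use/nonuse episode sequences.

Pairs screen_on/screen_off events, classifies proactive vs reactive use by
the 60 s notification rule, splits at local midnight, drops each user's
first and last day, and flags sleep per the configured policy. Writes
``episodes.csv`` (one row per episode) and ``episodes_qc.json`` (anomaly
counts).
"""

import argparse
import json
from pathlib import Path

from screenuse import StudyConfig, days_to_frame, extract_days, read_events


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--events", type=Path, default=Path("results/events.csv"))
    parser.add_argument("--config", type=Path, default=None,
                        help="optional TOML overriding the default StudyConfig")
    parser.add_argument("--out", type=Path, default=Path("results/episodes.csv"))
    args = parser.parse_args()

    config = StudyConfig.from_toml(args.config) if args.config else StudyConfig()
    events, rejects = read_events(args.events)
    if rejects.n_rejected:
        print(f"rejected {rejects.n_rejected} malformed row(s):")
        for reason in rejects.reasons[:10]:
            print("  " + reason)
    days, qc = extract_days(events, config)
    frame = days_to_frame(days)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False)
    qc_path = args.out.with_name("episodes_qc.json")
    qc_path.write_text(json.dumps(qc.as_dict(), indent=2) + "\n")

    n_use = int((frame["kind"] == "use").sum())
    print(
        f"{len(days)} user-days -> {len(frame)} episodes ({n_use} use); "
        f"{qc.total_anomalies()} stream anomalies (see {qc_path.name})"
    )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
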