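"""Readers/writers for event logs, SPAI-5 tables and daily-parameter tables.

Formats are deliberately plain:

* event log — tidy CSV (or JSON-lines) with columns
  ``user_id,timestamp,event_type``; ISO 8601 timestamps with an explicit
  UTC offset; ``event_type`` one of ``screen_on`` / ``screen_off`` /
  ``notification``.
* SPAI-5 — CSV ``user_id,item1..item5``; items are 1-4 Likert responses.
* daily parameters — CSV ``user_id,date,F,D,PF,PD,RMSSD,SI,CI``; durations
  in seconds; undefined values serialize as empty cells (never sentinel
  numbers) and round-trip losslessly.

Readers are deterministic: identical input bytes yield identical in-memory
tables, with ties at equal timestamps kept in input order (stable sort).
Malformed rows are rejected and counted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple, Union

import pandas as pd

from .episodes import EVENT_NOTIFICATION, EVENT_SCREEN_OFF, EVENT_SCREEN_ON
from .parameters import PARAMETER_NAMES

VALID_EVENT_TYPES = frozenset({EVENT_SCREEN_ON, EVENT_SCREEN_OFF, EVENT_NOTIFICATION})

EVENT_COLUMNS = ["user_id", "timestamp", "event_type"]
SPAI_ITEM_COLUMNS = [f"item{i}" for i in range(1, 6)]


class FormatError(ValueError):
    """A file is structurally unusable (e.g. a required column is missing)."""


@dataclass
class RejectionReport:
    """Row/user-level rejections collected while reading a file."""

    n_rejected: int = 0
    reasons: List[str] = field(default_factory=list)

    def add(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons.append(reason)


def _require_columns(frame: pd.DataFrame, required: List[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Event logs


def read_events(
    path: Union[str, Path]
) -> Tuple[pd.DataFrame, RejectionReport]:
    """Read an event log (CSV or ``.jsonl`` JSON-lines) into a tidy table.

    Returns the events grouped by user and stably sorted by timestamp,
    together with a report of rejected rows (unparseable timestamps,
    unknown event types) identified by input line number.
    """
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson"}:
        frame = pd.read_json(path, lines=True, dtype={"user_id": str}, convert_dates=False)
        if len(frame) == 0:
            frame = pd.DataFrame(columns=EVENT_COLUMNS)
        header_offset = 1  # line numbers are 1-based data lines
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        header_offset = 2  # line 1 is the header
    _require_columns(frame, EVENT_COLUMNS, path)
    frame = frame[EVENT_COLUMNS].copy()

    report = RejectionReport()
    stamps = pd.to_datetime(frame["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad_time = stamps.isna()
    bad_type = ~frame["event_type"].isin(VALID_EVENT_TYPES)
    for idx in frame.index[bad_time]:
        report.add(f"line {idx + header_offset}: unparseable timestamp "
                   f"{frame.at[idx, 'timestamp']!r}")
    for idx in frame.index[~bad_time & bad_type]:
        report.add(f"line {idx + header_offset}: unknown event_type "
                   f"{frame.at[idx, 'event_type']!r}")
    keep = ~(bad_time | bad_type)
    out = frame[keep].copy()
    out["timestamp"] = stamps[keep]
    out = out.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
    return out, report


def write_events(events: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write an event table as tidy CSV with ISO 8601 offset timestamps."""
    out = events.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out[EVENT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SPAI-5


def read_spai5(path: Union[str, Path]) -> Tuple[pd.DataFrame, RejectionReport]:
    """Read SPAI-5 responses; totals are recomputed from the five items.

    Users with any item outside 1-4 (or non-integer) are rejected with a
    reason; a duplicated ``user_id`` is a format error.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"user_id": str})
    _require_columns(frame, ["user_id", *SPAI_ITEM_COLUMNS], path)
    if frame["user_id"].duplicated().any():
        dupes = frame.loc[frame["user_id"].duplicated(), "user_id"].unique()
        raise FormatError(f"{path}: duplicate user_id(s): {', '.join(map(str, dupes))}")

    report = RejectionReport()
    items = frame[SPAI_ITEM_COLUMNS].apply(pd.to_numeric, errors="coerce")
    whole = (items == items.round()).all(axis=1) & items.notna().all(axis=1)
    in_range = ((items >= 1) & (items <= 4)).all(axis=1)
    ok = whole & in_range
    for idx in frame.index[~ok]:
        report.add(f"user {frame.at[idx, 'user_id']}: item outside the 1-4 Likert range")
    out = frame[ok].copy()
    out[SPAI_ITEM_COLUMNS] = items[ok].astype(int)
    out["total"] = out[SPAI_ITEM_COLUMNS].sum(axis=1)
    return out.reset_index(drop=True), report


def write_spai5(spai: pd.DataFrame, path: Union[str, Path]) -> None:
    columns = ["user_id", *SPAI_ITEM_COLUMNS]
    spai[columns].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Daily parameter tables


def write_daily_parameters(daily: pd.DataFrame, path: Union[str, Path]) -> None:
    """One row per user-day; NaN (undefined) values become empty cells."""
    out = daily.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    for col in PARAMETER_NAMES:  # shortest round-trip repr; NaN -> empty cell
        out[col] = [
            "" if pd.isna(v) else (str(int(v)) if float(v).is_integer() else repr(float(v)))
            for v in out[col]
        ]
    out[["user_id", "date", *PARAMETER_NAMES]].to_csv(path, index=False)


def read_daily_parameters(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(
        path, dtype={"user_id": str}, parse_dates=["date"], float_precision="round_trip"
    )
    _require_columns(frame, ["user_id", "date", *PARAMETER_NAMES], path)
    return frame
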