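"""Segment raw screen events into daily alternating use/nonuse episode sequences.

A *use episode* runs from a screen-on event to the next screen-off; the waking
gaps between use episodes are *nonuse episodes*. Each calendar day (local
midnight to midnight, half-open) yields one :class:`DaySequence` whose episodes
strictly alternate use / nonuse and jointly tile the day. A use episode is
*proactive* when no notification arrived in the window (default 60 s) before
its screen-on, *reactive* otherwise. Sleep is identified per the configured
policy and the matching nonuse time is flagged so it contributes to no
parameter.

Internally times are float64 epoch seconds in the user's local clock; the
public containers expose datetimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    FixedWindow,
    LongestOvernightGap,
    NoSleepExclusion,
    SleepPolicy,
    StudyConfig,
)

DAY_S = 86400.0
_EPOCH = datetime(1970, 1, 1)

EVENT_SCREEN_ON = "screen_on"
EVENT_SCREEN_OFF = "screen_off"
EVENT_NOTIFICATION = "notification"


# ---------------------------------------------------------------------------
# QC bookkeeping


@dataclass
class QCReport:
    """Counts of event-stream anomalies resolved during pairing."""

    superseded_screen_on: int = 0   # a second screen_on arrived before a screen_off
    orphan_screen_off: int = 0      # screen_off with no pending screen_on
    unterminated_screen_on: int = 0  # trailing screen_on never closed
    zero_length_interval: int = 0   # on and off at the identical instant
    merged_zero_gap: int = 0        # consecutive uses touching exactly; merged

    def __iadd__(self, other: "QCReport") -> "QCReport":
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self

    def total_anomalies(self) -> int:
        return sum(getattr(self, f) for f in self.__dataclass_fields__)

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class Episode:
    """One use or nonuse interval within a day (half-open [start, end))."""

    kind: str                      # "use" | "nonuse"
    start: datetime
    end: datetime
    proactive: Optional[bool]      # defined iff kind == "use"
    sleep_excluded: Optional[bool]  # defined iff kind == "nonuse"

    @property
    def duration(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class DaySequence:
    """A day's strictly alternating episode sequence, array-backed.

    ``start``/``end`` are local epoch seconds; ``proactive`` is meaningful
    only where ``is_use`` and ``sleep_excluded`` only where ``~is_use``.
    """

    user_id: str
    date: date
    is_use: np.ndarray
    start: np.ndarray
    end: np.ndarray
    proactive: np.ndarray
    sleep_excluded: np.ndarray

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    def __len__(self) -> int:
        return len(self.is_use)

    def episodes(self) -> Iterator[Episode]:
        for i in range(len(self)):
            use = bool(self.is_use[i])
            yield Episode(
                kind="use" if use else "nonuse",
                start=_EPOCH + timedelta(seconds=float(self.start[i])),
                end=_EPOCH + timedelta(seconds=float(self.end[i])),
                proactive=bool(self.proactive[i]) if use else None,
                sleep_excluded=None if use else bool(self.sleep_excluded[i]),
            )

    def validate(self) -> None:
        """Raise if the alternation/tiling invariants are violated."""
        if len(self) == 0:
            return
        if np.any(self.end <= self.start):
            raise ValueError("episode with nonpositive duration")
        if np.any(self.start[1:] != self.end[:-1]):
            raise ValueError("episodes do not tile the day contiguously")
        if np.any(self.is_use[1:] == self.is_use[:-1]):
            raise ValueError("use/nonuse alternation violated")
        day0 = np.floor(self.start[0] / DAY_S)
        if _end_day_index(np.array([self.end[-1]]))[0] != day0:
            raise ValueError("episode crosses the day boundary")


# ---------------------------------------------------------------------------
# Pairing screen events into use intervals


def pair_screen_events(
    event_types: Sequence[str] | np.ndarray,
    times: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, QCReport]:
    """Match each screen_on to the next screen_off; resolve anomalies.

    Rules: a second screen_on before any screen_off supersedes the first
    (the later on wins); an orphan screen_off is dropped; zero-length
    intervals are dropped; consecutive intervals touching exactly
    (off == next on) are merged into one use episode. All resolutions are
    counted in the returned :class:`QCReport`.

    Parameters
    ----------
    event_types:
        Event labels aligned with ``times`` (time-ordered).
    times:
        Event instants, float epoch seconds.

    Returns
    -------
    (starts, ends, qc) — ordered, non-overlapping use intervals.
    """
    types = np.asarray(event_types)
    times = np.asarray(times, dtype=np.float64)
    qc = QCReport()
    screen_mask = types != EVENT_NOTIFICATION
    kinds = types[screen_mask]
    t = times[screen_mask]
    n = len(t)
    if n == 0:
        return np.empty(0), np.empty(0), qc

    is_on = kinds == EVENT_SCREEN_ON
    # Fast path: a perfectly alternating on/off/on/off... stream.
    if n % 2 == 0 and np.all(is_on[0::2]) and not np.any(is_on[1::2]):
        on, off = t[0::2], t[1::2]
    else:
        on_l: List[float] = []
        off_l: List[float] = []
        pending: Optional[float] = None
        for ti, oi in zip(t, is_on):
            if oi:
                if pending is not None:
                    qc.superseded_screen_on += 1
                pending = ti
            else:
                if pending is None:
                    qc.orphan_screen_off += 1
                else:
                    on_l.append(pending)
                    off_l.append(ti)
                    pending = None
        if pending is not None:
            qc.unterminated_screen_on += 1
        on, off = np.asarray(on_l), np.asarray(off_l)

    # Drop zero-length intervals.
    zero = off <= on
    if np.any(zero):
        qc.zero_length_interval += int(zero.sum())
        on, off = on[~zero], off[~zero]
    # Merge runs of touching intervals (gap <= 0).
    if len(on) > 1:
        new_group = np.concatenate(([True], on[1:] - off[:-1] > 0))
        if not new_group.all():
            gid = np.cumsum(new_group) - 1
            first = new_group.nonzero()[0]
            merged_on = on[first]
            merged_off = np.maximum.reduceat(off, first)
            qc.merged_zero_gap += len(on) - len(merged_on)
            on, off = merged_on, merged_off
    return on, off, qc


# ---------------------------------------------------------------------------
# Proactive / reactive classification


def classify_proactive(
    start: float,
    notifications: np.ndarray,
    window: float = 60.0,
) -> bool:
    """True (proactive) iff no notification lies in ``[start - window, start)``.

    The window is half-open: a notification exactly at screen-on does not
    make the episode reactive.
    """
    notifications = np.asarray(notifications, dtype=np.float64)
    lo = np.searchsorted(notifications, start - window, side="left")
    hi = np.searchsorted(notifications, start, side="left")
    return bool(hi == lo)


def classify_proactive_many(
    starts: np.ndarray,
    notifications: np.ndarray,
    window: float = 60.0,
) -> np.ndarray:
    """Vectorized :func:`classify_proactive` over many episode starts."""
    starts = np.asarray(starts, dtype=np.float64)
    notifications = np.asarray(notifications, dtype=np.float64)
    lo = np.searchsorted(notifications, starts - window, side="left")
    hi = np.searchsorted(notifications, starts, side="left")
    return lo == hi


# ---------------------------------------------------------------------------
# Day assembly


def _end_day_index(t: np.ndarray) -> np.ndarray:
    """Day index containing the instant just before ``t`` (half-open ends).

    An end exactly at midnight belongs to the previous day; midnights are
    exactly representable in float epoch seconds, so no epsilon is needed.
    """
    d = np.floor(np.asarray(t) / DAY_S)
    return np.where(d * DAY_S == t, d - 1, d)


def _split_at_midnight(
    on: np.ndarray, off: np.ndarray, proactive: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split use intervals crossing local midnight; flags copy to both parts."""
    while True:
        d_on = np.floor(on / DAY_S)
        d_off = _end_day_index(off)
        crossing = d_off > d_on
        if not np.any(crossing):
            return on, off, proactive
        idx = crossing.nonzero()[0]
        cut = (d_on[idx] + 1.0) * DAY_S
        on = np.concatenate([on, cut])
        off_new = off.copy()
        off_new[idx] = cut
        off = np.concatenate([off_new, off[idx]])
        proactive = np.concatenate([proactive, proactive[idx]])
        order = np.argsort(on, kind="stable")
        on, off, proactive = on[order], off[order], proactive[order]


def build_day_sequences(
    user_id: str,
    on: np.ndarray,
    off: np.ndarray,
    proactive: np.ndarray,
    config: StudyConfig,
    record_span: Optional[Tuple[float, float]] = None,
) -> List[DaySequence]:
    """Assemble per-day alternating sequences from classified use intervals.

    Intervals are split at local midnight, gaps become nonuse episodes
    (including the partial gaps bounded by midnight before the first and
    after the last use of the day), and — when
    ``config.exclude_first_last_day`` — each user's first and last calendar
    day is dropped as incomplete.

    Parameters
    ----------
    record_span:
        (first, last) epoch seconds of the user's raw record, used to decide
        which calendar days are the first/last; defaults to the span of the
        use intervals themselves.
    """
    on = np.asarray(on, dtype=np.float64)
    off = np.asarray(off, dtype=np.float64)
    proactive = np.asarray(proactive, dtype=bool)
    if len(on) == 0:
        return []
    on, off, proactive = _split_at_midnight(on, off, proactive)

    if record_span is None:
        record_span = (float(on[0]), float(off[-1]))
    first_day = int(np.floor(record_span[0] / DAY_S))
    last_day = int(_end_day_index(np.array([record_span[1]]))[0])
    days = range(first_day, last_day + 1)
    if config.exclude_first_last_day:
        days = range(first_day + 1, last_day)

    day_of = np.floor(on / DAY_S).astype(np.int64)
    out: List[DaySequence] = []
    lo = 0
    for d in days:
        i0 = np.searchsorted(day_of, d, side="left")
        i1 = np.searchsorted(day_of, d, side="right")
        lo = i1
        d_start, d_end = d * DAY_S, (d + 1) * DAY_S
        u_on, u_off, u_pro = on[i0:i1], off[i0:i1], proactive[i0:i1]
        k = len(u_on)
        n_ep = 2 * k + 1
        starts = np.empty(n_ep)
        ends = np.empty(n_ep)
        is_use = np.zeros(n_ep, dtype=bool)
        is_use[1::2] = True
        starts[0] = d_start
        starts[1::2] = u_on
        starts[2::2] = u_off
        ends[0::2][:-1] = u_on
        ends[1::2] = u_off
        ends[-1] = d_end
        pro = np.zeros(n_ep, dtype=bool)
        pro[1::2] = u_pro
        keep = ends > starts  # degenerate gaps at the midnight boundary
        seq = DaySequence(
            user_id=user_id,
            date=(_EPOCH + timedelta(days=d)).date(),
            is_use=is_use[keep],
            start=starts[keep],
            end=ends[keep],
            proactive=pro[keep],
            sleep_excluded=np.zeros(int(keep.sum()), dtype=bool),
        )
        out.append(seq)
    return out


# ---------------------------------------------------------------------------
# Sleep exclusion


def _clock_region(start_hour: float, end_hour: float) -> List[Tuple[float, float]]:
    """Seconds-of-day intervals for a clock window, split at midnight."""
    s, e = start_hour * 3600.0, end_hour * 3600.0
    if s < e:
        return [(s, e)]
    if s == e:
        return []
    return [(0.0, e), (s, DAY_S)]


def apply_sleep_exclusion(day: DaySequence, policy: SleepPolicy) -> DaySequence:
    """Return a copy of ``day`` with sleep-time nonuse episodes flagged.

    ``fixed_window`` splits partially-overlapping nonuse episodes at the
    window boundary so exactly the overlap is flagged;
    ``longest_overnight_gap`` flags (in full) the single longest nonuse gap
    overlapping the night window, provided it is long enough. Use episodes
    are never flagged.
    """
    if isinstance(policy, NoSleepExclusion):
        return day
    if isinstance(policy, LongestOvernightGap):
        return _apply_longest_gap(day, policy)
    if isinstance(policy, FixedWindow):
        return _apply_fixed_window(day, policy)
    raise ValueError(f"unknown sleep policy object: {policy!r}")


def _apply_longest_gap(day: DaySequence, policy: LongestOvernightGap) -> DaySequence:
    if len(day) == 0:
        return day
    d0 = np.floor(day.start[0] / DAY_S) * DAY_S
    region = _clock_region(policy.night_start, policy.night_end)
    dur = day.duration
    overlap = np.zeros(len(day))
    for lo, hi in region:
        overlap += np.clip(
            np.minimum(day.end, d0 + hi) - np.maximum(day.start, d0 + lo), 0.0, None
        )
    cand = (~day.is_use) & (overlap > 0) & (dur >= policy.min_hours * 3600.0)
    flags = np.zeros(len(day), dtype=bool)
    if np.any(cand):
        masked = np.where(cand, dur, -np.inf)
        flags[int(np.argmax(masked))] = True  # ties: earliest wins via argmax
    return replace(day, sleep_excluded=flags)


def _apply_fixed_window(day: DaySequence, policy: FixedWindow) -> DaySequence:
    if len(day) == 0:
        return day
    d0 = np.floor(day.start[0] / DAY_S) * DAY_S
    region = [(d0 + lo, d0 + hi) for lo, hi in _clock_region(policy.start_hour, policy.end_hour)]
    starts: List[float] = []
    ends: List[float] = []
    is_use: List[bool] = []
    pro: List[bool] = []
    excl: List[bool] = []

    def emit(s: float, e: float, use: bool, p: bool, x: bool) -> None:
        if e > s:
            starts.append(s)
            ends.append(e)
            is_use.append(use)
            pro.append(p)
            excl.append(x)

    for i in range(len(day)):
        s, e = float(day.start[i]), float(day.end[i])
        if day.is_use[i]:
            emit(s, e, True, bool(day.proactive[i]), False)
            continue
        cuts = sorted({s, e, *[c for lo, hi in region for c in (lo, hi) if s < c < e]})
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = 0.5 * (a + b)
            inside = any(lo <= mid < hi for lo, hi in region)
            emit(a, b, False, False, inside)
    out = DaySequence(
        user_id=day.user_id,
        date=day.date,
        is_use=np.array(is_use, dtype=bool),
        start=np.array(starts),
        end=np.array(ends),
        proactive=np.array(pro, dtype=bool),
        sleep_excluded=np.array(excl, dtype=bool),
    )
    return out


# ---------------------------------------------------------------------------
# End-to-end per-user extraction


def _local_epoch_seconds(timestamps: pd.Series, timezone: str) -> np.ndarray:
    """Convert tz-aware timestamps to float epoch seconds on the local clock."""
    local = timestamps.dt.tz_convert(timezone).dt.tz_localize(None)
    return local.astype("int64").to_numpy() / 1e9


def extract_user_days(
    user_events: pd.DataFrame,
    config: StudyConfig,
) -> Tuple[List[DaySequence], QCReport]:
    """Full pipeline for one user: pair, classify, split into days, flag sleep.

    ``user_events`` needs time-ordered columns ``timestamp`` (tz-aware) and
    ``event_type``.
    """
    t = _local_epoch_seconds(user_events["timestamp"], config.timezone)
    types = user_events["event_type"].to_numpy()
    on, off, qc = pair_screen_events(types, t)
    notif = np.sort(t[types == EVENT_NOTIFICATION])
    pro = classify_proactive_many(on, notif, config.proactive_window)
    user_id = str(user_events["user_id"].iloc[0]) if len(user_events) else ""
    span = (float(t[0]), float(t[-1])) if len(t) else None
    days = build_day_sequences(user_id, on, off, pro, config, record_span=span)
    days = [apply_sleep_exclusion(d, config.sleep_policy) for d in days]
    return days, qc


def extract_days(
    events: pd.DataFrame, config: StudyConfig
) -> Tuple[List[DaySequence], QCReport]:
    """Run :func:`extract_user_days` for every user in an event table."""
    qc = QCReport()
    out: List[DaySequence] = []
    for _, grp in events.groupby("user_id", sort=True):
        days, q = extract_user_days(grp, config)
        out.extend(days)
        qc += q
    return out, qc


def days_to_frame(days: Sequence[DaySequence]) -> pd.DataFrame:
    """Tabulate day sequences as one row per episode (for CSV export)."""
    rows = []
    for day in days:
        for ep in day.episodes():
            rows.append(
                {
                    "user_id": day.user_id,
                    "date": day.date.isoformat(),
                    "kind": ep.kind,
                    "start": ep.start.isoformat(),
                    "end": ep.end.isoformat(),
                    "duration": ep.duration,
                    "proactive": ep.proactive,
                    "sleep_excluded": ep.sleep_excluded,
                }
            )
    columns = [
        "user_id", "date", "kind", "start", "end",
        "duration", "proactive", "sleep_excluded",
    ]
    return pd.DataFrame(rows, columns=columns)


def days_from_frame(frame: pd.DataFrame) -> List[DaySequence]:
    """Rebuild :class:`DaySequence` objects from a :func:`days_to_frame` table."""
    out: List[DaySequence] = []
    start = (
        pd.to_datetime(frame["start"], format="ISO8601").astype("int64").to_numpy() / 1e9
    )
    end = pd.to_datetime(frame["end"], format="ISO8601").astype("int64").to_numpy() / 1e9
    is_use = (frame["kind"] == "use").to_numpy()
    pro = frame["proactive"].map(lambda v: bool(v) if pd.notna(v) else False).to_numpy(bool)
    excl = frame["sleep_excluded"].map(lambda v: bool(v) if pd.notna(v) else False).to_numpy(bool)
    groups = frame.reset_index(drop=True).groupby(["user_id", "date"]).indices
    for (user_id, day), sel in groups.items():
        sel = sel[np.argsort(start[sel], kind="stable")]
        out.append(
            DaySequence(
                user_id=str(user_id),
                date=pd.Timestamp(day).date(),
                is_use=is_use[sel],
                start=start[sel],
                end=end[sel],
                proactive=pro[sel],
                sleep_excluded=excl[sel],
            )
        )
    out.sort(key=lambda d: (d.user_id, d.date))
    return out
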