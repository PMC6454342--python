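"""The seven daily use parameters and their multi-week averages.

For each user-day the package computes:

* ``F``  — total use frequency: number of use episodes.
* ``D``  — total use duration: summed use-episode seconds.
* ``PF`` — proactive use frequency: use episodes with no notification in the
  minute before screen-on.
* ``PD`` — proactive use duration: their summed seconds.
* ``RMSSD`` — root mean square of successive differences between adjacent
  use/nonuse episode durations (sleep removed): with durations A_1..A_n in
  temporal order, sqrt( sum (A_{i+1} - A_i)^2 / (n-1) ). Low values mean the
  use and nonuse rhythm is even (high use/nonuse similarity).
* ``SI`` — Similarity Index: mean |X_i - Y_j| over each nonuse duration X_i
  and its k (default 3) following use durations Y_i, Y_{i+1}, Y_{i+2}.
* ``CI`` — Control Index: mean |X_i - (Y_i + Y_{i+1} + Y_{i+2})| over the
  same pairs of a nonuse episode with its k following uses.

RMSSD/SI/CI are undefined (NaN) on degenerate days — never coerced to zero,
which would fake perfect reciprocity.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import StudyConfig
from .episodes import DaySequence

PARAMETER_NAMES = ["F", "D", "PF", "PD", "RMSSD", "SI", "CI"]

ArrayLike = Union[np.ndarray, Sequence[float]]


# ---------------------------------------------------------------------------
# Active-sequence view (sleep removed)


def active_segments(
    day: DaySequence, bridge: bool = True
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Episode (durations, is_use) with sleep-excluded gaps removed.

    With ``bridge=True`` the removal closes the sequence up (one segment);
    otherwise the sequence breaks into independent segments at every removed
    gap, and successive-difference / lookahead computations do not straddle
    a break. Adjacent nonuse episodes left touching by a removal (possible
    after fixed-window splitting) are merged.
    """
    keep = day.is_use | ~day.sleep_excluded
    segment_id = np.cumsum(~keep)[keep] if not bridge else np.zeros(int(keep.sum()), int)
    durations = day.duration[keep]
    is_use = day.is_use[keep]
    segments: List[Tuple[np.ndarray, np.ndarray]] = []
    for sid in np.unique(segment_id):
        m = segment_id == sid
        d, u = durations[m], is_use[m]
        if len(d) > 1:  # merge touching nonuse runs
            new_run = np.concatenate(([True], (u[1:] != u[:-1]) | u[1:]))
            first = new_run.nonzero()[0]
            d = np.add.reduceat(d, first)
            u = u[first]
        if len(d):
            segments.append((d, u))
    return segments


def _as_segments(
    day: Union[DaySequence, ArrayLike],
    is_use: Optional[ArrayLike],
    bridge: bool,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    if isinstance(day, DaySequence):
        return active_segments(day, bridge=bridge)
    durations = np.asarray(day, dtype=np.float64)
    if is_use is None:
        # durations alone: assume strict alternation starting with nonuse
        is_use_arr = np.zeros(len(durations), dtype=bool)
        is_use_arr[1::2] = True
    else:
        is_use_arr = np.asarray(is_use, dtype=bool)
    return [(durations, is_use_arr)] if len(durations) else []


# ---------------------------------------------------------------------------
# Reciprocity statistics


def rmssd(
    day: Union[DaySequence, ArrayLike],
    is_use: Optional[ArrayLike] = None,
    bridge: bool = True,
) -> float:
    """Root mean square of successive differences of episode durations.

    Accepts a :class:`DaySequence` (sleep-excluded gaps are removed first) or
    a plain duration sequence. NaN when fewer than two episodes remain.
    """
    segments = _as_segments(day, is_use, bridge)
    sq_sum = 0.0
    n_diff = 0
    for durations, _ in segments:
        if len(durations) >= 2:
            diffs = np.diff(durations)
            sq_sum += float(np.dot(diffs, diffs))
            n_diff += len(diffs)
    if n_diff == 0:
        return math.nan
    return math.sqrt(sq_sum / n_diff)


def _si_ci_terms(
    segments: List[Tuple[np.ndarray, np.ndarray]], k: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Eligible (X, Y-triplet) pairs, stacked across segments.

    Returns ``(x, y)`` where ``x[i]`` is a nonuse duration and ``y[i]`` its
    k following use durations; a nonuse episode with fewer than k following
    uses in its segment is skipped entirely.
    """
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for durations, is_use in segments:
        use_pos = np.flatnonzero(is_use)
        nonuse_pos = np.flatnonzero(~is_use)
        j = np.searchsorted(use_pos, nonuse_pos)
        eligible = j + k <= len(use_pos)
        if not np.any(eligible):
            continue
        use_dur = durations[use_pos]
        idx = j[eligible, None] + np.arange(k)[None, :]
        xs.append(durations[nonuse_pos[eligible]])
        ys.append(use_dur[idx])
    if not xs:
        return np.empty(0), np.empty((0, k))
    return np.concatenate(xs), np.vstack(ys)


def similarity_index(
    day: Union[DaySequence, ArrayLike],
    is_use: Optional[ArrayLike] = None,
    k: int = 3,
    pooled: bool = True,
    bridge: bool = True,
) -> float:
    """Mean absolute difference between nonuse gaps and their k following uses.

    ``pooled=True`` averages over all 3k differences; ``pooled=False``
    averages the per-gap means (identical when every gap is eligible with a
    full triplet). NaN when no nonuse episode has k following uses.
    """
    segments = _as_segments(day, is_use, bridge)
    x, y = _si_ci_terms(segments, k)
    if len(x) == 0:
        return math.nan
    diffs = np.abs(x[:, None] - y)
    return float(diffs.mean()) if pooled else float(diffs.mean(axis=1).mean())


def control_index(
    day: Union[DaySequence, ArrayLike],
    is_use: Optional[ArrayLike] = None,
    k: int = 3,
    bridge: bool = True,
) -> float:
    """Mean |nonuse gap - sum of its k following uses| over eligible gaps.

    A small value means nonuse pauses are commensurate with the use they
    "buy" — the proposed index of use-control ability. NaN when no gap is
    eligible.
    """
    segments = _as_segments(day, is_use, bridge)
    x, y = _si_ci_terms(segments, k)
    if len(x) == 0:
        return math.nan
    return float(np.abs(x - y.sum(axis=1)).mean())


# ---------------------------------------------------------------------------
# Daily counts and durations


def daily_counts_durations(day: DaySequence) -> Tuple[int, float, int, float]:
    """(F, D, PF, PD) for one day; zeros on a day without use episodes."""
    use = day.is_use
    durations = day.duration
    pro = use & day.proactive
    return (
        int(use.sum()),
        float(durations[use].sum()),
        int(pro.sum()),
        float(durations[pro].sum()),
    )


def daily_parameters(
    day: DaySequence, config: Optional[StudyConfig] = None
) -> dict:
    """All seven parameters for one day as a plain record."""
    config = config or StudyConfig()
    f, d, pf, pd_ = daily_counts_durations(day)
    return {
        "user_id": day.user_id,
        "date": day.date,
        "F": f,
        "D": d,
        "PF": pf,
        "PD": pd_,
        "RMSSD": rmssd(day, bridge=config.bridge_sleep_gaps),
        "SI": similarity_index(
            day,
            k=config.lookahead_k,
            pooled=config.si_pooled_denominator,
            bridge=config.bridge_sleep_gaps,
        ),
        "CI": control_index(day, k=config.lookahead_k, bridge=config.bridge_sleep_gaps),
    }


def daily_parameters_table(
    days: Iterable[DaySequence], config: Optional[StudyConfig] = None
) -> pd.DataFrame:
    """One row per user-day with columns user_id, date, F..CI."""
    records = [daily_parameters(day, config) for day in days]
    columns = ["user_id", "date", *PARAMETER_NAMES]
    frame = pd.DataFrame(records, columns=columns)
    if len(frame):
        frame["date"] = pd.to_datetime(frame["date"])
    return frame


# ---------------------------------------------------------------------------
# Period summaries


def summarize_period(
    daily: pd.DataFrame,
    window: Optional[Tuple] = None,
) -> pd.Series:
    """Mean of each parameter for ONE user over a date window.

    Means skip undefined (NaN) days; the number of contributing days per
    parameter is recorded as ``n_<param>``. Raises when the table mixes
    users or the window covers no days.
    """
    users = daily["user_id"].unique()
    if len(users) != 1:
        raise ValueError(f"summarize_period expects one user, got {len(users)}")
    sub = daily
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        sub = daily[(daily["date"] >= lo) & (daily["date"] <= hi)]
    if len(sub) == 0:
        raise ValueError("window covers no days")
    out = {"user_id": users[0], "n_days": len(sub)}
    for p in PARAMETER_NAMES:
        out[p] = sub[p].mean(skipna=True)
        out[f"n_{p}"] = int(sub[p].notna().sum())
    return pd.Series(out)


def summarize_users(
    daily: pd.DataFrame, window: Optional[Tuple] = None
) -> pd.DataFrame:
    """Per-user :func:`summarize_period` over a whole cohort table."""
    rows = [
        summarize_period(grp, window) for _, grp in daily.groupby("user_id", sort=True)
    ]
    return pd.DataFrame(rows).reset_index(drop=True)
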