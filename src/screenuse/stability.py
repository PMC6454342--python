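"""Temporal-stability and addiction-correlation analyses.

Two complementary reliability analyses over an (aligned) multi-week cohort
of daily parameters:

* **Fundamental time unit** (:func:`unit_vs_total`): how well the per-user
  mean over one grid-aligned block of 1/2/4 weeks correlates, across users,
  with the per-user mean over the whole record (default 8 weeks). A block is
  a candidate "fundamental time unit" when its correlation clears the high-
  correlation threshold (default r >= .75).

* **Independent cycle** (:func:`independent_cycle`): the across-user
  correlation between two non-overlapping blocks separated by a time
  interval (TI) of whole weeks, averaged over every block pair at that TI
  (sliding weekly offsets). A TI at which the mean correlation falls below
  the threshold marks the two periods as belonging to different use cycles.

Plus the exploratory correlation of each two-month parameter mean with the
SPAI-5 smartphone-addiction total.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import PARAMETER_NAMES

MIN_USERS = 3  # below this a correlation is reported undefined


# ---------------------------------------------------------------------------
# Pearson r with explicit degenerate handling


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Product-moment correlation and two-sided p (t transform).

    Returns (nan, nan) — never a fake 0 or 1 — when fewer than
    ``MIN_USERS`` finite pairs remain or either side has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < MIN_USERS or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Week grid


def assign_weeks(daily: pd.DataFrame, origin=None) -> pd.DataFrame:
    """Add a 0-based ``week`` column: whole weeks since ``origin``.

    ``origin`` defaults to the earliest date in the table, so a cohort whose
    users share a calendar is aligned on a common weekly grid.
    """
    out = daily.copy()
    dates = pd.to_datetime(out["date"])
    origin = pd.Timestamp(origin) if origin is not None else dates.min()
    out["week"] = ((dates - origin).dt.days // 7).astype(int)
    return out


def _block_means(
    daily: pd.DataFrame, weeks: Sequence[int], parameter: str
) -> pd.Series:
    """Per-user mean of one parameter over the given weeks (NaN days skipped)."""
    sub = daily[daily["week"].isin(list(weeks))]
    return sub.groupby("user_id")[parameter].mean()


# ---------------------------------------------------------------------------
# Fundamental time unit


def unit_vs_total(
    daily: pd.DataFrame,
    unit_weeks: int,
    total_weeks: int = 8,
    parameters: Sequence[str] = PARAMETER_NAMES,
    high_corr_threshold: float = 0.75,
    leave_block_out: bool = False,
) -> pd.DataFrame:
    """Correlate each grid-aligned unit block with the whole-record mean.

    Blocks partition weeks 0..total_weeks-1 into consecutive runs of
    ``unit_weeks`` (8, 4 or 2 blocks for units of 1, 2, 4 weeks). For each
    parameter and block, the across-user Pearson r between the block mean
    and the total mean is reported, flagged ``high`` when it clears the
    threshold. Users lacking data for a cell are dropped from that cell.

    By default the block is part of the total (the usual way such
    reliability curves are computed); ``leave_block_out=True`` instead
    correlates the block against the mean of the *remaining* weeks,
    removing the part-whole overlap.
    """
    if total_weeks % unit_weeks:
        raise ValueError("unit_weeks must divide total_weeks")
    daily = daily if "week" in daily.columns else assign_weeks(daily)
    daily = daily[daily["week"] < total_weeks]
    rows = []
    for parameter in parameters:
        total = _block_means(daily, range(total_weeks), parameter)
        for b in range(total_weeks // unit_weeks):
            weeks = range(b * unit_weeks, (b + 1) * unit_weeks)
            block = _block_means(daily, weeks, parameter)
            if leave_block_out:
                rest = [w for w in range(total_weeks) if w not in weeks]
                total = _block_means(daily, rest, parameter)
            joined = pd.concat([block, total], axis=1, join="inner").dropna()
            r, p = pearson(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append(
                {
                    "parameter": parameter,
                    "unit_weeks": unit_weeks,
                    "block": b + 1,
                    "first_week": b * unit_weeks + 1,
                    "r": r,
                    "p_value": p,
                    "n_users": len(joined),
                    "high": bool(r >= high_corr_threshold) if np.isfinite(r) else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independent cycle


def cycle_block_pairs(unit_weeks: int, max_weeks: int = 8) -> List[Tuple[int, int, int]]:
    """All ordered non-overlapping block-start pairs as (start1, start2, TI).

    Blocks of ``unit_weeks`` start at every weekly offset; TI is the gap in
    weeks between the end of the first block and the start of the second.
    For 1-week units in an 8-week record, TI 0..6 have 7,6,5,4,3,2,1 pairs.
    """
    starts = range(max_weeks - unit_weeks + 1)
    return [
        (s1, s2, s2 - s1 - unit_weeks)
        for s1 in starts
        for s2 in starts
        if s2 >= s1 + unit_weeks
    ]


def independent_cycle(
    daily: pd.DataFrame,
    unit_weeks: int,
    max_weeks: int = 8,
    parameters: Sequence[str] = PARAMETER_NAMES,
    high_corr_threshold: float = 0.75,
) -> pd.DataFrame:
    """Mean across-user correlation of two blocks at each time interval.

    For each parameter and TI, every pair of non-overlapping
    ``unit_weeks``-week blocks whose gap is exactly TI weeks contributes one
    across-user Pearson r; the pair correlations are averaged into
    ``mean_r`` (a general index of temporal reliability at that TI).
    """
    daily = daily if "week" in daily.columns else assign_weeks(daily)
    daily = daily[daily["week"] < max_weeks]
    pairs = cycle_block_pairs(unit_weeks, max_weeks)
    rows = []
    for parameter in parameters:
        means = {
            s: _block_means(daily, range(s, s + unit_weeks), parameter)
            for s in range(max_weeks - unit_weeks + 1)
        }
        by_ti: dict = {}
        for s1, s2, ti in pairs:
            joined = pd.concat([means[s1], means[s2]], axis=1, join="inner").dropna()
            r, _ = pearson(joined.iloc[:, 0], joined.iloc[:, 1])
            by_ti.setdefault(ti, []).append(r)
        for ti in sorted(by_ti):
            rs = np.asarray(by_ti[ti], dtype=float)
            mean_r = float(np.nanmean(rs)) if np.any(np.isfinite(rs)) else math.nan
            rows.append(
                {
                    "parameter": parameter,
                    "unit_weeks": unit_weeks,
                    "TI": ti,
                    "mean_r": mean_r,
                    "n_pairs": len(rs),
                    "high": bool(mean_r >= high_corr_threshold)
                    if np.isfinite(mean_r)
                    else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Addiction correlations


def addiction_correlations(
    summaries: pd.DataFrame,
    spai: pd.DataFrame,
    parameters: Sequence[str] = PARAMETER_NAMES,
) -> Tuple[pd.DataFrame, int]:
    """Correlate per-user period means with the SPAI-5 total.

    ``summaries`` is the output of
    :func:`screenuse.parameters.summarize_users`; ``spai`` needs columns
    ``user_id`` and ``total``. Users present in only one table are dropped;
    their count is returned alongside the correlation table.
    """
    merged = summaries.merge(spai[["user_id", "total"]], on="user_id", how="inner")
    dropped = (len(summaries) - len(merged)) + (len(spai) - len(merged))
    rows = []
    for parameter in parameters:
        r, p = pearson(merged[parameter], merged["total"])
        n = int((merged[parameter].notna() & merged["total"].notna()).sum())
        rows.append({"parameter": parameter, "r": r, "p_value": p, "n_users": n})
    return pd.DataFrame(rows), dropped


def intercorrelation_matrix(
    summaries: pd.DataFrame, parameters: Sequence[str] = PARAMETER_NAMES
) -> pd.DataFrame:
    """Pairwise Pearson r among the per-user parameter means (7x7)."""
    k = len(parameters)
    mat = np.full((k, k), np.nan)
    for i, a in enumerate(parameters):
        mat[i, i] = 1.0
        for j in range(i):
            r, _ = pearson(summaries[a], summaries[parameters[j]])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=list(parameters), columns=list(parameters))
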