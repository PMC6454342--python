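"""End-to-end conveniences chaining the pipeline stages in memory."""

from __future__ import annotations

from typing import Optional, Tuple

import pandas as pd

from .config import StudyConfig
from .episodes import QCReport, extract_days
from .parameters import daily_parameters_table, summarize_users
from .stability import (
    addiction_correlations,
    assign_weeks,
    independent_cycle,
    intercorrelation_matrix,
    unit_vs_total,
)


def events_to_daily_parameters(
    events: pd.DataFrame, config: Optional[StudyConfig] = None
) -> Tuple[pd.DataFrame, QCReport]:
    """Raw events -> one row of the seven parameters per user-day."""
    config = config or StudyConfig()
    days, qc = extract_days(events, config)
    return daily_parameters_table(days, config), qc


def run_stability_suite(
    daily: pd.DataFrame,
    spai: Optional[pd.DataFrame] = None,
    config: Optional[StudyConfig] = None,
    total_weeks: int = 8,
) -> dict:
    """All analyses over a daily-parameter table.

    Returns a dict with the unit-vs-total table (units 1/2/4 weeks), the
    independent-cycle table (units 1/2 weeks), the per-user period summary,
    the 7x7 intercorrelation matrix and — when ``spai`` is given — the
    parameter-vs-SPAI-5 correlation table.
    """
    config = config or StudyConfig()
    weekly = assign_weeks(daily)
    thr = config.high_corr_threshold
    out = {
        "unit_stability": pd.concat(
            [
                unit_vs_total(weekly, u, total_weeks, high_corr_threshold=thr)
                for u in (1, 2, 4)
                if total_weeks % u == 0
            ],
            ignore_index=True,
        ),
        "cycle_stability": pd.concat(
            [
                independent_cycle(weekly, u, total_weeks, high_corr_threshold=thr)
                for u in (1, 2)
                if total_weeks > u
            ],
            ignore_index=True,
        ),
    }
    summaries = summarize_users(daily)
    out["user_summaries"] = summaries
    out["intercorrelation"] = intercorrelation_matrix(summaries)
    if spai is not None:
        corr, dropped = addiction_correlations(summaries, spai)
        out["addiction_correlations"] = corr
        out["n_unmatched_users"] = dropped
    return out
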