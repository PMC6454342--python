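"""Shared fixtures and helpers for the screenuse test suite."""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pytest

from screenuse import CohortSpec, DaySequence, StudyConfig, generate_cohort
from screenuse.episodes import DAY_S

# A generated day can legitimately warn when trait draws make it overfull.
warnings.filterwarnings(
    "ignore", message="day overfull after resampling.*", category=UserWarning
)

BASE_DAY = date(2017, 3, 8)
BASE_DAY_S = (BASE_DAY - date(1970, 1, 1)).days * DAY_S


def make_day(
    durations,
    first_kind: str = "nonuse",
    proactive=None,
    sleep_excluded=None,
    user_id: str = "u1",
    day: date = BASE_DAY,
) -> DaySequence:
    """Build a strictly alternating DaySequence from a duration list.

    Episodes tile the day starting at local midnight; the remainder of the
    day (if any) is appended as a final episode continuing the alternation,
    so the sequence always covers the full 86 400 s.
    """
    durations = [float(d) for d in durations]
    total = sum(durations)
    if total > DAY_S:
        raise ValueError("durations exceed one day")
    if total < DAY_S:
        durations = durations + [DAY_S - total]
    n = len(durations)
    is_use = np.zeros(n, dtype=bool)
    is_use[0 if first_kind == "use" else 1 :: 2] = True
    day0 = (day - date(1970, 1, 1)).days * DAY_S
    ends = day0 + np.cumsum(durations)
    starts = np.concatenate(([day0], ends[:-1]))
    pro = np.zeros(n, dtype=bool)
    if proactive is not None:
        pro[is_use] = np.asarray(proactive, dtype=bool)[: int(is_use.sum())]
    excl = np.zeros(n, dtype=bool)
    if sleep_excluded is not None:
        excl[~is_use] = np.asarray(sleep_excluded, dtype=bool)[: int((~is_use).sum())]
    seq = DaySequence(
        user_id=user_id,
        date=day,
        is_use=is_use,
        start=starts,
        end=ends,
        proactive=pro,
        sleep_excluded=excl,
    )
    seq.validate()
    return seq


# ---------------------------------------------------------------------------
# Independent brute-force oracles (direct loops over the definitions)


def brute_rmssd(durations) -> float:
    durations = list(map(float, durations))
    n = len(durations)
    if n < 2:
        return float("nan")
    total = 0.0
    for i in range(n - 1):
        total += (durations[i + 1] - durations[i]) ** 2
    return (total / (n - 1)) ** 0.5


def brute_si(durations, is_use, k=3) -> float:
    durations = list(map(float, durations))
    diffs = []
    for i, use in enumerate(is_use):
        if use:
            continue
        following = [durations[j] for j in range(i + 1, len(durations)) if is_use[j]]
        if len(following) < k:
            continue
        for y in following[:k]:
            diffs.append(abs(durations[i] - y))
    if not diffs:
        return float("nan")
    return sum(diffs) / len(diffs)


def brute_ci(durations, is_use, k=3) -> float:
    durations = list(map(float, durations))
    vals = []
    for i, use in enumerate(is_use):
        if use:
            continue
        following = [durations[j] for j in range(i + 1, len(durations)) if is_use[j]]
        if len(following) < k:
            continue
        vals.append(abs(durations[i] - sum(following[:k])))
    if not vals:
        return float("nan")
    return sum(vals) / len(vals)


def random_alternating_sequences(rng, n_seq=1000, max_len=40):
    """(durations, is_use) pairs, strictly alternating, random start kind."""
    out = []
    for _ in range(n_seq):
        n = int(rng.integers(0, max_len + 1))
        durations = rng.lognormal(5.0, 1.5, size=n)
        start_use = bool(rng.integers(0, 2))
        is_use = np.zeros(n, dtype=bool)
        is_use[0 if start_use else 1 :: 2] = True
        out.append((durations, is_use))
    return out


# ---------------------------------------------------------------------------
# Cohort fixtures (module-scoped: generation is the slow part)


@pytest.fixture(scope="session")
def small_cohort():
    """8 users x 2 weeks, default traits — for closure/IO round trips."""
    return generate_cohort(CohortSpec(n_users=8, n_weeks=2, seed=42))


@pytest.fixture(scope="session")
def eight_week_cohort():
    """12 users x 8 weeks, zero drift — for stability identities."""
    return generate_cohort(
        CohortSpec(n_users=12, n_weeks=8, seed=7, drift_sd_per_week=0.0)
    )


@pytest.fixture()
def config():
    return StudyConfig()
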