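"""Study configuration: episode rules, sleep policy, analysis thresholds.

All clock times are expressed as fractional hours of the local day
(e.g. ``21.5`` is 21:30). Durations are seconds throughout the package.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union


@dataclass(frozen=True)
class NoSleepExclusion:
    """Sleep policy that flags nothing (identity)."""

    name = "none"


@dataclass(frozen=True)
class FixedWindow:
    """Flag every part of a nonuse episode inside a fixed clock window.

    The window may cross midnight (``start_hour > end_hour``); episodes are
    split at the window boundaries so only the overlapping part is flagged.
    """

    start_hour: float = 0.0
    end_hour: float = 7.0
    name = "fixed_window"

    def __post_init__(self) -> None:
        for h in (self.start_hour, self.end_hour):
            if not 0.0 <= h <= 24.0:
                raise ValueError(f"clock hour out of [0, 24]: {h}")


@dataclass(frozen=True)
class LongestOvernightGap:
    """Flag the longest nonuse gap overlapping the night window, per day.

    The gap is flagged in full when it lasts at least ``min_hours``. This is
    a heuristic sleep detector: the biggest night-time gap in screen activity
    is taken to be the sleep period.
    """

    min_hours: float = 4.0
    night_start: float = 21.0
    night_end: float = 11.0
    name = "longest_overnight_gap"

    def __post_init__(self) -> None:
        if self.min_hours <= 0:
            raise ValueError("min_hours must be positive")


SleepPolicy = Union[NoSleepExclusion, FixedWindow, LongestOvernightGap]

_POLICIES = {
    "none": NoSleepExclusion,
    "fixed_window": FixedWindow,
    "longest_overnight_gap": LongestOvernightGap,
}


def parse_sleep_policy(obj: Union[str, dict, SleepPolicy]) -> SleepPolicy:
    """Build a sleep policy from a name, a ``{"policy": ...}`` mapping, or pass through."""
    if isinstance(obj, (NoSleepExclusion, FixedWindow, LongestOvernightGap)):
        return obj
    if isinstance(obj, str):
        spec: dict = {"policy": obj}
    else:
        spec = dict(obj)
    name = spec.pop("policy", None)
    if name not in _POLICIES:
        raise ValueError(f"unknown sleep policy: {name!r} (known: {sorted(_POLICIES)})")
    return _POLICIES[name](**spec)


@dataclass(frozen=True)
class StudyConfig:
    """Parameters governing episode construction and the stability analyses.

    Attributes
    ----------
    proactive_window:
        Length in seconds of the pre-screen-on window scanned for
        notifications; an episode with no notification in
        ``[screen_on - proactive_window, screen_on)`` is proactive.
    sleep_policy:
        How sleep time is identified and removed from nonuse episodes.
    lookahead_k:
        Number of use episodes following a nonuse episode that enter the
        Similarity and Control Index computations.
    high_corr_threshold:
        Pearson r at or above which a stability cell is flagged "high".
    exclude_first_last_day:
        Drop each user's first and last calendar day (partial recordings).
    timezone:
        IANA name or fixed offset used to convert event timestamps to local
        time for day assignment.
    si_pooled_denominator:
        If True (default) the Similarity Index averages over all 3k absolute
        differences; if False it is a mean of per-nonuse-episode means (the
        two coincide when every eligible episode has exactly k followers).
    bridge_sleep_gaps:
        If True (default), removing a sleep-flagged gap makes its neighbours
        adjacent in the reciprocity sequence; if False the sequence is broken
        into segments at each removed gap.
    """

    proactive_window: float = 60.0
    sleep_policy: SleepPolicy = field(default_factory=LongestOvernightGap)
    lookahead_k: int = 3
    high_corr_threshold: float = 0.75
    exclude_first_last_day: bool = True
    timezone: str = "UTC"
    si_pooled_denominator: bool = True
    bridge_sleep_gaps: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.proactive_window <= 0:
            raise ValueError("proactive_window must be > 0")
        if self.lookahead_k < 1:
            raise ValueError("lookahead_k must be >= 1")
        if not 0.0 < self.high_corr_threshold < 1.0:
            raise ValueError("high_corr_threshold must be in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "sleep_policy" in data:
            data["sleep_policy"] = parse_sleep_policy(data["sleep_policy"])
        return cls(**data)

    @classmethod
    def from_toml(cls, path: Union[str, Path]) -> "StudyConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def with_overrides(self, **kwargs) -> "StudyConfig":
        if "sleep_policy" in kwargs:
            kwargs["sleep_policy"] = parse_sleep_policy(kwargs["sleep_policy"])
        return replace(self, **kwargs)
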