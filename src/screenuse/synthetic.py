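"""Synthetic smartphone-use cohort generator.

Emulates a cohort of heavy smartphone users tracked passively for several
weeks: per-user stable traits (episode rate, mean episode length, proactive
fraction, sleep schedule, weekend effect), a within-day structure of
alternating use/nonuse episodes confined to waking hours, a slow
multiplicative between-week drift of the use rate (which makes correlations
between periods decay with their time interval), and a latent
addiction-proneness score observed through a 5-item Likert questionnaire
(SPAI-5, totals 5-20).

Default trait means are calibrated to a heavy-use adult cohort: about 57
use episodes and 5.74 h of screen time per day, with 40% of episodes (23%
of duration) proactive, i.e. initiated without a notification in the
preceding minute. Episode counts are Poisson and episode durations
log-normal — the simplest positive-valued laws with the heavy right skew
such data show. The weekly weekend/weekday profile is normalized to mean 1
so the weekend multiplier shapes the week without changing cohort means,
and the weekly drift random walk is martingale-corrected for the same
reason.

Reactive episodes get exactly one notification placed strictly inside the
60 s pre-screen-on window (and outside every proactive episode's window),
so the downstream classifier's label provably equals the generator's label
for every episode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .episodes import DAY_S, EVENT_NOTIFICATION, EVENT_SCREEN_OFF, EVENT_SCREEN_ON

# Fraction of the waking window that episode durations may fill before the
# day is resampled: phone use cannot exceed time awake.
_FILL_BUDGET = 0.9
_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class UserTraits:
    """Stable per-user traits driving event generation."""

    user_id: str
    base_episode_rate: float            # use episodes per day
    base_mean_episode_duration: float   # seconds
    proactive_prob: float               # fraction of episodes self-initiated
    sleep_start: float                  # local clock hours, < 24
    sleep_end: float                    # local clock hours (next morning)
    weekend_multiplier: float           # weekend/weekday rate ratio
    addiction_latent: float             # standardized addiction proneness

    def __post_init__(self) -> None:
        if not 0.0 <= self.proactive_prob <= 1.0:
            raise ValueError("proactive_prob must be in [0, 1]")
        if self.base_episode_rate <= 0 or self.base_mean_episode_duration <= 0:
            raise ValueError("rates and durations must be strictly positive")
        if not 0.0 <= self.sleep_end < self.sleep_start <= 24.0:
            raise ValueError("need 0 <= sleep_end < sleep_start <= 24 (clock hours)")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation settings (defaults are the study conditions)."""

    n_users: int = 33
    n_weeks: int = 8
    seed: int = 0
    start_date: date = date(2017, 3, 6)  # a Monday; weeks align with calendar weeks
    timezone: str = "UTC"

    episode_rate_mean: float = 57.29
    episode_rate_sd: float = 22.96
    # chosen so mean daily duration = rate * episode duration = 20666.96 s (5.74 h)
    episode_duration_mean: float = 20666.96 / 57.29
    episode_duration_cv: float = 0.4     # between-user spread of the mean duration
    episode_duration_shape: float = 1.0  # within-user log-normal sigma
    proactive_prob_mean: float = 0.40
    proactive_prob_sd: float = 0.15
    # proactive episodes are shorter: 23% of duration vs 40% of frequency
    proactive_duration_factor: float = 0.23 / 0.40
    sleep_start_mean: float = 23.5
    sleep_start_sd: float = 0.5
    sleep_end_mean: float = 7.5
    sleep_end_sd: float = 0.5
    weekend_multiplier_mean: float = 1.15
    weekend_multiplier_sd: float = 0.10
    drift_sd_per_week: float = 0.10      # sd of the weekly log-rate random-walk step
    addiction_corr_target: float = 0.40  # latent vs standardized log expected PD
    spai_mean: float = 12.55
    spai_sd: float = 2.41
    proactive_window: float = 60.0

    def __post_init__(self) -> None:
        if self.n_users < 2:
            raise ValueError("n_users must be >= 2")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        if self.drift_sd_per_week < 0:
            raise ValueError("drift_sd_per_week must be >= 0")
        for name in (
            "episode_rate_sd",
            "episode_duration_cv",
            "episode_duration_shape",
            "proactive_prob_sd",
            "sleep_start_sd",
            "sleep_end_sd",
            "weekend_multiplier_sd",
            "spai_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not -1.0 <= self.addiction_corr_target <= 1.0:
            raise ValueError("addiction_corr_target must be in [-1, 1]")

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks

    @classmethod
    def from_toml(cls, path) -> "CohortSpec":
        import tomllib
        from pathlib import Path

        with open(Path(path), "rb") as fh:
            data = tomllib.load(fh)
        if "start_date" in data and not isinstance(data["start_date"], date):
            data["start_date"] = date.fromisoformat(str(data["start_date"]))
        return cls(**data)


def expected_daily_summary(spec: CohortSpec) -> dict:
    """Analytic cohort expectations implied by a spec (no simulation).

    Traits are sampled independently and the weekly profile and drift are
    mean-normalized, so expectations factorize.
    """
    f = spec.episode_rate_mean
    d = spec.episode_rate_mean * spec.episode_duration_mean
    return {
        "mean_F": f,
        "mean_D_seconds": d,
        "mean_D_hours": d / 3600.0,
        "proactive_frequency_fraction": spec.proactive_prob_mean,
        "proactive_duration_fraction": spec.proactive_prob_mean
        * spec.proactive_duration_factor,
    }


# ---------------------------------------------------------------------------
# Trait sampling


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _beta_params(mean: float, sd: float) -> Tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("proactive_prob_sd too large for a Beta law")
    return mean * nu, (1 - mean) * nu


def sample_traits(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> List[UserTraits]:
    """Draw per-user traits; the addiction latent follows a Gaussian copula.

    The latent is ``rho * z + sqrt(1-rho^2) * eps`` where ``z`` is the
    within-cohort standardized log of the user's expected proactive use
    duration (the trait product rate x mean duration x proactive fraction x
    proactive length factor) — so the latent correlates ``rho``
    (``addiction_corr_target``) with the trait that controls proactive use
    duration.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_users
    mu_r, sg_r = _lognormal_params(spec.episode_rate_mean, spec.episode_rate_sd)
    rate = rng.lognormal(mu_r, sg_r, size=n)
    mu_d, sg_d = _lognormal_params(
        spec.episode_duration_mean,
        spec.episode_duration_cv * spec.episode_duration_mean,
    )
    mean_dur = rng.lognormal(mu_d, sg_d, size=n)
    a_b, b_b = _beta_params(spec.proactive_prob_mean, spec.proactive_prob_sd)
    pro = np.clip(rng.beta(a_b, b_b, size=n), 0.01, 0.99)
    sleep_start = np.clip(
        rng.normal(spec.sleep_start_mean, spec.sleep_start_sd, size=n), 21.5, 23.95
    )
    sleep_end = np.clip(
        rng.normal(spec.sleep_end_mean, spec.sleep_end_sd, size=n), 5.0, 10.5
    )
    mu_w, sg_w = _lognormal_params(
        spec.weekend_multiplier_mean, spec.weekend_multiplier_sd
    )
    weekend = rng.lognormal(mu_w, sg_w, size=n)

    log_pd = np.log(rate * mean_dur * pro * spec.proactive_duration_factor)
    z = (log_pd - log_pd.mean()) / log_pd.std() if log_pd.std() > 0 else np.zeros(n)
    rho = spec.addiction_corr_target
    latent = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)

    width = len(str(n))
    return [
        UserTraits(
            user_id=f"u{i + 1:0{width}d}",
            base_episode_rate=float(rate[i]),
            base_mean_episode_duration=float(mean_dur[i]),
            proactive_prob=float(pro[i]),
            sleep_start=float(sleep_start[i]),
            sleep_end=float(sleep_end[i]),
            weekend_multiplier=float(weekend[i]),
            addiction_latent=float(latent[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Event generation


def _weekly_profile(spec: CohortSpec, traits: UserTraits) -> np.ndarray:
    """Day-of-week rate factors, normalized to mean 1 over the week."""
    prof = np.ones(7)
    prof[5:] = traits.weekend_multiplier  # start_date is a Monday
    return prof / prof.mean()


def _drift_factors(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-week multiplicative drift: a mean-one geometric random walk."""
    s = spec.drift_sd_per_week
    if s == 0:
        return np.ones(spec.n_weeks)
    steps = rng.normal(0.0, s, size=spec.n_weeks)
    steps[0] = 0.0  # week 1 defines the baseline
    walk = np.cumsum(steps)
    return np.exp(walk - np.arange(spec.n_weeks) * s**2 / 2.0)


def _place_notifications(
    ons: np.ndarray,
    proactive: np.ndarray,
    window: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Notification instants for reactive episodes; may flip crowded ones.

    Each reactive episode receives one notification uniform in
    ``[on - window, on)`` further constrained to stay outside every
    proactive episode's window. When episode onsets crowd within ``window``
    seconds and no legal slot remains, the episode is flipped to proactive
    (no notification) so generator labels and classifier labels stay equal
    by construction. Returns (notification times, final proactive flags).
    """
    proactive = proactive.copy()
    n = len(ons)
    for _ in range(n + 1):
        pro_ons = ons[proactive]
        lo = ons - window
        hi = ons.copy()
        if len(pro_ons):
            idx_prev = np.searchsorted(pro_ons, ons, side="left") - 1
            has_prev = idx_prev >= 0
            lo[has_prev] = np.maximum(lo[has_prev], pro_ons[idx_prev[has_prev]])
            idx_next = np.searchsorted(pro_ons, ons, side="right")
            has_next = idx_next < len(pro_ons)
            hi[has_next] = np.minimum(hi[has_next], pro_ons[idx_next[has_next]] - window)
        bad = ~proactive & (hi <= lo)
        if not np.any(bad):
            break
        proactive[bad] = True
    reactive = ~proactive
    notif = rng.uniform(lo[reactive], hi[reactive]) if np.any(reactive) else np.empty(0)
    return notif, proactive


def generate_user_events(
    traits: UserTraits,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Event stream and ground-truth episode table for one user.

    Returns ``(events, truth)``: events with columns user_id / timestamp /
    event_type covering ``spec.n_days`` days, and the generating episode
    intervals with their true proactive labels (local epoch seconds).
    """
    profile = _weekly_profile(spec, traits)
    drift = _drift_factors(spec, rng)
    day0 = (spec.start_date - date(1970, 1, 1)).days

    wake_lo = traits.sleep_end * 3600.0
    wake_hi = traits.sleep_start * 3600.0
    budget = _FILL_BUDGET * (wake_hi - wake_lo)
    p = traits.proactive_prob
    a = spec.proactive_duration_factor
    mean_pro = traits.base_mean_episode_duration * a
    mean_rea = traits.base_mean_episode_duration * (1 - p * a) / (1 - p) if p < 1 else 1.0
    sg = spec.episode_duration_shape
    mu_pro = np.log(mean_pro) - sg**2 / 2.0
    mu_rea = np.log(max(mean_rea, 1e-9)) - sg**2 / 2.0

    all_on: List[np.ndarray] = []
    all_off: List[np.ndarray] = []
    all_pro: List[np.ndarray] = []
    all_notif: List[np.ndarray] = []
    for d in range(spec.n_days):
        lam = traits.base_episode_rate * profile[d % 7] * drift[d // 7]
        n_ep = int(rng.poisson(lam))
        if n_ep == 0:
            continue
        flags = rng.random(n_ep) < p
        for attempt in range(_MAX_RESAMPLE + 1):
            durations = rng.lognormal(np.where(flags, mu_pro, mu_rea), sg)
            if durations.sum() <= budget:
                break
        else:  # pragma: no cover - extreme trait draws only
            pass
        if durations.sum() > budget:
            warnings.warn(
                "day overfull after resampling; durations scaled to the waking budget",
                stacklevel=2,
            )
            durations *= budget / durations.sum()
        free = (wake_hi - wake_lo) - durations.sum()
        gaps = rng.dirichlet(np.ones(n_ep + 1)) * free
        base = (day0 + d) * DAY_S + wake_lo
        ons = base + np.cumsum(gaps[:-1]) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
        offs = ons + durations
        notif, flags = _place_notifications(ons, flags, spec.proactive_window, rng)
        all_on.append(ons)
        all_off.append(offs)
        all_pro.append(flags)
        all_notif.append(notif)

    on = np.concatenate(all_on) if all_on else np.empty(0)
    off = np.concatenate(all_off) if all_off else np.empty(0)
    pro = np.concatenate(all_pro) if all_pro else np.empty(0, dtype=bool)
    notif = np.concatenate(all_notif) if all_notif else np.empty(0)

    t = np.concatenate([on, off, notif])
    kind = np.concatenate(
        [
            np.repeat(EVENT_SCREEN_ON, len(on)),
            np.repeat(EVENT_SCREEN_OFF, len(off)),
            np.repeat(EVENT_NOTIFICATION, len(notif)),
        ]
    )
    order = np.argsort(t, kind="stable")
    stamps = pd.to_datetime(np.round(t[order] * 1e9).astype(np.int64)).tz_localize(
        spec.timezone
    )
    events = pd.DataFrame(
        {
            "user_id": traits.user_id,
            "timestamp": stamps,
            "event_type": kind[order],
        }
    )
    truth = pd.DataFrame(
        {
            "user_id": traits.user_id,
            "start": on,
            "end": off,
            "proactive": pro,
        }
    )
    return events, truth


# ---------------------------------------------------------------------------
# Questionnaire + full cohort


def spai5_from_latent(
    latent: np.ndarray,
    rng: np.random.Generator,
    mean: float = 12.55,
    sd: float = 2.41,
) -> pd.DataFrame:
    """Discretize a standardized latent into SPAI-5 item scores.

    The total is an affine map of the latent (rounded, clipped to [5, 20]);
    items are a random feasible decomposition of the total into five 1-4
    Likert responses.
    """
    totals = np.clip(np.rint(mean + sd * np.asarray(latent)), 5, 20).astype(int)
    items = np.ones((len(totals), 5), dtype=int)
    for row, total in enumerate(totals):
        remaining = total - 5
        while remaining > 0:
            capacity = items[row] < 4
            j = rng.choice(np.flatnonzero(capacity))
            items[row, j] += 1
            remaining -= 1
    frame = pd.DataFrame(items, columns=[f"item{j}" for j in range(1, 6)])
    frame["total"] = totals
    return frame


@dataclass
class CohortData:
    """A generated cohort: events, questionnaire, traits and ground truth."""

    spec: CohortSpec
    traits: List[UserTraits]
    events: pd.DataFrame
    spai5: pd.DataFrame
    truth: pd.DataFrame  # generating episode intervals with true labels

    def write(self, out_dir) -> None:
        from . import io as _io  # deferred to avoid a cycle at import time

        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_events(self.events, out / "events.csv")
        _io.write_spai5(self.spai5, out / "spai5.csv")


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a full cohort, reproducible from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_users + 2)
    traits = sample_traits(spec, np.random.default_rng(children[0]))
    events_parts = []
    truth_parts = []
    for i, tr in enumerate(traits):
        ev, truth = generate_user_events(tr, spec, np.random.default_rng(children[i + 1]))
        events_parts.append(ev)
        truth_parts.append(truth)
    events = pd.concat(events_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    latent = np.array([tr.addiction_latent for tr in traits])
    spai = spai5_from_latent(
        latent, np.random.default_rng(children[-1]), spec.spai_mean, spec.spai_sd
    )
    spai.insert(0, "user_id", [tr.user_id for tr in traits])
    return CohortData(spec=spec, traits=traits, events=events, spai5=spai, truth=truth)
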