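"""Likelihood scoring and per-night selection of the overnight episode.

Stage two of the estimator.  Each candidate episode receives three scores
in (0, 1]:

* ``s_bed``  — how close the putative bedtime is to an assumed time to
  bed (22:00 by default), measured circularly on the 24-h clock;
* ``s_wake`` — how close the putative wake time is to the user's habitual
  wake time, estimated from the entire log, weekdays and weekends
  separately;
* ``s_dur``  — how close the net duration is to a reference duration
  (480 min, the midpoint of the recommended 420–540 min band for healthy
  adults).

Each score is an exponential decay ``exp(-distance / tau)``; the episode
likelihood is their product, i.e. a log-additive penalty.  The candidate
with the highest likelihood is the night's sleep estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import circmean

from .detector import CandidateEpisode

__all__ = [
    "DayType",
    "day_type_of",
    "HabitualProfile",
    "ScorerConfig",
    "ScoredEpisode",
    "estimate_habitual_wake",
    "circular_minutes",
    "score_bedtime",
    "score_wake",
    "score_duration",
    "score_episode",
    "select_overnight_episode",
]

DayType = Literal["weekday", "weekend"]

_MIN_PER_DAY = 1440.0


def day_type_of(d: date) -> DayType:
    """Saturday and Sunday wake dates are weekend nights."""
    return "weekend" if d.weekday() >= 5 else "weekday"


def _minutes_of_day(t: time) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7


def circular_minutes(a: time, b: time) -> float:
    """Shortest distance in minutes between two times on the 24-h circle."""
    d = abs(_minutes_of_day(a) - _minutes_of_day(b))
    return min(d, _MIN_PER_DAY - d)


@dataclass(frozen=True)
class HabitualProfile:
    """Typical wake times, estimated separately for weekdays and weekends."""

    wake_weekday: time
    wake_weekend: time
    derived_from: int = 1

    def wake_for(self, day_type: DayType) -> time:
        return self.wake_weekend if day_type == "weekend" else self.wake_weekday


@dataclass(frozen=True)
class ScorerConfig:
    """Scoring constants.

    The decay scales ``tau_*`` are all 120 min by default — the same scale
    as the detector's two-hour lookback; ``dur_anchor`` is the midpoint of
    the recommended 420–540 min sleep band.
    """

    bed_anchor: time = time(22, 0)
    tau_bed: float = 120.0
    tau_wake: float = 120.0
    tau_dur: float = 120.0
    dur_anchor: float = 480.0

    def __post_init__(self) -> None:
        if min(self.tau_bed, self.tau_wake, self.tau_dur) <= 0:
            raise ValueError("decay scales must be positive")


@dataclass(frozen=True)
class ScoredEpisode:
    episode: CandidateEpisode
    s_bed: float
    s_wake: float
    s_dur: float

    @property
    def likelihood(self) -> float:
        return self.s_bed * self.s_wake * self.s_dur


_DEFAULT_WAKE = time(8, 0)


def estimate_habitual_wake(nightly_ends: Iterable[tuple[datetime, DayType]],
                           day_type: DayType) -> time:
    """Circular median wake time-of-day for one day type.

    Falls back to the pooled observations when the requested day type has
    none, and to 08:00 when there are no observations at all.  The median
    is taken on the 24-h circle (times are unwrapped around their circular
    mean) so wake times straddling midnight average correctly.
    """
    ends = list(nightly_ends)
    mins = [_minutes_of_day(dt.time()) for dt, dtp in ends if dtp == day_type]
    if not mins:
        mins = [_minutes_of_day(dt.time()) for dt, _ in ends]
    if not mins:
        return _DEFAULT_WAKE
    arr = np.asarray(mins, dtype=float)
    mu = float(circmean(arr, high=_MIN_PER_DAY)) % _MIN_PER_DAY
    unwrapped = (arr - mu + _MIN_PER_DAY / 2) % _MIN_PER_DAY - _MIN_PER_DAY / 2
    med = (mu + float(np.median(unwrapped))) % _MIN_PER_DAY
    whole_sec = int(round(med * 60.0)) % 86400
    return time(whole_sec // 3600, (whole_sec % 3600) // 60, whole_sec % 60)


def score_bedtime(start: datetime, config: ScorerConfig | None = None) -> float:
    config = config or ScorerConfig()
    return math.exp(-circular_minutes(start.time(), config.bed_anchor) / config.tau_bed)


def score_wake(end: datetime, profile: HabitualProfile, day_type: DayType,
               config: ScorerConfig | None = None) -> float:
    config = config or ScorerConfig()
    return math.exp(-circular_minutes(end.time(), profile.wake_for(day_type)) / config.tau_wake)


def score_duration(episode: CandidateEpisode, config: ScorerConfig | None = None) -> float:
    config = config or ScorerConfig()
    return math.exp(-abs(episode.net_duration_min - config.dur_anchor) / config.tau_dur)


def score_episode(episode: CandidateEpisode, profile: HabitualProfile,
                  day_type: DayType, config: ScorerConfig | None = None) -> ScoredEpisode:
    config = config or ScorerConfig()
    return ScoredEpisode(
        episode=episode,
        s_bed=score_bedtime(episode.start, config),
        s_wake=score_wake(episode.end, profile, day_type, config),
        s_dur=score_duration(episode, config),
    )


def select_overnight_episode(candidates: Sequence[CandidateEpisode],
                             profile: HabitualProfile, day_type: DayType,
                             config: ScorerConfig | None = None) -> ScoredEpisode | None:
    """Highest-likelihood candidate of one night, or None for no estimate.

    Ties break toward the larger net duration, then the earlier start.
    """
    config = config or ScorerConfig()
    scored = [score_episode(c, profile, day_type, config) for c in candidates]
    if not scored:
        return None
    return max(
        scored,
        key=lambda s: (s.likelihood, s.episode.net_duration_min, -s.episode.start.timestamp()),
    )
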