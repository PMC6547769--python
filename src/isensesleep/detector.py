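"""Candidate sleep-episode enumeration and bedtime refinement.

Stage one of the two-stage estimator: every OFF→ON gap of at least
``min_gap`` (default 4 h) between consecutive interaction sessions becomes
a *candidate* sleep episode.  A candidate whose putative bedtime is really
a brief mid-night phone check (the user woke, glanced at the phone, went
back to sleep) is refined: the bedtime is walked back to the last screen-off
at least ``lookback`` (default 2 h) earlier that night, and the check
interval is recorded as a break inside the episode.

The stage is deliberately permissive — a phone left untouched all afternoon
also yields a candidate.  Disambiguation is the scorer's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

from .events import ScreenSession

__all__ = [
    "DetectorConfig",
    "CandidateEpisode",
    "enumerate_gap_candidates",
    "refine_bedtime",
    "detect_nights",
    "night_window_date",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Detection constants.

    min_gap
        Minimum no-interaction OFF→ON gap for a candidate episode (inclusive).
    cluster_radius
        Events within this of one another chain into one interaction
        cluster; a cluster of such short sessions bounding a candidate's
        start is treated as a potential night check.
    lookback
        A night-check cluster is bridged only if an earlier screen-off
        exists at least this long before the cluster, in the same night.
    window_anchor
        Local time-of-day splitting the timeline into noon-to-noon analysis
        windows; noon is maximally distant from typical overnight sleep.
    """

    min_gap: timedelta = timedelta(minutes=240)
    cluster_radius: timedelta = timedelta(minutes=5)
    lookback: timedelta = timedelta(minutes=120)
    window_anchor: time = time(12, 0)

    def __post_init__(self) -> None:
        if not (self.min_gap > self.lookback > self.cluster_radius > timedelta(0)):
            raise ValueError("require min_gap > lookback > cluster_radius > 0")


@dataclass(frozen=True)
class CandidateEpisode:
    """A putative sleep interval: a screen-off .. next screen-on span.

    ``breaks`` holds mid-night phone-check intervals absorbed into the
    episode by refinement; ``net_duration_min`` subtracts their total
    length from the gross span.
    """

    start: datetime
    end: datetime
    night_date: date
    breaks: tuple[tuple[datetime, datetime], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("episode requires start < end")
        prev = self.start
        for b0, b1 in self.breaks:
            if not (self.start < b0 < b1 < self.end):
                raise ValueError("break must lie strictly inside the episode")
            if b0 < prev:
                raise ValueError("breaks must be sorted and disjoint")
            prev = b1

    @property
    def gross_duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    @property
    def net_duration_min(self) -> float:
        brk = sum(((b1 - b0).total_seconds() for b0, b1 in self.breaks), 0.0)
        return self.gross_duration_min - brk / 60.0


def night_window_date(end: datetime, config: DetectorConfig) -> date:
    """Label of the noon-to-noon analysis window containing ``end``.

    The label is the window's closing calendar date, i.e. the wake date of
    an overnight sleep ending that morning.
    """
    local = end  # wall clock carried by the timestamp's own offset
    if local.time() < config.window_anchor:
        return local.date()
    return local.date() + timedelta(days=1)


def enumerate_gap_candidates(sessions: Sequence[ScreenSession],
                             config: DetectorConfig | None = None) -> list[CandidateEpisode]:
    """All OFF→ON gaps of at least ``min_gap`` between consecutive sessions."""
    config = config or DetectorConfig()
    out: list[CandidateEpisode] = []
    for prev, nxt in zip(sessions, sessions[1:]):
        if nxt.on_time - prev.off_time >= config.min_gap:
            out.append(CandidateEpisode(
                start=prev.off_time,
                end=nxt.on_time,
                night_date=night_window_date(nxt.on_time, config),
            ))
    return out


def _window_start(candidate: CandidateEpisode, config: DetectorConfig) -> datetime:
    """Opening instant of the analysis window holding the candidate's end."""
    anchor_date = candidate.night_date - timedelta(days=1)
    return datetime.combine(anchor_date, config.window_anchor, tzinfo=candidate.end.tzinfo)


def _cluster_before(sessions: Sequence[ScreenSession], idx: int,
                    config: DetectorConfig) -> tuple[int, int]:
    """Maximal chain of short sessions ending at sessions[idx].

    Chains backwards over sessions whose own span is below
    ``cluster_radius`` and whose inter-session spacing is below
    ``cluster_radius``.  Returns (first_idx, last_idx) inclusive; an empty
    chain (the session at idx is a long interaction) returns (idx+1, idx).
    """
    r = config.cluster_radius
    if sessions[idx].off_time - sessions[idx].on_time >= r:
        return idx + 1, idx
    first = idx
    while first > 0:
        prev = sessions[first - 1]
        if (sessions[first].on_time - prev.off_time < r
                and prev.off_time - prev.on_time < r):
            first -= 1
        else:
            break
    return first, idx


def refine_bedtime(candidate: CandidateEpisode, sessions: Sequence[ScreenSession],
                   config: DetectorConfig | None = None) -> CandidateEpisode:
    """Walk a candidate's bedtime back across mid-night phone-check clusters.

    If the session ending at the candidate's start is (part of) a short
    interaction cluster, and an earlier session's screen-off exists at
    least ``lookback`` before that cluster within the same analysis
    window, the start moves back to that screen-off and the cluster is
    recorded as an in-episode break.  Applied to fixpoint: the earlier
    bedtime may itself bound another night check.
    """
    config = config or DetectorConfig()
    win_start = _window_start(candidate, config)
    # index of the session whose off_time is the current start
    by_off = {s.off_time: i for i, s in enumerate(sessions)}
    start = candidate.start
    breaks: list[tuple[datetime, datetime]] = list(candidate.breaks)
    while True:
        idx = by_off.get(start)
        if idx is None or idx == 0:
            break
        first, last = _cluster_before(sessions, idx, config)
        if first > last:          # long interaction: a genuine bedtime
            break
        prev = sessions[first - 1] if first > 0 else None
        if prev is None:
            break
        cluster_open = sessions[first].on_time
        if cluster_open - prev.off_time < config.lookback:
            break
        if prev.off_time < win_start:   # earlier off is outside this night
            break
        breaks.insert(0, (cluster_open, sessions[last].off_time))
        start = prev.off_time
    if start == candidate.start:
        return candidate
    return replace(candidate, start=start, breaks=tuple(breaks))


def detect_nights(sessions: Sequence[ScreenSession],
                  config: DetectorConfig | None = None) -> dict[date, list[CandidateEpisode]]:
    """Enumerate and refine candidates over a whole stream, grouped per night.

    Returns a mapping from analysis-window label (the wake date) to the
    refined candidates whose end falls in that window.  Windows spanned by
    the stream but holding no candidate map to an empty list (no estimate).
    """
    config = config or DetectorConfig()
    candidates = [refine_bedtime(c, sessions, config)
                  for c in enumerate_gap_candidates(sessions, config)]
    nights: dict[date, list[CandidateEpisode]] = {}
    if sessions:
        d0 = night_window_date(sessions[0].on_time, config)
        d1 = night_window_date(sessions[-1].off_time, config)
        d = d0
        while d <= d1:
            nights[d] = []
            d += timedelta(days=1)
    for c in candidates:
        nights.setdefault(c.night_date, []).append(c)
    return nights
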