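"""End-to-end sleep estimation: detect candidates, learn the habitual wake
profile from the whole log, score and select one episode per night.

The habitual wake time is bootstrapped, since it is itself derived from
the log being analysed: a provisional profile seeds from the end of the
longest refined candidate in each night window, episodes are selected with
it, and the profile is re-estimated once from the selected episodes before
the final selection pass.  On regular sleepers the second pass changes
nothing; it exists to wash out nights whose longest gap was not the sleep.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

from .detector import CandidateEpisode, DetectorConfig, detect_nights
from .events import ScreenEventRecord, ScreenSession, pair_sessions
from .scorer import (DayType, HabitualProfile, ScorerConfig, ScoredEpisode,
                     day_type_of, estimate_habitual_wake, select_overnight_episode)

__all__ = ["SleepEstimate", "estimate_sleep", "estimate_from_events",
           "build_profile", "write_estimates_csv", "read_estimates_csv"]


@dataclass(frozen=True)
class SleepEstimate:
    """One night's selected sleep episode with its scores."""

    night_date: date
    day_type: DayType
    start: datetime
    end: datetime
    gross_min: float
    net_min: float
    likelihood: float
    s_bed: float
    s_wake: float
    s_dur: float


def build_profile(selected: dict[date, ScoredEpisode | None]) -> HabitualProfile:
    ends = [(s.episode.end, day_type_of(d)) for d, s in selected.items() if s is not None]
    n = len(ends)
    return HabitualProfile(
        wake_weekday=estimate_habitual_wake(ends, "weekday"),
        wake_weekend=estimate_habitual_wake(ends, "weekend"),
        derived_from=max(n, 1),
    )


def _select_all(nights: dict[date, list[CandidateEpisode]], profile: HabitualProfile,
                config: ScorerConfig) -> dict[date, ScoredEpisode | None]:
    return {d: select_overnight_episode(cands, profile, day_type_of(d), config)
            for d, cands in nights.items()}


def estimate_sleep(sessions: Sequence[ScreenSession],
                   detector_config: DetectorConfig | None = None,
                   scorer_config: ScorerConfig | None = None) -> list[SleepEstimate]:
    """Estimate one sleep episode per night from an interaction-session stream.

    Nights without any candidate are omitted from the result (no estimate).
    """
    detector_config = detector_config or DetectorConfig()
    scorer_config = scorer_config or ScorerConfig()
    nights = detect_nights(sessions, detector_config)

    # provisional wake profile: end of the longest refined candidate per night
    seeds = [(max(cands, key=lambda c: c.net_duration_min).end, day_type_of(d))
             for d, cands in nights.items() if cands]
    profile = HabitualProfile(
        wake_weekday=estimate_habitual_wake(seeds, "weekday"),
        wake_weekend=estimate_habitual_wake(seeds, "weekend"),
        derived_from=max(len(seeds), 1),
    )
    selected = _select_all(nights, profile, scorer_config)
    # one refinement pass from the episodes actually selected
    profile = build_profile(selected)
    selected = _select_all(nights, profile, scorer_config)

    out: list[SleepEstimate] = []
    for d in sorted(selected):
        s = selected[d]
        if s is None:
            continue
        out.append(SleepEstimate(
            night_date=d, day_type=day_type_of(d),
            start=s.episode.start, end=s.episode.end,
            gross_min=s.episode.gross_duration_min,
            net_min=s.episode.net_duration_min,
            likelihood=s.likelihood, s_bed=s.s_bed, s_wake=s.s_wake, s_dur=s.s_dur,
        ))
    return out


def estimate_from_events(events: Sequence[ScreenEventRecord], **kwargs) -> list[SleepEstimate]:
    return estimate_sleep(pair_sessions(events), **kwargs)


_EST_HEADER = ["night_date", "day_type", "start", "end", "gross_min", "net_min",
               "likelihood", "s_bed", "s_wake", "s_dur"]


def write_estimates_csv(estimates: Sequence[SleepEstimate], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EST_HEADER)
        for e in estimates:
            w.writerow([e.night_date.isoformat(), e.day_type,
                        e.start.isoformat(), e.end.isoformat(),
                        f"{e.gross_min:.3f}", f"{e.net_min:.3f}",
                        f"{e.likelihood:.6g}", f"{e.s_bed:.6g}",
                        f"{e.s_wake:.6g}", f"{e.s_dur:.6g}"])


def read_estimates_csv(path: str | Path) -> list[SleepEstimate]:
    out: list[SleepEstimate] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SleepEstimate(
                night_date=date.fromisoformat(row["night_date"]),
                day_type=row["day_type"],  # type: ignore[arg-type]
                start=datetime.fromisoformat(row["start"]),
                end=datetime.fromisoformat(row["end"]),
                gross_min=float(row["gross_min"]),
                net_min=float(row["net_min"]),
                likelihood=float(row["likelihood"]),
                s_bed=float(row["s_bed"]),
                s_wake=float(row["s_wake"]),
                s_dur=float(row["s_dur"]),
            ))
    return out
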