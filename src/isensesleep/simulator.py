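"""Synthetic paired (screen-event log, ground-truth sleep) generation.

The generator emulates the data-collection setting the estimator is built
for: habitual sleepers whose last phone interaction precedes sleep onset
by a short gap and whose first interaction follows wake by another short
gap, with Poisson daytime usage, occasional brief mid-night phone checks,
and an actigraphy-style ground truth that records interruptions and
segments of unknown classification the way a sleep-tracking smartwatch
does.

Two engagement presets are provided.  ``student`` models a high-engagement,
digitally native user (short pre-sleep/post-wake gaps, frequent daytime
sessions, more night checks); ``working_mother`` models a lower-engagement
user whose last and first interactions sit much further from the sleep
boundary and who uses the phone less during the day.  The contrast drives
the estimator's error apart between the two groups by construction.

A mid-night phone check is sampled, when it occurs, uniformly over the
part of the night at least two hours after sleep onset and at least four
hours before wake: the pattern of a brief awakening after the first sleep
cycles, with the consolidated block of sleep still to come.  A check also
leaves an interruption in the ground truth over the same interval — the
wearer was demonstrably awake.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .events import ScreenEventKind, ScreenEventRecord

__all__ = [
    "UserProfile", "PRESETS", "SegmentLabel", "RawSleepSegment",
    "GroundTruthSleep", "sample_user_days", "consolidate_ground_truth",
    "write_truth_csv", "read_truth_csv", "load_profile", "save_profile",
]

_TZ = timezone(timedelta(hours=1))  # fixed local offset for generated logs


@dataclass(frozen=True)
class UserProfile:
    """Behavioural parameters of one simulated user.

    Times of day are local wall-clock; all durations and SDs in minutes.
    Gaps are exponential, session and interruption lengths lognormal
    (median/sigma parameterisation), bed/wake times normal truncated at
    ±3 SD.
    """

    bedtime_mean: time = time(23, 30)
    bedtime_sd: float = 45.0
    wake_mean_weekday: time = time(7, 0)
    wake_sd_weekday: float = 30.0
    wake_mean_weekend: time = time(8, 30)
    wake_sd_weekend: float = 45.0
    pre_sleep_gap_mean: float = 10.0
    post_wake_gap_mean: float = 10.0
    day_sessions_per_hour: float = 2.0
    session_length_median: float = 1.5
    session_length_sigma: float = 1.0
    night_check_prob: float = 0.3
    interruption_prob: float = 0.2
    interruption_length_median: float = 5.0
    interruption_length_sigma: float = 0.5
    unknown_segment_prob: float = 0.1
    unknown_length_median: float = 8.0
    unknown_length_sigma: float = 0.5
    engagement_preset: str | None = None

    def validate(self) -> None:
        for name in ("night_check_prob", "interruption_prob", "unknown_segment_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("bedtime_sd", "wake_sd_weekday", "wake_sd_weekend",
                     "session_length_median", "session_length_sigma",
                     "interruption_length_median", "interruption_length_sigma",
                     "unknown_length_median", "unknown_length_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pre_sleep_gap_mean", "post_wake_gap_mean", "day_sessions_per_hour"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


PRESETS: dict[str, UserProfile] = {
    "student": UserProfile(engagement_preset="student"),
    "working_mother": UserProfile(
        bedtime_mean=time(23, 0), bedtime_sd=60.0,
        wake_mean_weekday=time(6, 30), wake_sd_weekday=30.0,
        wake_mean_weekend=time(7, 30), wake_sd_weekend=60.0,
        pre_sleep_gap_mean=45.0, post_wake_gap_mean=60.0,
        day_sessions_per_hour=0.8,
        night_check_prob=0.15,
        interruption_prob=0.15,
        engagement_preset="working_mother",
    ),
}


class SegmentLabel(str, Enum):
    SLEEP = "sleep"
    INTERRUPTION = "interruption"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class RawSleepSegment:
    start: datetime
    end: datetime
    label: SegmentLabel

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment requires start < end")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class GroundTruthSleep:
    """One consolidated nightly sleep episode from the reference device."""

    night_date: date
    start: datetime
    end: datetime
    net_duration_min: float
    segments: tuple[RawSleepSegment, ...] = ()


def _truth_night_date(end: datetime) -> date:
    return end.date() if end.time() < time(12, 0) else end.date() + timedelta(days=1)


def consolidate_ground_truth(segments: Sequence[RawSleepSegment],
                             max_bridge: timedelta = timedelta(minutes=15)) -> list[GroundTruthSleep]:
    """Merge raw smartwatch segments into sleep episodes.

    An interruption strictly shorter than ``max_bridge`` between two sleep
    segments keeps the night as one episode but is subtracted from the net
    duration; a short-enough unknown segment between two sleeps counts
    fully as sleep.  At or above the bridge limit either kind splits the
    night into separate episodes.  Leading/trailing non-sleep segments are
    dropped.
    """
    segs = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping segments at {b.start.isoformat()}")

    episodes: list[GroundTruthSleep] = []
    cur: list[RawSleepSegment] = []     # segments of the open episode
    net = 0.0
    pending: list[RawSleepSegment] = [] # connectors awaiting a following sleep

    def close() -> None:
        nonlocal cur, net, pending
        if cur:
            start, end = cur[0].start, cur[-1].end
            episodes.append(GroundTruthSleep(
                night_date=_truth_night_date(end),
                start=start, end=end, net_duration_min=net,
                segments=tuple(cur)))
        cur, net, pending = [], 0.0, []

    for seg in segs:
        if seg.label is SegmentLabel.SLEEP:
            if cur and pending:
                if all(p.end - p.start < max_bridge for p in pending) and \
                        pending[0].start == cur[-1].end and seg.start == pending[-1].end:
                    for p in pending:
                        cur.append(p)
                        if p.label is SegmentLabel.UNKNOWN:
                            net += p.duration_min   # counts as sleep
                else:
                    close()
            elif cur and seg.start != cur[-1].end:
                close()                  # gap with no connector: device off wrist
            cur.append(seg)
            net += seg.duration_min
            pending = []
        else:
            if cur:
                pending.append(seg)
            # leading connectors (no open episode) are dropped
    close()
    return episodes


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    while True:
        z = rng.standard_normal()
        if abs(z) <= 3.0:
            return mean + sd * z


def _minutes(t: time) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def sample_user_days(profile: UserProfile, n_days: int, seed: int,
                     start_date: date = date(2016, 1, 4),
                     ) -> tuple[list[ScreenEventRecord], list[GroundTruthSleep]]:
    """Generate ``n_days`` nights of screen events plus ground truth.

    ``start_date`` defaults to a Monday so weekday/weekend structure is
    reproducible.  Same (profile, n_days, seed) yields bit-identical
    output.
    """
    profile.validate()
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rng = np.random.default_rng(seed)
    sessions: list[tuple[datetime, datetime]] = []
    truths: list[GroundTruthSleep] = []

    def noon(d: date) -> datetime:
        return datetime.combine(d, time(12, 0), tzinfo=_TZ)

    def midnight(d: date) -> datetime:
        return datetime.combine(d, time(0, 0), tzinfo=_TZ)

    def session_len(minimum: float = 10 / 60.0) -> timedelta:
        return timedelta(minutes=max(_lognormal(rng, profile.session_length_median,
                                                profile.session_length_sigma), minimum))

    # boundary where the current day's daytime usage may begin
    day_begin = datetime.combine(start_date, time(8, 0), tzinfo=_TZ) if n_days else None

    for n in range(n_days):
        d = start_date + timedelta(days=n)
        wake_date = d + timedelta(days=1)
        weekend = wake_date.weekday() >= 5
        wake_mean = profile.wake_mean_weekend if weekend else profile.wake_mean_weekday
        wake_sd = profile.wake_sd_weekend if weekend else profile.wake_sd_weekday
        while True:
            bed_off = _sample_truncnorm(rng, (_minutes(profile.bedtime_mean) - 720.0) % 1440.0,
                                        profile.bedtime_sd)
            wake_off = _sample_truncnorm(rng, _minutes(wake_mean), wake_sd)
            onset = noon(d) + timedelta(minutes=bed_off)
            wake = midnight(wake_date) + timedelta(minutes=wake_off)
            if (wake - onset) >= timedelta(minutes=270):
                break

        # pre-sleep session: last interaction ends pre_sleep_gap before onset
        # (gap capped at 6 h: the user interacts at least once in the evening)
        pre_gap = timedelta(minutes=min(float(rng.exponential(profile.pre_sleep_gap_mean)), 360.0)
                            if profile.pre_sleep_gap_mean > 0 else 0.0)
        presleep_off = onset - pre_gap
        if day_begin is not None:
            presleep_off = max(presleep_off, day_begin + timedelta(minutes=7))
        presleep_on = presleep_off - max(session_len(), timedelta(minutes=5.0 / 60))
        # the pre-sleep interaction itself should be a real session, not a
        # blip the detector could mistake for a night-check cluster
        presleep_on = min(presleep_on, presleep_off - timedelta(minutes=6))

        # daytime sessions between this day's start boundary and the pre-sleep session
        if day_begin is not None and profile.day_sessions_per_hour > 0:
            span_h = max((presleep_on - day_begin).total_seconds() / 3600.0, 0.0)
            k = rng.poisson(profile.day_sessions_per_hour * span_h)
            starts = sorted(float(u) for u in rng.uniform(0.0, span_h * 60.0, size=k))
            cursor = day_begin
            for s_min in starts:
                s_on = day_begin + timedelta(minutes=s_min)
                if s_on < cursor + timedelta(minutes=1):
                    continue
                s_off = s_on + session_len()
                if s_off > presleep_on - timedelta(minutes=1):
                    continue
                sessions.append((s_on, s_off))
                cursor = s_off
        sessions.append((presleep_on, presleep_off))

        # optional mid-night phone check, mirrored as a truth interruption
        truth_cuts: list[RawSleepSegment] = []
        check_lo = onset + timedelta(minutes=120)
        check_hi = wake - timedelta(minutes=240)
        if rng.random() < profile.night_check_prob and check_hi - check_lo > timedelta(minutes=10):
            span = (check_hi - check_lo).total_seconds() / 60.0
            c_on = check_lo + timedelta(minutes=float(rng.uniform(0.0, span - 6.0)))
            c_off = c_on + timedelta(minutes=float(rng.uniform(1.0, 5.0)))
            sessions.append((c_on, c_off))
            truth_cuts.append(RawSleepSegment(c_on, c_off, SegmentLabel.INTERRUPTION))

        # independent phone-free interruption and unknown segment
        for prob, median, sigma, label in (
                (profile.interruption_prob, profile.interruption_length_median,
                 profile.interruption_length_sigma, SegmentLabel.INTERRUPTION),
                (profile.unknown_segment_prob, profile.unknown_length_median,
                 profile.unknown_length_sigma, SegmentLabel.UNKNOWN)):
            if rng.random() >= prob:
                continue
            length = timedelta(minutes=min(_lognormal(rng, median, sigma), 120.0))
            for _ in range(20):
                pos = onset + timedelta(minutes=float(
                    rng.uniform(10.0, (wake - onset).total_seconds() / 60.0 - 10.0 -
                                length.total_seconds() / 60.0)))
                cand = RawSleepSegment(pos, pos + length, label)
                if all(cand.end <= c.start or cand.start >= c.end for c in truth_cuts):
                    truth_cuts.append(cand)
                    break

        # assemble contiguous truth segments for the night
        truth_cuts.sort(key=lambda s: s.start)
        segs: list[RawSleepSegment] = []
        cursor_t = onset
        for cut in truth_cuts:
            if cut.start > cursor_t:
                segs.append(RawSleepSegment(cursor_t, cut.start, SegmentLabel.SLEEP))
            segs.append(cut)
            cursor_t = cut.end
        if wake > cursor_t:
            segs.append(RawSleepSegment(cursor_t, wake, SegmentLabel.SLEEP))
        episodes = consolidate_ground_truth(segs)
        if episodes:
            truths.append(max(episodes, key=lambda e: e.net_duration_min))

        # post-wake session: first interaction post_wake_gap after wake
        post_gap = timedelta(minutes=min(float(rng.exponential(profile.post_wake_gap_mean)), 360.0)
                             if profile.post_wake_gap_mean > 0 else 0.0)
        postwake_on = wake + post_gap
        postwake_off = postwake_on + session_len()
        sessions.append((postwake_on, postwake_off))
        day_begin = postwake_off + timedelta(minutes=1)

    sessions.sort(key=lambda p: p[0])
    events: list[ScreenEventRecord] = []
    for on, off in sessions:
        events.append(ScreenEventRecord(on, ScreenEventKind.SCREEN_ON))
        if rng.random() < 0.85 and off - on > timedelta(seconds=5):
            events.append(ScreenEventRecord(on + timedelta(seconds=2), ScreenEventKind.PRESENT))
        events.append(ScreenEventRecord(off, ScreenEventKind.SCREEN_OFF))
    events.sort(key=lambda e: e.timestamp)
    return events, truths


_TRUTH_HEADER = ["night_date", "start", "end", "net_min"]


def write_truth_csv(truths: Sequence[GroundTruthSleep], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRUTH_HEADER)
        for t in truths:
            w.writerow([t.night_date.isoformat(), t.start.isoformat(),
                        t.end.isoformat(), f"{t.net_duration_min:.3f}"])


def read_truth_csv(path: str | Path) -> list[GroundTruthSleep]:
    out: list[GroundTruthSleep] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(GroundTruthSleep(
                night_date=date.fromisoformat(row["night_date"]),
                start=datetime.fromisoformat(row["start"]),
                end=datetime.fromisoformat(row["end"]),
                net_duration_min=float(row["net_min"])))
    return out


def _profile_to_dict(profile: UserProfile) -> dict:
    d = asdict(profile)
    for k, v in d.items():
        if isinstance(v, time):
            d[k] = v.isoformat(timespec="minutes")
    return d


def save_profile(profile: UserProfile, path: str | Path) -> None:
    path = Path(path)
    data = _profile_to_dict(profile)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_profile(path: str | Path) -> UserProfile:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    for k in ("bedtime_mean", "wake_mean_weekday", "wake_mean_weekend"):
        if k in data and isinstance(data[k], str):
            data[k] = time.fromisoformat(data[k])
    return UserProfile(**data)
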