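"""Agreement metrics between estimated and reference sleep.

Per matched night: absolute duration error (minutes and as a percentage
of the reference duration) and absolute start/end time differences.
Aggregates are arithmetic mean and sample SD, stratified over all days,
weekdays, and weekend days; a paired one-tailed t test on the per-night
durations decides whether the estimator systematically over- or
under-estimates; mean duration is classified against the recommended
420–540 min band for healthy adults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .pipeline import SleepEstimate
from .scorer import DayType, day_type_of
from .simulator import GroundTruthSleep

__all__ = [
    "NightComparison", "MatchResult", "match_nights", "aggregate",
    "paired_one_tailed_t", "TTestResult", "classify_deprivation", "evaluate",
]

Stratum = Literal["all", "weekday", "weekend"]
_METRICS = ("dur_err_min", "dur_err_pct", "start_diff_min", "end_diff_min")


@dataclass(frozen=True)
class NightComparison:
    night_date: object
    day_type: DayType
    est_start: object
    est_end: object
    est_dur_min: float
    truth_start: object
    truth_end: object
    truth_dur_min: float

    @property
    def dur_err_min(self) -> float:
        return abs(self.est_dur_min - self.truth_dur_min)

    @property
    def dur_err_pct(self) -> float:
        return 100.0 * self.dur_err_min / self.truth_dur_min

    @property
    def start_diff_min(self) -> float:
        return abs((self.est_start - self.truth_start).total_seconds()) / 60.0

    @property
    def end_diff_min(self) -> float:
        return abs((self.est_end - self.truth_end).total_seconds()) / 60.0


@dataclass
class MatchResult:
    comparisons: list[NightComparison]
    unmatched_estimates: int
    unmatched_truths: int


def match_nights(estimates: Sequence[SleepEstimate],
                 truths: Sequence[GroundTruthSleep]) -> MatchResult:
    """Inner-join estimates and reference nights on the wake date.

    Unmatched nights on either side are counted and excluded from the
    error means; a duplicated night within one source is a hard error.
    """
    est_by_date: dict = {}
    for e in estimates:
        if e.night_date in est_by_date:
            raise ValueError(f"duplicate estimate for night {e.night_date}")
        est_by_date[e.night_date] = e
    truth_by_date: dict = {}
    for t in truths:
        if t.night_date in truth_by_date:
            raise ValueError(f"duplicate ground truth for night {t.night_date}")
        truth_by_date[t.night_date] = t

    shared = sorted(set(est_by_date) & set(truth_by_date))
    comparisons = []
    for d in shared:
        e, t = est_by_date[d], truth_by_date[d]
        comparisons.append(NightComparison(
            night_date=d, day_type=day_type_of(d),
            est_start=e.start, est_end=e.end, est_dur_min=e.net_min,
            truth_start=t.start, truth_end=t.end, truth_dur_min=t.net_duration_min,
        ))
    return MatchResult(
        comparisons=comparisons,
        unmatched_estimates=len(est_by_date) - len(shared),
        unmatched_truths=len(truth_by_date) - len(shared),
    )


def _mean_sd(values: Sequence[float]) -> dict:
    if not values:
        return {"n": 0, "mean": None, "sd": None}
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return {"n": len(values), "mean": mean, "sd": sd}


def aggregate(comparisons: Sequence[NightComparison], stratum: Stratum = "all") -> dict:
    """Mean and sample SD (n−1) of each error metric within one stratum."""
    if stratum == "all":
        rows = list(comparisons)
    else:
        rows = [c for c in comparisons if c.day_type == stratum]
    out: dict = {"stratum": stratum, "n_nights": len(rows)}
    for m in _METRICS:
        out[m] = _mean_sd([getattr(c, m) for c in rows])
    out["est_dur_min"] = _mean_sd([c.est_dur_min for c in rows])
    out["truth_dur_min"] = _mean_sd([c.truth_dur_min for c in rows])
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    verdict: Literal["adequate", "differs"]
    direction: Literal["over", "under"] | None


def paired_one_tailed_t(est_durs: Sequence[float], truth_durs: Sequence[float],
                        alpha: float = 0.05) -> TTestResult:
    """Paired one-tailed t test on per-night durations (estimate − truth).

    The tail is taken in the direction of the observed mean difference.
    The estimator is judged "adequate" when p > alpha; the over/under
    direction is reported only for significant results.  Identical paired
    vectors give the t → 0 limit: p = 0.5, adequate.
    """
    est = np.asarray(est_durs, dtype=float)
    truth = np.asarray(truth_durs, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("paired vectors must have equal length")
    n = est.size
    if n < 2:
        raise ValueError("paired t test requires at least 2 pairs")
    d = est - truth
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            t_stat, p = 0.0, 0.5
        else:
            t_stat, p = math.copysign(math.inf, mean), 0.0
    else:
        t_stat = mean / (sd / math.sqrt(n))
        p = float(stats.t.sf(abs(t_stat), df=n - 1))
    verdict = "adequate" if p > alpha else "differs"
    direction = None
    if verdict == "differs" and mean != 0.0:
        direction = "over" if mean > 0 else "under"
    return TTestResult(t=t_stat, p=p, verdict=verdict, direction=direction)


def classify_deprivation(mean_dur_min: float, low: float = 420.0,
                         high: float = 540.0) -> str:
    """Classify a mean nightly duration against the recommended band.

    Below 7 h (420 min) is sleep-deprived; above 9 h (540 min) is long;
    the boundaries themselves count as adequate.
    """
    if mean_dur_min <= 0:
        raise ValueError("mean duration must be positive")
    if mean_dur_min < low:
        return "deprived"
    if mean_dur_min > high:
        return "long"
    return "adequate"


def evaluate(estimates: Sequence[SleepEstimate], truths: Sequence[GroundTruthSleep],
             alpha: float = 0.05) -> dict:
    """Full evaluation report: stratified errors, paired t, deprivation flags."""
    matched = match_nights(estimates, truths)
    comps = matched.comparisons
    report: dict = {
        "n_matched": len(comps),
        "unmatched_estimates": matched.unmatched_estimates,
        "unmatched_truths": matched.unmatched_truths,
        "strata": {s: aggregate(comps, s) for s in ("all", "weekday", "weekend")},
    }
    if len(comps) >= 2:
        tt = paired_one_tailed_t([c.est_dur_min for c in comps],
                                 [c.truth_dur_min for c in comps], alpha=alpha)
        report["paired_t"] = {"t": tt.t, "p": tt.p, "verdict": tt.verdict,
                              "direction": tt.direction}
    if comps:
        est_mean = float(np.mean([c.est_dur_min for c in comps]))
        truth_mean = float(np.mean([c.truth_dur_min for c in comps]))
        report["deprivation"] = {
            "estimate": classify_deprivation(est_mean),
            "truth": classify_deprivation(truth_mean),
            "est_mean_dur_min": est_mean,
            "truth_mean_dur_min": truth_mean,
        }
    return report
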