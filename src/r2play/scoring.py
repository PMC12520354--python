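"""Per-repetition metrics, multi-domain cost scores, and cohort summaries.

Performance on a repetition is summarized by three metrics:

* completion time, standardized as **seconds per tablet** — repetition span
  (minus exercise pauses, by default) divided by the number of correct
  selections, so levels with fewer selections remain comparable;
* **errors** — the count of incorrect tablet selections;
* **average HR** — time-weighted mean heart rate over the repetition span.

A multi-domain cost score is the percent change in a metric between a
baseline level/condition and a more demanding one::

    cost = (challenge - baseline) / baseline * 100

Where a standard condition or motor task is duplicated, the *best* of the two
repetitions (shortest time, fewest errors, lowest average HR) serves as the
baseline.  Six costs are produced: exertion (number-letter vs exercise),
cognitive moderate (vs go/no-go), cognitive high (vs Stroop), auditory
interference and scramble (per-level standard best vs the matching condition
repetition, averaged over the four core levels), and fatigue (motor task pre
vs post).  Positive values indicate degraded performance under the added
challenge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .session import RepetitionRecord, SessionRecord

__all__ = [
    "COSTS",
    "METRICS",
    "RepMetrics",
    "CostValue",
    "CostScores",
    "CohortSummary",
    "seconds_per_tablet",
    "avg_hr_over",
    "rep_metrics",
    "best_of",
    "cost_score",
    "compute_cost_scores",
    "summarize_cohort",
    "round2",
]

COSTS = ("exertion", "cognitive_moderate", "cognitive_high", "auditory", "scramble", "fatigue")
METRICS = ("time", "errors", "hr")

#: machine-readable reasons a cost/metric is undefined
ZERO_BASELINE = "zero_baseline"
MISSING_HR = "missing_hr"
MISSING_LEVEL = "missing_level"


def round2(x: float) -> float:
    """Round half-up to 2 decimals (reporting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RepMetrics:
    """The three per-repetition metrics; None marks an undefined value."""

    seconds_per_tablet: float | None
    errors: int
    avg_hr_bpm: float | None


@dataclass(frozen=True)
class CostValue:
    value: float | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class CostScores:
    """All six costs x three metrics for one session."""

    scores: dict[str, dict[str, CostValue]]

    def get(self, cost: str, metric: str) -> CostValue:
        return self.scores[cost][metric]

    def to_dict(self) -> dict:
        return {
            cost: {
                metric: {"value": cv.value, "reason": cv.reason}
                for metric, cv in by_metric.items()
            }
            for cost, by_metric in self.scores.items()
        }


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive block used for cohort reporting: mean +/- SD (95% CI) and
    median (IQR)."""

    n: int
    mean: float
    sd_sample: float | None
    ci95: tuple[float, float] | None
    median: float
    iqr: float
    min: float
    max: float


def seconds_per_tablet(rep: RepetitionRecord, pause_exclusion: bool = True) -> float | None:
    """Repetition completion time per correct selection.

    Exercise-beep pauses are excluded from the numerator by default so the
    exercise level's metric reflects trail speed, not exercise time.  Returns
    None when no correct taps were recorded.
    """
    n = rep.n_correct
    if n == 0:
        return None
    span = rep.span_s - (rep.pause_s if pause_exclusion else 0.0)
    return span / n


def avg_hr_over(hr_stream, start_s: float, end_s: float) -> float | None:
    """Time-weighted (trapezoidal) mean HR over [start_s, end_s].

    Samples are interpolated to the interval edges when the stream covers
    them; returns None when no samples fall in the interval (e.g., HR/event
    synchronization was lost for that repetition).
    """
    ts = np.array([h.t_s for h in hr_stream], dtype=float)
    bpm = np.array([h.bpm for h in hr_stream], dtype=float)
    inside = (ts >= start_s) & (ts <= end_s)
    if not inside.any():
        return None
    t_in, b_in = ts[inside], bpm[inside]
    # extend to the interval edges by interpolation where the stream brackets them
    if ts[0] <= start_s and t_in[0] > start_s:
        t_in = np.insert(t_in, 0, start_s)
        b_in = np.insert(b_in, 0, np.interp(start_s, ts, bpm))
    if ts[-1] >= end_s and t_in[-1] < end_s:
        t_in = np.append(t_in, end_s)
        b_in = np.append(b_in, np.interp(end_s, ts, bpm))
    if len(t_in) == 1 or t_in[-1] == t_in[0]:
        return float(b_in.mean())
    return float(np.trapezoid(b_in, t_in) / (t_in[-1] - t_in[0]))


def rep_metrics(rep: RepetitionRecord, hr_stream=(), pause_exclusion: bool = True) -> RepMetrics:
    return RepMetrics(
        seconds_per_tablet=seconds_per_tablet(rep, pause_exclusion=pause_exclusion),
        errors=rep.n_errors,
        avg_hr_bpm=avg_hr_over(hr_stream, rep.start_s, rep.end_s) if len(hr_stream) else None,
    )


def best_of(values) -> float | None:
    """Best (minimum) value over repetitions, skipping undefined entries.

    "Best" is the minimum for every metric: shortest completion time, fewest
    errors, lowest average heart rate.
    """
    defined = [v for v in values if v is not None]
    return min(defined) if defined else None


def cost_score(baseline: float | None, challenge: float | None,
               undefined_reason: str = MISSING_LEVEL) -> CostValue:
    """Percent change from baseline to challenge; undefined on zero baseline.

    A zero baseline (typically an error count of 0) makes the percent change
    ill-defined — this is why error-based costs frequently cannot be computed
    for healthy, accurate participants.
    """
    if baseline is None or challenge is None:
        return CostValue(None, undefined_reason)
    if baseline == 0:
        return CostValue(None, ZERO_BASELINE)
    return CostValue(float((challenge - baseline) / baseline * 100.0))


def _metric_of(m: RepMetrics, metric: str) -> float | None:
    if metric == "time":
        return m.seconds_per_tablet
    if metric == "errors":
        return float(m.errors)
    if metric == "hr":
        return m.avg_hr_bpm
    raise ValueError(f"unknown metric {metric!r}")


def compute_cost_scores(session: SessionRecord, pause_exclusion: bool = True) -> CostScores:
    """All six multi-domain cost scores for one session, per metric.

    Level-to-level costs (exertion, cognitive moderate/high, fatigue) compare
    best-of-two standard/motor repetitions.  Condition costs (auditory,
    scramble) compare the unweighted mean over the four core levels of the
    per-level standard best against the mean of the per-level condition
    repetition.
    """
    from .protocol import CORE_LEVELS  # avoid import cycle at module load

    _cache: dict[int, RepMetrics] = {}

    def metrics_for(rep: RepetitionRecord) -> RepMetrics:
        key = id(rep)
        if key not in _cache:
            _cache[key] = rep_metrics(rep, session.hr_stream, pause_exclusion=pause_exclusion)
        return _cache[key]

    def level_best(level_kind: str, condition: str | None, metric: str) -> float | None:
        """Best value over the level's repetitions matching the condition."""
        if not session.has_level(level_kind):
            return None
        reps = session.level(level_kind)
        if condition is not None:
            reps = tuple(r for r in reps if r.condition == condition)
        if not reps:
            return None
        return best_of(_metric_of(metrics_for(r), metric) for r in reps)

    def condition_mean(condition: str, metric: str) -> tuple[float | None, str]:
        """Unweighted mean over core levels of the single condition rep."""
        vals = []
        for lk in CORE_LEVELS:
            if not session.has_level(lk):
                return None, MISSING_LEVEL
            reps = [r for r in session.level(lk) if r.condition == condition]
            if not reps:
                return None, MISSING_LEVEL
            v = _metric_of(metrics_for(reps[0]), metric)
            if v is None:
                return None, MISSING_HR if metric == "hr" else MISSING_LEVEL
            vals.append(v)
        return float(np.mean(vals)), ""

    def standard_mean(metric: str) -> tuple[float | None, str]:
        """Unweighted mean over core levels of the per-level standard best."""
        vals = []
        for lk in CORE_LEVELS:
            v = level_best(lk, "standard", metric)
            if v is None:
                reason = MISSING_HR if (metric == "hr" and session.has_level(lk)) else MISSING_LEVEL
                return None, reason
            vals.append(v)
        return float(np.mean(vals)), ""

    scores: dict[str, dict[str, CostValue]] = {c: {} for c in COSTS}
    pairs = {
        "exertion": ("number_letter", "exercise"),
        "cognitive_moderate": ("number_letter", "go_no_go"),
        "cognitive_high": ("number_letter", "stroop"),
        "fatigue": ("motor_pre", "motor_post"),
    }
    for cost, (base_lk, chal_lk) in pairs.items():
        base_cond = "standard" if base_lk in CORE_LEVELS else None
        chal_cond = "standard" if chal_lk in CORE_LEVELS else None
        for metric in METRICS:
            b = level_best(base_lk, base_cond, metric)
            c = level_best(chal_lk, chal_cond, metric)
            reason = MISSING_HR if metric == "hr" and (
                session.has_level(base_lk) and session.has_level(chal_lk)
            ) else MISSING_LEVEL
            scores[cost][metric] = cost_score(b, c, undefined_reason=reason)

    for cost, condition in (("auditory", "auditory"), ("scramble", "scramble")):
        for metric in METRICS:
            b, b_reason = standard_mean(metric)
            c, c_reason = condition_mean(condition, metric)
            scores[cost][metric] = cost_score(b, c, undefined_reason=b_reason or c_reason or MISSING_LEVEL)

    return CostScores(scores=scores)


def _tukey_hinges(sorted_vals: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower/upper halves, middle value shared
    when n is odd."""
    n = len(sorted_vals)
    half = (n + 1) // 2
    lower = sorted_vals[:half]
    upper = sorted_vals[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def summarize_cohort(values, quartile: str = "linear") -> CohortSummary:
    """Descriptive summary of a cohort of values.

    SD uses the sample (n-1) convention; the 95% CI is the normal
    approximation mean +/- 1.96*SD/sqrt(n).  Quartiles for the IQR use linear
    interpolation by default, or Tukey hinges with ``quartile="tukey"``.
    SD and CI are undefined (None) at n = 1.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    n = len(vals)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    mean = float(vals.mean())
    if n >= 2:
        sd = float(vals.std(ddof=1))
        half = 1.96 * sd / math.sqrt(n)
        ci: tuple[float, float] | None = (mean - half, mean + half)
    else:
        sd, ci = None, None
    srt = np.sort(vals)
    median = float(np.median(srt))
    if quartile == "linear":
        q1, q3 = (float(q) for q in np.percentile(srt, [25, 75], method="linear"))
    elif quartile == "tukey":
        q1, q3 = _tukey_hinges(srt)
    else:
        raise ValueError(f"unknown quartile convention {quartile!r}")
    return CohortSummary(
        n=n, mean=mean, sd_sample=sd, ci95=ci,
        median=median, iqr=q3 - q1, min=float(srt[0]), max=float(srt[-1]),
    )
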