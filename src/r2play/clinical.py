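"""Clinical measures around the core task: exertion, usability, symptoms.

Exertion is summarized over *active assessment time* — repetition spans plus
a 10 s tail after each — as raw average/peak HR and as percentages of the
age-predicted maximal heart rate from the Tanaka equation::

    HRmax = 208 - 0.7 * age

Perceived exertion uses the ten-point pediatric OMNI scale (0-10), reported
as the peak across post-level check-ins.  Usability uses the standard
ten-item System Usability Scale (SUS) with Brooke's 0-4 item contributions,
and symptom check-ins use a four-option response where option 4 ("symptoms
so much worse I had to stop") triggers the stop rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import avg_hr_over
from .session import CheckInRecord, SessionRecord, active_windows

__all__ = [
    "ExertionSummary",
    "SUSResult",
    "tanaka_hrmax",
    "exertion_summary",
    "sus_score",
    "symptom_stop_flag",
]


def tanaka_hrmax(age_years: float) -> float:
    """Age-predicted maximal heart rate (bpm), 208 - 0.7 * age."""
    if not (5 <= age_years <= 80):
        raise ValueError(f"age_years must be in [5, 80], got {age_years}")
    return 208.0 - 0.7 * age_years


@dataclass(frozen=True)
class ExertionSummary:
    """Average/peak HR over active windows, raw and as % of predicted max."""

    avg_hr_bpm: float | None
    peak_hr_bpm: float | None
    avg_pct_max: float | None
    peak_pct_max: float | None
    peak_rpe: int | None
    hrmax_predicted_bpm: float

    def to_dict(self) -> dict:
        return {
            "avg_hr_bpm": self.avg_hr_bpm,
            "peak_hr_bpm": self.peak_hr_bpm,
            "avg_pct_max": self.avg_pct_max,
            "peak_pct_max": self.peak_pct_max,
            "peak_rpe": self.peak_rpe,
            "hrmax_predicted_bpm": self.hrmax_predicted_bpm,
        }


def exertion_summary(session: SessionRecord, hr_averaging: str = "trapezoid") -> ExertionSummary:
    """Exertion over the session's active windows.

    The average is the duration-weighted mean across windows (trapezoidal
    within each window by default; ``hr_averaging="samples"`` uses the plain
    mean of the samples falling inside the windows).  HR fields are None when
    the stream does not overlap any active window (e.g., lost HR/event
    synchronization); the RPE peak is still reported.
    """
    hrmax = tanaka_hrmax(session.participant.age_years)
    windows = active_windows(session)
    peak_rpe = max((c.rpe for c in session.checkins), default=None)

    avg = peak = None
    if session.hr_stream and windows:
        if hr_averaging == "trapezoid":
            weighted, total_t = 0.0, 0.0
            for (s, e) in windows:
                w_avg = avg_hr_over(session.hr_stream, s, e)
                if w_avg is not None:
                    weighted += w_avg * (e - s)
                    total_t += e - s
            avg = weighted / total_t if total_t > 0 else None
        elif hr_averaging == "samples":
            inside = [h.bpm for h in session.hr_stream
                      if any(s <= h.t_s <= e for s, e in windows)]
            avg = float(np.mean(inside)) if inside else None
        else:
            raise ValueError(f"unknown hr_averaging {hr_averaging!r}")
        peaks = [h.bpm for h in session.hr_stream
                 if any(s <= h.t_s <= e for s, e in windows)]
        peak = max(peaks) if peaks else None
        if avg is not None and peak is None:
            peak = avg

    return ExertionSummary(
        avg_hr_bpm=avg,
        peak_hr_bpm=peak,
        avg_pct_max=(100.0 * avg / hrmax) if avg is not None else None,
        peak_pct_max=(100.0 * peak / hrmax) if peak is not None else None,
        peak_rpe=peak_rpe,
        hrmax_predicted_bpm=hrmax,
    )


@dataclass(frozen=True)
class SUSResult:
    responses: tuple[int, ...]
    item_contributions: tuple[int, ...]
    total: float
    band: str


def sus_score(responses) -> SUSResult:
    """Score a ten-item SUS questionnaire (responses 1-5).

    Following Brooke's instrument, odd-numbered (positively worded) items
    contribute ``response - 1`` and even-numbered (negatively worded) items
    contribute ``5 - response``; the total is 2.5x the summed contributions,
    giving a 0-100 score in 2.5-point steps.  Bands: < 68 below average,
    68-80 average-to-good, >= 80 good-to-excellent.
    """
    responses = tuple(int(r) for r in responses)
    if len(responses) != 10:
        raise ValueError(f"SUS requires exactly 10 responses, got {len(responses)}")
    if any(not (1 <= r <= 5) for r in responses):
        raise ValueError(f"SUS responses must be in 1-5, got {responses}")
    contributions = tuple(
        (r - 1) if i % 2 == 0 else (5 - r)  # 0-based index: even index = odd item
        for i, r in enumerate(responses)
    )
    total = 2.5 * sum(contributions)
    if total >= 80:
        band = "good_to_excellent"
    elif total >= 68:
        band = "average_to_good"
    else:
        band = "below_average"
    return SUSResult(responses=responses, item_contributions=contributions,
                     total=total, band=band)


def symptom_stop_flag(checkins) -> dict:
    """Apply the symptom stop rule over ordered check-ins.

    Response 4 ("symptoms so much worse I had to stop") stops the assessment
    at that level; response 3 ("symptoms got worse") is flagged as worsened
    without stopping.
    """
    stop = False
    stop_at = None
    worsened = False
    worsened_at = None
    for i, c in enumerate(checkins):
        # bare integers are accepted for convenience; levels then report
        # 1-based positions
        level = c.after_level if isinstance(c, CheckInRecord) else i + 1
        response = c.symptom_response if isinstance(c, CheckInRecord) else int(c)
        if response not in (1, 2, 3, 4):
            raise ValueError(f"symptom response must be in 1-4, got {response}")
        if response == 3 and not worsened:
            worsened, worsened_at = True, level
        if response == 4:
            stop, stop_at = True, level
            break
    return {"stop": stop, "at_level": stop_at, "worsened": worsened, "worsened_at": worsened_at}
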