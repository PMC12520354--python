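"""Reference values from the prototype's proof-of-concept pilot cohort.

Ten healthy youth athletes (ages 10-22, one wheelchair user) completed the
full assessment administered by five clinicians.  The per-participant values
recorded here — exertion measures, session duration breakdowns, and the
worked cost-score inputs used in the scoring documentation — serve as
regression anchors: the package's summary statistics recompute the published
cohort rows from these raw inputs.

Heart-rate averages are missing (None) for two participants whose HR stream
lost synchronization with the event markers mid-session.
"""

from __future__ import annotations

__all__ = [
    "WORKED_COST_INPUTS",
    "PILOT_EXERTION",
    "PILOT_DURATIONS_MIN",
]

#: Worked cost-score inputs (baseline, challenge), in seconds per tablet:
#: the documented single-participant examples for each of the six costs.
WORKED_COST_INPUTS: dict[str, tuple[float, float]] = {
    "exertion": (1.75, 1.94),            # number-letter vs exercise, standard
    "cognitive_moderate": (1.65, 1.74),  # number-letter vs go/no-go
    "cognitive_high": (1.68, 2.06),      # number-letter vs Stroop
    "auditory": (1.66, 1.81),            # mean standard best vs mean auditory rep
    "scramble": (1.18, 1.44),            # mean standard best vs mean scramble rep
    "fatigue": (0.83, 0.93),             # motor task pre vs post
}

#: Per-participant exertion rows: (participant_id, age_years, avg_hr_bpm,
#: peak_hr_bpm, peak_rpe).  avg HR is None where HR/event synchronization
#: was lost.
PILOT_EXERTION: tuple[tuple[str, int, float | None, float, int], ...] = (
    ("Y1", 14, 154.0, 184.0, 5),
    ("Y2", 14, 128.0, 155.0, 4),
    ("Y3", 13, 172.0, 196.0, 7),
    ("Y4", 13, 137.0, 156.0, 2),
    ("Y5", 15, None, 155.0, 3),
    ("Y6", 21, 117.0, 152.0, 2),
    ("Y7", 22, 155.0, 184.0, 5),
    ("Y8", 15, 115.0, 132.0, 4),
    ("Y9", 22, None, 158.0, 2),
    ("Y10", 10, 134.0, 163.0, 6),
)

#: Per-session assessment durations in minutes:
#: (session_number, configuration, active, total).  Session 1 was extended
#: by unresponsive equipment.
PILOT_DURATIONS_MIN: tuple[tuple[int, float, float, float], ...] = (
    (1, 5.38, 41.48, 46.86),
    (2, 6.05, 25.49, 31.54),
    (3, 4.42, 27.32, 31.74),
    (4, 7.53, 25.16, 32.69),
    (5, 3.46, 24.33, 27.79),
    (6, 5.97, 23.27, 29.24),
    (7, 6.34, 29.58, 35.92),
    (8, 5.76, 23.27, 29.03),
    (9, 6.16, 28.44, 34.60),
    (10, 6.93, 24.25, 31.18),
)
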