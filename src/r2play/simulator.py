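"""Synthetic session generation with controllable demand-loading effects.

The simulator plays a participant through an assessment protocol and emits a
complete session event log, so the scoring pipeline can be exercised — and
its parameter recovery demonstrated — without hardware or participants.

Behavioral model
----------------
* **Tap timing.**  Each correct selection takes a lognormally distributed
  interval with mean ``base_spt * (product of applicable challenge factors)``
  and per-tap coefficient of variation ``noise_cv``.  Intervals are
  apportioned to trail segments in proportion to segment distance,
  normalized so the repetition total is exact in expectation; with
  ``noise_cv = 0`` every repetition's seconds-per-tablet equals the planned
  mean exactly.  Challenge factors multiply per level (exercise, go/no-go,
  Stroop, motor-post fatigue) and per condition (auditory, scramble); a
  factor of 1.10 therefore injects a 10% completion-time cost.
* **Errors.**  Each correct selection is preceded by an incorrect tap with a
  small probability (baseline per-tap rate times a per-challenge odds
  multiplier).  Healthy defaults keep errors rare, so error-based cost
  scores are frequently undefined, as observed with accurate participants.
* **Heart rate.**  First-order exponential relaxation toward a
  level-dependent target intensity (fraction of Tanaka-predicted maximal HR
  above rest) with time constant ``tau_s``, sampled at 1 Hz; HR rises during
  repetitions and decays toward a mildly elevated recovery target during
  breaks.  Exercise-beep pauses insert a high-intensity bout mid-repetition.
* **Check-ins.**  RPE maps from the level's mean %HRmax through
  ``rpe_slope``; symptom responses stay at 1-2 for healthy profiles.

Default effect factors emulate the behavior observed in the healthy pilot
cohort: slow-down under Stroop, scramble, and auditory challenge, slight
speed-up in the exercise and motor-post trails (pacing/learning), and HR
elevation across all challenges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .clinical import tanaka_hrmax
from .protocol import AssessmentProtocol, RepetitionPlan, build_protocol
from .session import (
    CheckInRecord,
    HRSample,
    Participant,
    RepetitionRecord,
    SessionRecord,
    TapEvent,
)

__all__ = [
    "ParticipantProfile",
    "EffectConfig",
    "simulate_session",
    "simulate_cohort",
    "recover_effects",
    "draw_profile",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent behavioral/physiological parameters of one simulated youth."""

    participant_id: str = "SIM"
    age_years: float = 14.0
    wheelchair: bool = False
    base_spt: float = 1.7          # baseline seconds per correct selection
    hr_rest_bpm: float = 70.0
    hr_gain: float = 0.62          # steady-state active intensity, fraction of (HRmax - rest)
    tau_s: float = 30.0            # HR relaxation time constant
    error_rate_base: float = 0.01  # per-selection probability of an incorrect tap
    rpe_slope: float = 0.6         # RPE = clamp(round(slope * %max / 10), 0, 10)

    def __post_init__(self) -> None:
        if self.base_spt <= 0:
            raise ValueError("base_spt must be > 0")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if not (0.0 <= self.error_rate_base <= 1.0):
            raise ValueError("error_rate_base must be a probability")


@dataclass(frozen=True)
class EffectConfig:
    """Injected challenge effects; factors multiply completion time.

    Defaults reproduce the qualitative loading seen in healthy pilot data:
    largest time costs for Stroop and scramble, moderate for auditory,
    negative (speed-up) for exercise and motor-post.
    """

    exercise_f: float = 0.93
    gng_f: float = 0.97
    stroop_f: float = 1.20
    auditory_f: float = 1.09
    scramble_f: float = 1.21
    fatigue_f: float = 0.88

    # per-challenge error-odds multipliers (relative to error_rate_base)
    error_odds: dict = field(default_factory=lambda: {
        "exercise": 1.0, "go_no_go": 2.0, "stroop": 3.0,
        "auditory": 1.5, "scramble": 2.0, "fatigue": 1.0,
    })

    # active HR intensity offsets per level (added to profile.hr_gain)
    hr_offsets: dict = field(default_factory=lambda: {
        "motor_pre": -0.10, "number_letter": 0.0, "exercise": 0.18,
        "go_no_go": 0.02, "stroop": 0.07, "motor_post": 0.10,
    })
    # condition HR intensity offsets
    hr_condition_offsets: dict = field(default_factory=lambda: {
        "standard": 0.0, "auditory": 0.02, "scramble": 0.03,
    })

    noise_cv: float = 0.10         # per-tap lognormal coefficient of variation
    exercise_pause_s: float = 12.0  # three exercise repetitions at the beep

    def __post_init__(self) -> None:
        for name in ("exercise_f", "gng_f", "stroop_f", "auditory_f", "scramble_f", "fatigue_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def null(self) -> "EffectConfig":
        """Copy with every time factor at 1 (no injected effects)."""
        return replace(self, exercise_f=1.0, gng_f=1.0, stroop_f=1.0,
                       auditory_f=1.0, scramble_f=1.0, fatigue_f=1.0)

    def time_factor(self, plan: RepetitionPlan) -> float:
        f = 1.0
        if plan.level_kind == "exercise":
            f *= self.exercise_f
        elif plan.level_kind == "go_no_go":
            f *= self.gng_f
        elif plan.level_kind == "stroop":
            f *= self.stroop_f
        elif plan.level_kind == "motor_post":
            f *= self.fatigue_f
        if plan.condition == "auditory":
            f *= self.auditory_f
        elif plan.condition == "scramble":
            f *= self.scramble_f
        return f

    def error_prob(self, profile: ParticipantProfile, plan: RepetitionPlan) -> float:
        mult = 1.0
        key = {"exercise": "exercise", "go_no_go": "go_no_go", "stroop": "stroop",
               "motor_post": "fatigue"}.get(plan.level_kind)
        if key:
            mult *= self.error_odds.get(key, 1.0)
        if plan.condition in ("auditory", "scramble"):
            mult *= self.error_odds.get(plan.condition, 1.0)
        return min(profile.error_rate_base * mult, 0.5)


def _lognormal_intervals(rng: np.random.Generator, means: np.ndarray, cv: float) -> np.ndarray:
    """Positive intervals with the requested means and per-tap CV (exact means
    at cv = 0)."""
    if cv == 0:
        return means.copy()
    sigma2 = math.log(1.0 + cv * cv)
    z = rng.standard_normal(len(means))
    return means * np.exp(math.sqrt(sigma2) * z - sigma2 / 2.0)


# inter-event gaps in the session timeline (seconds): level orientation
# covers instructions, video demonstration, and practice tracing
_ORIENTATION_GAP_S = 150.0
_REP_BREAK_S = 45.0
_CHECKIN_GAP_S = 60.0
_WARMUP_GAP_S = 60.0
_RECOVERY_INTENSITY = 0.15  # break-time HR target fraction of (HRmax - rest)


def simulate_session(
    protocol: AssessmentProtocol,
    profile: ParticipantProfile,
    effects: EffectConfig | None = None,
    rng: np.random.Generator | None = None,
    config_duration_s: float | None = None,
) -> SessionRecord:
    """Play one participant through the protocol and emit the event log."""
    effects = effects or EffectConfig()
    rng = rng if rng is not None else np.random.default_rng()
    hrmax = tanaka_hrmax(profile.age_years)

    if config_duration_s is None:
        config_duration_s = float(np.clip(rng.normal(360.0, 60.0), 150.0, 600.0))
    t = config_duration_s + _WARMUP_GAP_S

    levels: list[tuple[str, tuple[RepetitionRecord, ...]]] = []
    checkins: list[CheckInRecord] = []
    break_intervals: list[tuple[float, float]] = []
    # (start, end, intensity) blocks driving the HR model
    activity_blocks: list[tuple[float, float, float]] = []

    def mark_break(start: float, end: float) -> None:
        if end > start:
            break_intervals.append((start, end))

    level_pct_max: dict[str, float] = {}

    for level_kind, plans in protocol.levels:
        t += _ORIENTATION_GAP_S
        reps: list[RepetitionRecord] = []
        level_intensities: list[float] = []
        for rep_number, plan in enumerate(plans, start=1):
            if rep_number > 1:
                mark_break(t, t + _REP_BREAK_S)
                t += _REP_BREAK_S
            factor = effects.time_factor(plan)
            correct = plan.correct_items
            n = len(correct)
            # apportion the repetition's planned time across segments by
            # distance, normalized so the rep mean is exact
            seg_d = []
            pos = protocol.layout.start_position
            for it in correct:
                nxt = protocol.layout.position(it.tablet_id)
                seg_d.append(protocol.layout.distance(pos, nxt))
                pos = nxt
            seg_d = np.asarray(seg_d)
            means = profile.base_spt * factor * n * seg_d / seg_d.sum()
            intervals = [float(v) for v in _lognormal_intervals(rng, means, effects.noise_cv)]

            p_err = effects.error_prob(profile, plan)
            start_s = t
            taps: list[TapEvent] = []
            pauses: list[tuple[float, float]] = []
            cursor = start_s
            other_tablets = [tid for tid in protocol.layout.tablet_ids]
            for k, (it, dt) in enumerate(zip(correct, intervals)):
                if p_err > 0 and rng.random() < p_err:
                    wrong = [tid for tid in other_tablets if tid != it.tablet_id]
                    taps.append(TapEvent(
                        t_s=cursor + 0.5 * dt,
                        tablet_id=wrong[rng.integers(len(wrong))],
                        displayed_character=it.character,
                        correct=False,
                    ))
                cursor += dt
                taps.append(TapEvent(
                    t_s=cursor,
                    tablet_id=it.tablet_id,
                    displayed_character=it.character,
                    correct=True,
                ))
                if plan.exercise_trigger is not None and k == plan.exercise_trigger:
                    pauses.append((cursor, cursor + effects.exercise_pause_s))
                    cursor += effects.exercise_pause_s
                    # shift: remaining taps happen after the pause
            end_s = cursor
            # tap times after a pause were already accumulated via cursor
            rep = RepetitionRecord(
                level_kind=plan.level_kind,
                condition=plan.condition,
                rep_number=rep_number,
                start_s=start_s,
                end_s=end_s,
                taps=tuple(sorted(taps, key=lambda tap: tap.t_s)),
                pause_intervals=tuple(pauses),
            )
            reps.append(rep)
            intensity = min(profile.hr_gain
                            + effects.hr_offsets.get(level_kind, 0.0)
                            + effects.hr_condition_offsets.get(plan.condition, 0.0), 0.95)
            activity_blocks.append((rep.start_s, rep.end_s, intensity))
            for ps, pe in pauses:  # exercise bout drives HR hardest
                activity_blocks.append((ps, pe, min(intensity + 0.10, 0.95)))
            level_intensities.append(intensity)
            t = end_s
        levels.append((level_kind, tuple(reps)))

        mark_break(t, t + _CHECKIN_GAP_S)
        t += _CHECKIN_GAP_S
        mean_intensity = float(np.mean(level_intensities))
        target_hr = profile.hr_rest_bpm + mean_intensity * (hrmax - profile.hr_rest_bpm)
        pct = 100.0 * target_hr / hrmax
        level_pct_max[level_kind] = pct
        rpe = int(np.clip(round(profile.rpe_slope * pct / 10.0), 0, 10))
        checkins.append(CheckInRecord(
            after_level=level_kind,
            rpe=rpe,
            symptom_response=int(rng.choice([1, 1, 1, 2])),
        ))

    session_end = t + 30.0
    hr_stream = _simulate_hr(rng, profile, effects, hrmax, activity_blocks,
                             config_duration_s, session_end)

    return SessionRecord(
        participant=Participant(
            id=profile.participant_id,
            age_years=profile.age_years,
            wheelchair=profile.wheelchair,
        ),
        configuration_interval=(0.0, config_duration_s),
        levels=tuple(levels),
        hr_stream=hr_stream,
        checkins=tuple(checkins),
        break_intervals=tuple(break_intervals),
        baseline_pcsi_total=int(rng.integers(0, 12)),
        resting_hr_bpm=profile.hr_rest_bpm,
        sus_responses=None,
    )


def _simulate_hr(rng, profile: ParticipantProfile, effects: EffectConfig, hrmax: float,
                 blocks, config_end_s: float, session_end_s: float) -> tuple[HRSample, ...]:
    """First-order HR kinetics sampled at 1 Hz over the whole session."""
    rest = profile.hr_rest_bpm
    alpha = 1.0 - math.exp(-1.0 / profile.tau_s)
    n_steps = int(session_end_s) + 1
    hr = rest
    samples = []
    blocks = sorted(blocks)
    bi = 0
    noise_sd = 0.8 if effects.noise_cv > 0 else 0.0
    for step in range(n_steps):
        ts = float(step)
        while bi < len(blocks) and blocks[bi][1] < ts:
            bi += 1
        intensity = None
        for s, e, inten in blocks[bi:bi + 4]:
            if s <= ts <= e:
                intensity = max(intensity or 0.0, inten)
        if intensity is not None:
            target = rest + intensity * (hrmax - rest)
        elif ts < config_end_s:
            target = rest
        else:
            target = rest + _RECOVERY_INTENSITY * (hrmax - rest)
        hr += (target - hr) * alpha
        if noise_sd:
            hr += rng.normal(0.0, noise_sd)
        hr = float(np.clip(hr, rest, 0.98 * hrmax))
        samples.append(HRSample(t_s=ts, bpm=round(hr, 1)))
    return tuple(samples)


def draw_profile(rng: np.random.Generator, participant_id: str,
                 age_range: tuple[int, int] = (10, 22)) -> ParticipantProfile:
    """Draw one participant from the default cohort distribution.

    Ages are uniform over the cohort range (10-22 by default); baseline trail
    speed, resting HR, and steady-state intensity vary across plausible
    healthy-youth ranges.  One in ten simulated participants uses a
    wheelchair (metadata flag only; the behavioral model is shared).
    """
    return ParticipantProfile(
        participant_id=participant_id,
        age_years=float(rng.integers(age_range[0], age_range[1] + 1)),
        wheelchair=bool(rng.random() < 0.1),
        base_spt=float(rng.uniform(1.3, 2.1)),
        hr_rest_bpm=float(rng.uniform(60.0, 80.0)),
        hr_gain=float(rng.uniform(0.55, 0.70)),
        tau_s=30.0,
        error_rate_base=0.01,
        rpe_slope=0.6,
    )


def simulate_cohort(
    n: int,
    effects: EffectConfig | None = None,
    seed: int = 0,
    protocol: AssessmentProtocol | None = None,
    age_range: tuple[int, int] = (10, 22),
) -> list[SessionRecord]:
    """Simulate ``n`` independent sessions, reproducible from ``seed``.

    Each participant gets an independently drawn profile and a fresh protocol
    randomization (condition order, trail assignments) derived from the same
    seed sequence.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    root = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        proto = protocol
        if proto is None:
            proto_seed = int(child.generate_state(1)[0] % (2**31))
            from .protocol import ProtocolConfig
            proto = build_protocol(ProtocolConfig(rng_seed=proto_seed))
        profile = draw_profile(rng, participant_id=f"S{i + 1:03d}", age_range=age_range)
        sessions.append(simulate_session(proto, profile, effects, rng))
    return sessions


def recover_effects(sessions, quartile: str = "linear", pause_exclusion: bool = True) -> dict:
    """Cohort median/IQR of each cost x metric across scored sessions.

    Returns ``{cost: {metric: CohortSummary | None}}`` — None where the cost
    was undefined in every session (e.g., error costs with zero baselines).
    """
    from .scoring import COSTS, METRICS, compute_cost_scores, summarize_cohort

    per_cost: dict[str, dict[str, list[float]]] = {
        c: {m: [] for m in METRICS} for c in COSTS
    }
    for session in sessions:
        scores = compute_cost_scores(session, pause_exclusion=pause_exclusion)
        for c in COSTS:
            for m in METRICS:
                cv = scores.get(c, m)
                if cv.defined:
                    per_cost[c][m].append(cv.value)
    return {
        c: {
            m: (summarize_cohort(vals, quartile=quartile) if vals else None)
            for m, vals in by_metric.items()
        }
        for c, by_metric in per_cost.items()
    }
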