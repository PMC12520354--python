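"""Assessment protocol and distance-standardized trail generation.

The assessment is a tablet-based trail-making task: six floor tablets each
display one character of the repeating alphanumeric cycle 1-A-2-B-3-C and the
participant runs between them, tapping the characters in order.  A full
assessment consists of six levels run in a fixed order::

    motor_pre -> number_letter -> exercise -> go_no_go -> stroop -> motor_post

Each of the four core levels (number_letter, exercise, go_no_go, stroop) has
four repetitions: the first is always the standard condition, and repetitions
2-4 are a randomized permutation of {standard, auditory, scramble}.  The
motor task bookends are two standard repetitions each.

Trails are *distance standardized*: the cumulative run distance over the
correct (non-distractor) selections of a repetition is held at 45 m (+/- 1%)
for 12-selection trails and 30 m (+/- 1%) for the 8-selection response
inhibition trails, i.e. approximately 3.75 m per correct selection.  The
generator draws random character-to-tablet assignments and rejects trails
whose path length falls outside the tolerance window.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "CHARACTERS",
    "CORE_LEVELS",
    "LEVEL_ORDER",
    "TabletLayout",
    "SequenceItem",
    "RepetitionPlan",
    "AssessmentProtocol",
    "ProtocolConfig",
    "ConfigurationError",
    "TrailGenerationError",
    "default_layout",
    "build_protocol",
    "path_distance",
    "generate_trail",
    "apply_scramble",
]

#: The repeating alphanumeric cycle connected by the trail.
CHARACTERS = ("1", "A", "2", "B", "3", "C")

CORE_LEVELS = ("number_letter", "exercise", "go_no_go", "stroop")
LEVEL_ORDER = ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")

#: Levels whose trails omit 4 of 12 displayed characters (wrong-color
#: distractors), leaving 8 correct selections over 30 m.
REDUCED_LEVELS = ("go_no_go", "stroop")

CONDITIONS = ("standard", "auditory", "scramble")

_MAX_PROPOSALS = 10_000


class ConfigurationError(ValueError):
    """Raised for invalid protocol configuration (layout, distances, tolerance)."""


class TrailGenerationError(RuntimeError):
    """Raised when no trail satisfying the distance window is found."""

    def __init__(self, message: str, best_distance_m: float | None = None):
        super().__init__(message)
        self.best_distance_m = best_distance_m


@dataclass(frozen=True)
class TabletLayout:
    """Physical positions (meters) of the tablets and the participant start.

    ``tablets`` maps stable tablet identifiers to planar coordinates; the
    start position is where the participant stands before the first selection.
    """

    tablets: tuple[tuple[str, float, float], ...]
    start_position: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.tablets]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("tablet_ids must be unique")
        if len(ids) < 2:
            raise ConfigurationError("layout requires at least 2 tablets")
        for tid, x, y in self.tablets:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ConfigurationError(f"non-finite coordinates for tablet {tid!r}")

    @property
    def tablet_ids(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tablets)

    def position(self, tablet_id: str) -> tuple[float, float]:
        for tid, x, y in self.tablets:
            if tid == tablet_id:
                return (x, y)
        raise KeyError(f"unknown tablet_id {tablet_id!r}")

    def distance(self, a: tuple[float, float], b: tuple[float, float]) -> float:
        return math.hypot(a[0] - b[0], a[1] - b[1])


def default_layout(radius_m: float = 3.1, n_tablets: int = 6) -> TabletLayout:
    """Six tablets on a semicircular arc facing the start position.

    The arc radius is chosen so that a uniformly random no-repeat walk over
    the tablets averages close to 3.75 m per selection, which keeps the
    rejection sampler efficient for both the 45 m and 30 m targets.  The
    shape itself is a package convention — only the distances are
    standardized by the assessment.
    """
    angles = [math.pi * k / (n_tablets - 1) for k in range(n_tablets)]
    tablets = tuple(
        (f"T{k + 1}", round(radius_m * math.cos(a), 6), round(radius_m * math.sin(a), 6))
        for k, a in enumerate(angles)
    )
    return TabletLayout(tablets=tablets, start_position=(0.0, 0.0))


@dataclass(frozen=True)
class SequenceItem:
    """One displayed character in a trail.

    Distractor items are shown in the no-go color for the level and must be
    skipped; they do not count toward the standardized distance.
    """

    character: str
    tablet_id: str
    order_index: int
    is_distractor: bool = False
    display_color: str = "green"

    def __post_init__(self) -> None:
        if self.character not in CHARACTERS:
            raise ValueError(f"character must be one of {CHARACTERS}, got {self.character!r}")
        if self.display_color not in ("green", "red"):
            raise ValueError(f"display_color must be green or red, got {self.display_color!r}")


@dataclass(frozen=True)
class RepetitionPlan:
    """Planned trail for one repetition of one level."""

    level_kind: str
    condition: str
    items: tuple[SequenceItem, ...]
    target_distance_m: float
    tolerance_frac: float = 0.01
    scramble_trigger: int | None = None
    exercise_trigger: int | None = None

    def __post_init__(self) -> None:
        if self.level_kind not in LEVEL_ORDER:
            raise ValueError(f"unknown level_kind {self.level_kind!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if (self.scramble_trigger is not None) != (self.condition == "scramble"):
            raise ValueError("scramble_trigger must be set iff condition is scramble")
        if (self.exercise_trigger is not None) != (self.level_kind == "exercise"):
            raise ValueError("exercise_trigger must be set iff level_kind is exercise")

    @property
    def correct_items(self) -> tuple[SequenceItem, ...]:
        return tuple(it for it in self.items if not it.is_distractor)

    @property
    def n_selections(self) -> int:
        return len(self.correct_items)

    def to_dict(self) -> dict:
        return {
            "level_kind": self.level_kind,
            "condition": self.condition,
            "target_distance_m": self.target_distance_m,
            "tolerance_frac": self.tolerance_frac,
            "scramble_trigger": self.scramble_trigger,
            "exercise_trigger": self.exercise_trigger,
            "items": [
                {
                    "character": it.character,
                    "tablet_id": it.tablet_id,
                    "order_index": it.order_index,
                    "is_distractor": it.is_distractor,
                    "display_color": it.display_color,
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepetitionPlan":
        items = tuple(
            SequenceItem(
                character=i["character"],
                tablet_id=i["tablet_id"],
                order_index=i["order_index"],
                is_distractor=i["is_distractor"],
                display_color=i["display_color"],
            )
            for i in d["items"]
        )
        return cls(
            level_kind=d["level_kind"],
            condition=d["condition"],
            items=items,
            target_distance_m=d["target_distance_m"],
            tolerance_frac=d["tolerance_frac"],
            scramble_trigger=d.get("scramble_trigger"),
            exercise_trigger=d.get("exercise_trigger"),
        )


@dataclass(frozen=True)
class ProtocolConfig:
    """Tunable protocol parameters; defaults match the deployed assessment."""

    layout: TabletLayout = field(default_factory=default_layout)
    per_selection_distance_m: float = 3.75
    full_rep_distance_m: float = 45.0
    reduced_rep_distance_m: float = 30.0
    tolerance_frac: float = 0.01
    rng_seed: int = 0
    #: if True, every repetition of a level reuses the first repetition's
    #: character-to-tablet assignment instead of a fresh draw
    reuse_sequences: bool = False

    def __post_init__(self) -> None:
        for name in ("per_selection_distance_m", "full_rep_distance_m", "reduced_rep_distance_m"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0 < self.tolerance_frac <= 0.1):
            raise ConfigurationError("tolerance_frac must be in (0, 0.1]")

    @classmethod
    def from_file(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "layout" in raw:
            lay = raw["layout"]
            tablets = tuple((str(t[0]), float(t[1]), float(t[2])) for t in lay["tablets"])
            start = tuple(float(v) for v in lay.get("start", (0.0, 0.0)))
            kwargs["layout"] = TabletLayout(tablets=tablets, start_position=start)
        dist = raw.get("distances", {})
        if "per_selection" in dist:
            kwargs["per_selection_distance_m"] = float(dist["per_selection"])
        if "full" in dist:
            kwargs["full_rep_distance_m"] = float(dist["full"])
        if "reduced" in dist:
            kwargs["reduced_rep_distance_m"] = float(dist["reduced"])
        if "tolerance" in dist:
            kwargs["tolerance_frac"] = float(dist["tolerance"])
        if "seed" in raw:
            kwargs["rng_seed"] = int(raw["seed"])
        if "reuse_sequences" in raw:
            kwargs["reuse_sequences"] = bool(raw["reuse_sequences"])
        return cls(**kwargs)


@dataclass(frozen=True)
class AssessmentProtocol:
    """The full plan: ordered levels, each an ordered tuple of repetitions."""

    layout: TabletLayout
    levels: tuple[tuple[str, tuple[RepetitionPlan, ...]], ...]
    per_selection_distance_m: float = 3.75
    full_rep_distance_m: float = 45.0
    reduced_rep_distance_m: float = 30.0
    rng_seed: int = 0

    @property
    def repetitions(self) -> tuple[RepetitionPlan, ...]:
        return tuple(itertools.chain.from_iterable(reps for _, reps in self.levels))

    def level(self, level_kind: str) -> tuple[RepetitionPlan, ...]:
        for kind, reps in self.levels:
            if kind == level_kind:
                return reps
        raise KeyError(f"protocol has no level {level_kind!r}")

    def to_json(self) -> str:
        doc = {
            "schema": "r2play-protocol/1",
            "rng_seed": self.rng_seed,
            "per_selection_distance_m": self.per_selection_distance_m,
            "full_rep_distance_m": self.full_rep_distance_m,
            "reduced_rep_distance_m": self.reduced_rep_distance_m,
            "layout": {
                "tablets": [list(t) for t in self.layout.tablets],
                "start": list(self.layout.start_position),
            },
            "levels": [
                {"level_kind": kind, "repetitions": [r.to_dict() for r in reps]}
                for kind, reps in self.levels
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AssessmentProtocol":
        doc = json.loads(text)
        layout = TabletLayout(
            tablets=tuple((t[0], float(t[1]), float(t[2])) for t in doc["layout"]["tablets"]),
            start_position=tuple(doc["layout"]["start"]),
        )
        levels = tuple(
            (lv["level_kind"], tuple(RepetitionPlan.from_dict(r) for r in lv["repetitions"]))
            for lv in doc["levels"]
        )
        return cls(
            layout=layout,
            levels=levels,
            per_selection_distance_m=doc["per_selection_distance_m"],
            full_rep_distance_m=doc["full_rep_distance_m"],
            reduced_rep_distance_m=doc["reduced_rep_distance_m"],
            rng_seed=doc["rng_seed"],
        )


def path_distance(layout: TabletLayout, items) -> float:
    """Cumulative Euclidean run distance over the correct selections.

    Starts at the layout's start position, then sums consecutive
    tablet-to-tablet segments.  Distractor items are skipped (the participant
    never visits them).
    """
    pos = layout.start_position
    total = 0.0
    for it in items:
        if it.is_distractor:
            continue
        nxt = layout.position(it.tablet_id)
        total += layout.distance(pos, nxt)
        pos = nxt
    return total


def _cycle_characters(n: int, start: int = 0) -> list[str]:
    return [CHARACTERS[(start + k) % len(CHARACTERS)] for k in range(n)]


def _draw_assignment(rng: np.random.Generator, ids: tuple[str, ...], n: int,
                     prev: str | None = None) -> list[str]:
    """Random tablet per selection, consecutive selections on distinct tablets."""
    out: list[str] = []
    for _ in range(n):
        choices = [t for t in ids if t != prev]
        tid = choices[rng.integers(len(choices))]
        out.append(tid)
        prev = tid
    return out


def _default_scramble_trigger(n_selections: int) -> int:
    # halfway through the trail: after the 6th correct selection of 12
    # (0-based index 5), after the 4th of 8 (index 3)
    return n_selections // 2 - 1


def generate_trail(
    layout: TabletLayout,
    level_kind: str,
    condition: str,
    target_distance_m: float,
    tolerance_frac: float = 0.01,
    rng: np.random.Generator | None = None,
    scramble_trigger: int | None = None,
    exercise_trigger: int | None = None,
) -> RepetitionPlan:
    """Draw a distance-standardized trail for one repetition.

    Rejection sampling: character-to-tablet assignments are drawn uniformly
    (no consecutive repeats along the correct path) until the path length over
    correct selections lands within ``target_distance_m * (1 +/- tolerance_frac)``,
    bounded at 10,000 proposals.  For response-inhibition levels, 4 of the 12
    displayed items are distractors shown in the level's no-go color
    (go_no_go: distractors red, targets green; stroop: distractors green,
    targets red).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if level_kind not in LEVEL_ORDER:
        raise ConfigurationError(f"unknown level_kind {level_kind!r}")
    reduced = level_kind in REDUCED_LEVELS
    n_displayed = 12
    n_correct = 8 if reduced else 12
    if reduced:
        correct_color, distractor_color = ("green", "red") if level_kind == "go_no_go" else ("red", "green")
    else:
        correct_color, distractor_color = "green", "red"

    tol = tolerance_frac * target_distance_m
    ids = layout.tablet_ids
    correct_chars = _cycle_characters(n_correct)

    best = None
    best_err = math.inf
    for _ in range(_MAX_PROPOSALS):
        assignment = _draw_assignment(rng, ids, n_correct)
        pos = layout.start_position
        dist = 0.0
        for tid in assignment:
            nxt = layout.position(tid)
            dist += layout.distance(pos, nxt)
            pos = nxt
        err = abs(dist - target_distance_m)
        if err < best_err:
            best_err, best = err, dist
        if err <= tol:
            break
    else:
        raise TrailGenerationError(
            f"no trail within {target_distance_m} m +/- {tolerance_frac:.0%} for "
            f"{level_kind} after {_MAX_PROPOSALS} proposals "
            f"(best achieved {best:.2f} m)",
            best_distance_m=best,
        )

    items: list[SequenceItem] = []
    if reduced:
        # interleave 4 distractor slots among the 12 displayed positions
        distractor_slots = set(rng.choice(n_displayed, size=n_displayed - n_correct, replace=False).tolist())
        correct_iter = iter(zip(correct_chars, assignment))
        # distractors continue the cycle beyond the correct path so every
        # character on screen is plausible
        extra_chars = iter(_cycle_characters(n_displayed - n_correct, start=n_correct))
        for idx in range(n_displayed):
            if idx in distractor_slots:
                items.append(SequenceItem(
                    character=next(extra_chars),
                    tablet_id=ids[rng.integers(len(ids))],
                    order_index=idx,
                    is_distractor=True,
                    display_color=distractor_color,
                ))
            else:
                ch, tid = next(correct_iter)
                items.append(SequenceItem(ch, tid, idx, False, correct_color))
    else:
        for idx, (ch, tid) in enumerate(zip(correct_chars, assignment)):
            items.append(SequenceItem(ch, tid, idx, False, correct_color))

    if condition == "scramble" and scramble_trigger is None:
        scramble_trigger = _default_scramble_trigger(n_correct)
    if level_kind == "exercise" and exercise_trigger is None:
        exercise_trigger = int(rng.integers(1, n_correct - 1))

    plan = RepetitionPlan(
        level_kind=level_kind,
        condition=condition,
        items=tuple(items),
        target_distance_m=target_distance_m,
        tolerance_frac=tolerance_frac,
        scramble_trigger=scramble_trigger if condition == "scramble" else None,
        exercise_trigger=exercise_trigger if level_kind == "exercise" else None,
    )
    if condition == "scramble":
        plan = apply_scramble(plan, layout, rng)
    return plan


def apply_scramble(plan: RepetitionPlan, layout: TabletLayout,
                   rng: np.random.Generator) -> RepetitionPlan:
    """Relocate the post-trigger portion of a scramble trail.

    All displayed items after the trigger correct selection are re-assigned to
    tablets such that at least one correct item moves, consecutive correct
    selections stay on distinct tablets, the alphanumeric character order is
    untouched, and the total correct-path distance remains inside the target
    window.  Draws are repeated until both constraints hold (bounded).
    """
    if plan.condition != "scramble":
        raise ValueError("apply_scramble requires a scramble-condition plan")
    trigger = plan.scramble_trigger
    if trigger is None or not (0 <= trigger < plan.n_selections - 1):
        raise ValueError(f"scramble_trigger {trigger!r} outside correct-selection range")

    correct = plan.correct_items
    trigger_order_index = correct[trigger].order_index
    head = [it for it in plan.items if it.order_index <= trigger_order_index]
    tail = [it for it in plan.items if it.order_index > trigger_order_index]
    ids = layout.tablet_ids
    tol = plan.tolerance_frac * plan.target_distance_m
    head_correct_tablets = [it.tablet_id for it in head if not it.is_distractor]
    old_tail_correct = [it.tablet_id for it in tail if not it.is_distractor]

    best = None
    best_err = math.inf
    for _ in range(_MAX_PROPOSALS):
        new_correct = _draw_assignment(rng, ids, len(old_tail_correct),
                                       prev=head_correct_tablets[-1])
        if new_correct == old_tail_correct:
            continue  # "relocated" requires an actual change
        candidate: list[SequenceItem] = []
        it_correct = iter(new_correct)
        for it in tail:
            if it.is_distractor:
                candidate.append(replace(it, tablet_id=ids[rng.integers(len(ids))]))
            else:
                candidate.append(replace(it, tablet_id=next(it_correct)))
        dist = path_distance(layout, head + candidate)
        err = abs(dist - plan.target_distance_m)
        if err < best_err:
            best_err, best = err, dist
        if err <= tol:
            return replace(plan, items=tuple(head + candidate))
    raise TrailGenerationError(
        f"scramble relocation could not satisfy {plan.target_distance_m} m "
        f"+/- {plan.tolerance_frac:.0%} (best achieved {best:.2f} m)",
        best_distance_m=best,
    )


def build_protocol(config: ProtocolConfig | None = None) -> AssessmentProtocol:
    """Assemble the full assessment plan.

    Core levels get four repetitions (standard first, then a seeded random
    permutation of standard/auditory/scramble); the motor bookends get two
    standard repetitions each.  Deterministic for a given ``rng_seed``.
    """
    config = config or ProtocolConfig()
    rng = np.random.default_rng(config.rng_seed)
    levels: list[tuple[str, tuple[RepetitionPlan, ...]]] = []
    for level_kind in LEVEL_ORDER:
        if level_kind in ("motor_pre", "motor_post"):
            conditions = ["standard", "standard"]
        else:
            tail = ["standard", "auditory", "scramble"]
            rng.shuffle(tail)
            conditions = ["standard"] + tail
        target = (config.reduced_rep_distance_m if level_kind in REDUCED_LEVELS
                  else config.full_rep_distance_m)
        reps: list[RepetitionPlan] = []
        for cond in conditions:
            if config.reuse_sequences and reps:
                # reuse the first repetition's character-to-tablet assignment
                base = reps[0]
                plan = replace(
                    base,
                    condition=cond,
                    scramble_trigger=(_default_scramble_trigger(base.n_selections)
                                      if cond == "scramble" else None),
                )
                if cond == "scramble":
                    plan = apply_scramble(plan, config.layout, rng)
            else:
                plan = generate_trail(
                    config.layout, level_kind, cond, target,
                    tolerance_frac=config.tolerance_frac, rng=rng,
                )
            reps.append(plan)
        levels.append((level_kind, tuple(reps)))
    return AssessmentProtocol(
        layout=config.layout,
        levels=tuple(levels),
        per_selection_distance_m=config.per_selection_distance_m,
        full_rep_distance_m=config.full_rep_distance_m,
        reduced_rep_distance_m=config.reduced_rep_distance_m,
        rng_seed=config.rng_seed,
    )
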