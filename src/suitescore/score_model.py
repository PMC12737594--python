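"""Domain types and validation for circumplex valence-arousal scoring.

A behavioural suitability test for dogs in animal-assisted services is
divided into 24 scored sub-phases (letter codes ``a``-``x``).  Two
independent evaluators watch the recorded test and place each sub-phase
on a Cartesian grid: the x-axis is *valence* (negative = withdrawal,
refusal, aggression; positive = approach, tolerance) and the y-axis is
*arousal* (activation level, independent of valence), each bounded to
[-5, +5].  Scores are recorded on a half-point grid in practice, but any
real value in range is accepted here.

Two behavioural events override the raw coordinate:

* aggression forces the score to (-5, +5);
* refusal to participate forces valence to -5 (arousal is retained as
  observed, since only the valence assignment is fixed by the protocol).

This module provides the score containers, the override rules, and the
aggregation of several raters' sheets into a single consensus sheet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

SCORE_MIN = -5.0
SCORE_MAX = 5.0
GRID_STEP = 0.5

AGGRESSION_SCORE = (-5.0, 5.0)
REFUSAL_VALENCE = -5.0


class ScoreValidationError(ValueError):
    """A valence or arousal value is outside the admissible range."""


class SubPhase(enum.Enum):
    """The 24 scored sub-phases of the test battery.

    Sub-phases ``a``-``f`` expose the dog to environmental stimuli
    (exploration, food, toys, unusual objects, sounds); ``g``-``x`` are
    social stimuli (separation, handling and play with the caregiver and
    with unfamiliar people, groups, and unusual social appearances).
    Two further sub-phases (``y``, ``z``) exist in the protocol but are
    scored on a different grid and are rejected by this schema.
    """

    a = ("a", "room exploration")
    b = ("b", "food motivation")
    c = ("c", "toy motivation")
    d = ("d", "unusual static objects")
    e = ("e", "sounds")
    f = ("f", "unusual moving objects")
    g = ("g", "separation")
    h = ("h", "social attraction (caregiver)")
    i = ("i", "handling (caregiver)")
    j = ("j", "brush (caregiver)")
    k = ("k", "play invitation (caregiver)")
    l = ("l", "social attraction (female stranger)")
    m = ("m", "handling (female stranger)")
    n = ("n", "brush (female stranger)")
    o = ("o", "play invitation (female stranger)")
    p = ("p", "social attraction (male stranger)")
    q = ("q", "handling (male stranger)")
    r = ("r", "brush (male stranger)")
    s = ("s", "play invitation (male stranger)")
    t = ("t", "social attraction (group)")
    u = ("u", "handling (group)")
    v = ("v", "white coat and surgical face mask")
    w = ("w", "crutches and sunglasses")
    x = ("x", "baby doll")

    def __init__(self, code: str, label: str) -> None:
        self.code = code
        self.label = label

    @property
    def phase(self) -> str:
        """``"environmental"`` for a-f, ``"social"`` for g-x."""
        return "environmental" if self.code <= "f" else "social"

    @classmethod
    def from_code(cls, code: str) -> "SubPhase":
        try:
            return cls[code.strip()]
        except KeyError:
            raise ScoreValidationError(
                f"unknown sub-phase code {code!r}: scored sub-phases are "
                f"'a'..'x' (y and z use a separate grid and are not accepted)"
            ) from None


def validate_score(valence: float, arousal: float) -> tuple[float, float]:
    """Check a (valence, arousal) pair against the grid bounds.

    Returns the pair unchanged when both values lie in [-5, +5]; raises
    :class:`ScoreValidationError` naming the offending axis otherwise.
    """
    for axis, value in (("valence", valence), ("arousal", arousal)):
        value = float(value)
        if not (SCORE_MIN <= value <= SCORE_MAX):
            raise ScoreValidationError(
                f"{axis} = {value} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
            )
    return float(valence), float(arousal)


@dataclass(frozen=True)
class SubPhaseScore:
    """One rater's judgment of one sub-phase.

    ``aggression`` and ``refusal`` record behavioural events that carry
    mandatory score overrides (see :func:`apply_overrides`); the stored
    coordinates may predate the override, which is applied explicitly.
    """

    subphase: SubPhase
    valence: float
    arousal: float
    aggression: bool = False
    refusal: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        validate_score(self.valence, self.arousal)


def apply_overrides(score: SubPhaseScore) -> SubPhaseScore:
    """Apply the aggression and refusal score overrides.

    Aggression forces (valence, arousal) = (-5, +5).  Refusal forces
    valence = -5 and leaves arousal as observed.  Flags are preserved,
    so the operation is idempotent.
    """
    if score.aggression:
        return replace(score, valence=AGGRESSION_SCORE[0], arousal=AGGRESSION_SCORE[1])
    if score.refusal:
        return replace(score, valence=REFUSAL_VALENCE)
    return score


@dataclass
class RaterSheet:
    """One evaluator's score sheet for one dyad (dog-caregiver pair)."""

    dyad_id: str
    rater_id: str
    scores: dict[SubPhase, SubPhaseScore] = field(default_factory=dict)

    def add(self, score: SubPhaseScore) -> None:
        if score.subphase in self.scores:
            raise ScoreValidationError(
                f"duplicate score for sub-phase {score.subphase.code!r} "
                f"(dyad {self.dyad_id}, rater {self.rater_id})"
            )
        self.scores[score.subphase] = score

    @property
    def n_scored(self) -> int:
        return len(self.scores)

    def missing(self) -> list[SubPhase]:
        return [sp for sp in SubPhase if sp not in self.scores]


@dataclass
class ConsensusSheet:
    """Per-dyad scores aggregated over raters.

    Completeness is reported, never assumed: sub-phases scored by no
    rater are simply absent, and downstream consumers work with the
    fraction of *scored* sub-phases.
    """

    dyad_id: str
    scores: dict[SubPhase, SubPhaseScore] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_scored(self) -> int:
        return len(self.scores)

    def missing(self) -> list[SubPhase]:
        return [sp for sp in SubPhase if sp not in self.scores]


def aggregate_raters(
    sheets: Iterable[RaterSheet], method: str = "mean"
) -> ConsensusSheet:
    """Combine one dyad's rater sheets into a consensus sheet.

    Per sub-phase, valence and arousal are the arithmetic mean over the
    raters who scored it (the only supported policy); behaviour flags
    are OR'd across raters, and the overrides are re-applied *after*
    averaging so a flagged sub-phase can never average away.  Sub-phases
    scored by no rater are absent from the output.
    """
    sheets = list(sheets)
    if not sheets:
        raise ValueError("aggregate_raters requires at least one sheet")
    if method != "mean":
        raise ValueError(f"unknown aggregation method {method!r}")
    dyads = {s.dyad_id for s in sheets}
    if len(dyads) != 1:
        raise ValueError(f"sheets belong to different dyads: {sorted(dyads)}")

    consensus: dict[SubPhase, SubPhaseScore] = {}
    for sp in SubPhase:
        contributing = [s.scores[sp] for s in sheets if sp in s.scores]
        if not contributing:
            continue
        valence = sum(c.valence for c in contributing) / len(contributing)
        arousal = sum(c.arousal for c in contributing) / len(contributing)
        merged = SubPhaseScore(
            subphase=sp,
            valence=valence,
            arousal=arousal,
            aggression=any(c.aggression for c in contributing),
            refusal=any(c.refusal for c in contributing),
            note="; ".join(c.note for c in contributing if c.note),
        )
        consensus[sp] = apply_overrides(merged)

    return ConsensusSheet(
        dyad_id=sheets[0].dyad_id,
        scores=consensus,
        provenance={
            "method": method,
            "raters": sorted(s.rater_id for s in sheets),
        },
    )


def snap_to_grid(value: float, step: float = GRID_STEP) -> float:
    """Round a score to the nearest grid step (half points by default)."""
    return round(value / step) * step
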