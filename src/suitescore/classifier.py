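"""Triangular-region suitability classifier (suitable / pending / unsuitable).

A dog suitable for animal-assisted services shows positive valence with
an arousal band that widens as valence grows: the admissible pattern is
the closed triangle with vertices (0, 0), (+5, +3) and (+5, -3) in the
valence-arousal plane.  A dog is expected to place the majority of its
sub-phase scores inside this region, with particular weight on the most
diagnostic ("critical") sub-phases — unusual objects, sounds, handling
by strangers and groups.

The decision rule is a fixed priority cascade:

1. any aggression event -> U;
2. valence = -5 (refusal-grade) in a critical sub-phase -> U;
3. food exemption: every scored sub-phase inside the region except
   possibly food motivation (``b``), with positive median valence -> S;
4. majority of scores inside, no high-arousal episode, no critical
   sub-phase with negative valence -> S;
5. majority inside but high-arousal episodes (arousal above the
   region's +3 cap at positive valence, e.g. jumping on a stranger) or
   a critical sub-phase with negative valence -> P;
6. majority outside with negative median valence -> U;
7. majority outside with non-negative median valence -> borderline
   policy (default U, configurable to P).

Every classification carries a machine-readable rationale: the rule
that fired, the inside fraction, medians, and per-sub-phase membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .score_model import ConsensusSheet, SubPhase

#: Default critical sub-phases: unusual static objects, sounds, unusual
#: moving objects, and handling by the female stranger, male stranger
#: and the group.
DEFAULT_CRITICAL = frozenset(
    {SubPhase.d, SubPhase.e, SubPhase.f, SubPhase.m, SubPhase.q, SubPhase.u}
)


@dataclass(frozen=True)
class SuitabilityRegion:
    """The closed triangle {(x, y): 0 <= x <= 5, |y| <= 0.6 x}."""

    vertex_origin: tuple[float, float] = (0.0, 0.0)
    vertex_high: tuple[float, float] = (5.0, 3.0)
    vertex_low: tuple[float, float] = (5.0, -3.0)

    def contains(self, valence: float, arousal: float) -> bool:
        # 5*|a| <= 3*v is exact in binary floating point for half-grid
        # scores, unlike |a| <= 0.6*v.
        return 0.0 <= valence <= 5.0 and 5.0 * abs(arousal) <= 3.0 * valence


REGION = SuitabilityRegion()


def in_region(
    valence: float, arousal: float, region: SuitabilityRegion = REGION
) -> bool:
    """True iff the score lies in the closed suitability triangle."""
    return region.contains(valence, arousal)


@dataclass(frozen=True)
class ClassificationConfig:
    """Tunable parameters of the decision cascade.

    ``majority_threshold`` is the inside fraction that must be strictly
    exceeded ("majority" = more than half of the *scored* sub-phases).
    A high-arousal episode is a score with arousal strictly above
    ``high_arousal_cutoff`` (the region's arousal cap) at positive
    valence; ``high_arousal_k`` episodes demote S to P.  The borderline
    branch (majority outside, non-negative median valence) resolves to
    ``borderline_policy``.
    """

    region: SuitabilityRegion = REGION
    majority_threshold: float = 0.5
    high_arousal_cutoff: float = 3.0
    high_arousal_k: int = 1
    food_exempt: SubPhase = SubPhase.b
    critical: frozenset[SubPhase] = DEFAULT_CRITICAL
    critical_u_valence: float = -5.0
    borderline_policy: str = "U"  # or "P"
    aggression_to_u: bool = True

    def __post_init__(self) -> None:
        if self.high_arousal_k < 1:
            raise ValueError("high_arousal_k must be >= 1")
        if self.borderline_policy not in ("U", "P"):
            raise ValueError("borderline_policy must be 'U' or 'P'")
        if not (0.0 <= self.majority_threshold < 1.0):
            raise ValueError("majority_threshold must be in [0, 1)")


@dataclass
class ClassificationResult:
    dyad_id: str
    suitability: str  # "S" | "P" | "U"
    inside_fraction: float
    median_valence: float
    median_arousal: float
    triggered_rules: list[str]
    membership: dict[SubPhase, bool] = field(default_factory=dict)


def classify(
    sheet: ConsensusSheet, config: ClassificationConfig = ClassificationConfig()
) -> ClassificationResult:
    """Apply the S/P/U decision cascade to a consensus sheet.

    Deterministic and total over non-empty sheets; the first matching
    rule in the priority order decides, and its identifier (plus any
    informational antecedents) is recorded in ``triggered_rules``.
    """
    if not sheet.scores:
        raise ValueError(f"dyad {sheet.dyad_id}: cannot classify an empty sheet")

    scores = [sheet.scores[sp] for sp in SubPhase if sp in sheet.scores]
    membership = {
        s.subphase: in_region(s.valence, s.arousal, config.region) for s in scores
    }
    n = len(scores)
    inside_fraction = sum(membership.values()) / n
    median_valence = float(np.median([s.valence for s in scores]))
    median_arousal = float(np.median([s.arousal for s in scores]))

    episodes = [
        s.subphase
        for s in scores
        if s.valence > 0 and s.arousal > config.high_arousal_cutoff
    ]
    critical_negative = [
        s.subphase
        for s in scores
        if s.subphase in config.critical and s.valence < 0
    ]
    critical_floor = [
        s.subphase
        for s in scores
        if s.subphase in config.critical and s.valence <= config.critical_u_valence
    ]
    aggression = [s.subphase for s in scores if s.aggression]

    rules: list[str] = []

    def result(cls: str) -> ClassificationResult:
        return ClassificationResult(
            dyad_id=sheet.dyad_id,
            suitability=cls,
            inside_fraction=inside_fraction,
            median_valence=median_valence,
            median_arousal=median_arousal,
            triggered_rules=rules,
            membership=membership,
        )

    if config.aggression_to_u and aggression:
        rules.append(
            "R1:aggression in " + ",".join(sp.code for sp in aggression)
        )
        return result("U")

    if critical_floor:
        rules.append(
            "R2:valence at floor in critical sub-phase "
            + ",".join(sp.code for sp in critical_floor)
        )
        return result("U")

    outside = [sp for sp, ok in membership.items() if not ok]
    if outside and set(outside) <= {config.food_exempt} and median_valence > 0:
        rules.append(
            "R3:food exemption — all scored sub-phases inside except "
            f"{config.food_exempt.code}, median valence {median_valence:g} > 0"
        )
        return result("S")

    majority_inside = inside_fraction > config.majority_threshold
    if majority_inside:
        if len(episodes) >= config.high_arousal_k or critical_negative:
            if len(episodes) >= config.high_arousal_k:
                rules.append(
                    f"R5:{len(episodes)} high-arousal episode(s) in "
                    + ",".join(sp.code for sp in episodes)
                )
            if critical_negative:
                rules.append(
                    "R5:negative valence in critical sub-phase "
                    + ",".join(sp.code for sp in critical_negative)
                )
            return result("P")
        rules.append(
            f"R4:inside fraction {inside_fraction:.3f} > "
            f"{config.majority_threshold:g}, no high-arousal episode, "
            "no negative critical sub-phase"
        )
        return result("S")

    if median_valence < 0:
        rules.append(
            f"R6:inside fraction {inside_fraction:.3f} <= "
            f"{config.majority_threshold:g} and median valence "
            f"{median_valence:g} < 0"
        )
        return result("U")

    rules.append(
        f"R7:inside fraction {inside_fraction:.3f} <= "
        f"{config.majority_threshold:g} with non-negative median valence; "
        f"borderline policy -> {config.borderline_policy}"
    )
    return result(config.borderline_policy)


@dataclass
class SheetSummary:
    """Per-dyad descriptive statistics of a consensus sheet."""

    dyad_id: str
    n: int
    mean_valence: float
    median_valence: float
    q1_valence: float
    q3_valence: float
    min_valence: float
    max_valence: float
    mean_arousal: float
    median_arousal: float
    q1_arousal: float
    q3_arousal: float
    min_arousal: float
    max_arousal: float


def summarize(sheet: ConsensusSheet) -> SheetSummary:
    """Mean/median/quartiles (linear interpolation) per dimension."""
    if not sheet.scores:
        raise ValueError(f"dyad {sheet.dyad_id}: cannot summarize an empty sheet")
    v = np.array([s.valence for s in sheet.scores.values()])
    a = np.array([s.arousal for s in sheet.scores.values()])

    def stats(x: np.ndarray) -> tuple[float, ...]:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return (
            float(np.mean(x)), float(med), float(q1), float(q3),
            float(np.min(x)), float(np.max(x)),
        )

    return SheetSummary(sheet.dyad_id, len(v), *stats(v), *stats(a))
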