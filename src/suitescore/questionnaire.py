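"""Caregiver questionnaire scoring and open-ended verdict mapping.

The questionnaire has seven sections adapted from the Canine Behavioral
Assessment and Research Questionnaire (C-BARQ) plus purpose-built items;
each section records either the *frequency* or the *intensity* of a
behaviour on a bounded ordinal scale (0-4 by default).  A final
open-ended question asks whether the caregiver believes the dog would be
suitable for animal-assisted interventions; after manual simplification
the answer falls into one of four categories which map onto the
three-level suitability outcome:

====================================  =====
category                              class
====================================  =====
Yes                                   S
Yes after a training programme        P
Maybe                                 P
No                                    U
====================================  =====
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: (section key, score type) in questionnaire order.
SECTIONS: tuple[tuple[str, str], ...] = (
    ("trainability_obedience", "frequency"),
    ("separation", "frequency"),
    ("aggression", "intensity"),
    ("fear_anxiety", "intensity"),
    ("excitability", "intensity"),
    ("attachment", "frequency"),
    ("other", "frequency"),
)

SECTION_KEYS = tuple(name for name, _ in SECTIONS)

CATEGORIES = ("Yes", "Yes after a training programme", "Maybe", "No")

_CATEGORY_TO_CLASS = {
    "yes": "S",
    "no": "U",
    "maybe": "P",
    "yes after a training programme": "P",
    "yes after a training program": "P",
    "yes after training": "P",
}


class UnknownCategoryError(ValueError):
    """The open-ended verdict is not one of the four accepted labels."""


@dataclass
class QuestionnaireResponse:
    """One dyad's questionnaire: per-section item scores plus verdict."""

    dyad_id: str
    items: dict[str, list[float]] = field(default_factory=dict)
    open_ended: str | None = None

    def section_score(self, section: str, aggregation: str = "mean") -> float:
        return score_section(self.items[section], aggregation)


def score_section(items: Sequence[float], aggregation: str = "mean") -> float:
    """Aggregate one section's answered items into a section score.

    Missing items (``None`` or NaN) are excluded from the denominator.
    The default policy is the arithmetic mean; ``"sum"`` is available
    because intensity sections summed over many items produce scores an
    order of magnitude above the per-item scale, and published section
    scores are not always on the same footing.
    """
    answered = [
        float(x) for x in items if x is not None and not math.isnan(float(x))
    ]
    if not answered:
        raise ValueError("section has no answered items")
    if aggregation == "mean":
        return sum(answered) / len(answered)
    if aggregation == "sum":
        return sum(answered)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def map_open_ended(category: str) -> str:
    """Map a simplified open-ended verdict to an expected class S/P/U.

    Raises :class:`UnknownCategoryError` for anything outside the four
    controlled labels (both UK and US spellings of "programme" are
    accepted, as is the short form "Yes after training").
    """
    key = " ".join(str(category).strip().lower().split())
    try:
        return _CATEGORY_TO_CLASS[key]
    except KeyError:
        raise UnknownCategoryError(
            f"unknown open-ended category {category!r}; accepted: "
            + ", ".join(CATEGORIES)
        ) from None
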