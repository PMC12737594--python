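"""Published summary data of the original validation cohort (N = 38 dyads).

The raw score sheets of the validation study are not public, but its
printed summary tables are, and several analyses can be recomputed from
them exactly: the caregiver-verdict vs test-outcome agreement (38
category/class pairs), the Kruskal-Wallis H statistics per questionnaire
section, the Dunn post-hoc z statistics for valence, and the merged
two-group Mann-Whitney U for median valence.  These constants exist so
that the agreement and effect-size machinery can be exercised against
known published output; they are inputs, not expectations baked into the
library code.
"""

from __future__ import annotations

#: Caregiver's simplified open-ended category and the class assigned by
#: the behavioural test, one tuple per dyad, in published order.
AGREEMENT_PAIRS: tuple[tuple[str, str], ...] = (
    ("Yes", "U"),
    ("No", "U"),
    ("Yes", "S"),
    ("No", "U"),
    ("No", "U"),
    ("Yes", "U"),
    ("No", "U"),
    ("Yes", "U"),
    ("No", "U"),
    ("Maybe", "U"),
    ("No", "U"),
    ("No", "P"),
    ("Yes after a training programme", "U"),
    ("No", "U"),
    ("Yes after a training programme", "P"),
    ("Maybe", "U"),
    ("Yes", "S"),
    ("Yes", "S"),
    ("No", "U"),
    ("Yes", "U"),
    ("Yes", "S"),
    ("Yes", "S"),
    ("Yes", "U"),
    ("Yes", "S"),
    ("Yes", "U"),
    ("Yes", "U"),
    ("Yes", "U"),
    ("Yes", "S"),
    ("Yes", "S"),
    ("Yes", "U"),
    ("No", "U"),
    ("Maybe", "U"),
    ("No", "U"),
    ("Yes", "P"),
    ("Yes", "U"),
    ("Yes", "S"),
    ("Yes", "P"),
    ("Yes", "P"),
)

#: Kruskal-Wallis H per questionnaire section (k = 3 groups, n = 38).
QUESTIONNAIRE_KW_H: dict[str, float] = {
    "trainability_obedience": 1.35,
    "separation": 8.06,
    "aggression": 5.03,
    "fear_anxiety": 6.34,
    "excitability": 1.13,
    "attachment": 5.41,
    "other": 3.41,
}

KW_K = 3
KW_N = 38

#: Dunn post-hoc raw two-sided p-values for median valence across the
#: three classes (S vs U, S vs P, P vs U).  The first value follows from
#: the published z = -4.11; the middle one is the unrounded raw p
#: implied by the published Holm-adjusted 0.0273 at m = 3.
DUNN_VALENCE_RAW_P: tuple[float, ...] = (3.95e-05, 0.481, 0.01365)

#: Merged two-group (S+P vs U) Mann-Whitney for median valence.
MW_VALENCE_U = 25.5
MW_VALENCE_N1 = 14  # suitable + pending
MW_VALENCE_N2 = 24  # unsuitable


def published_agreement_pairs() -> tuple[list[str], list[str]]:
    """The 38 (caregiver category, test class) pairs as aligned lists."""
    categories = [c for c, _ in AGREEMENT_PAIRS]
    test_classes = [t for _, t in AGREEMENT_PAIRS]
    return categories, test_classes
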