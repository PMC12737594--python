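from fractions import Fraction

import pytest

from suitescore.score_model import (
    ConsensusSheet,
    RaterSheet,
    SubPhase,
    SubPhaseScore,
)
from suitescore.synthetic import GeneratorConfig, generate_cohort


def make_sheet(scores, dyad_id="d1"):
    """ConsensusSheet from {code: (valence, arousal)} or (v, a, flags) tuples."""
    sheet = ConsensusSheet(dyad_id=dyad_id)
    for code, value in scores.items():
        v, a, *rest = value
        flags = rest[0] if rest else {}
        sheet.scores[SubPhase[code]] = SubPhaseScore(
            subphase=SubPhase[code], valence=v, arousal=a, **flags
        )
    return sheet


def uniform_sheet(valence, arousal, dyad_id="d1", codes=None):
    codes = codes or [sp.name for sp in SubPhase]
    return make_sheet({c: (valence, arousal) for c in codes}, dyad_id=dyad_id)


def barycentric_oracle(v, a):
    """Independent point-in-triangle check via exact barycentric coordinates."""
    (x1, y1), (x2, y2), (x3, y3) = (0, 0), (5, 3), (5, -3)
    v, a = Fraction(v).limit_denominator(2), Fraction(a).limit_denominator(2)
    det = Fraction((y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3))
    l1 = ((y2 - y3) * (v - x3) + (x3 - x2) * (a - y3)) / det
    l2 = ((y3 - y1) * (v - x3) + (x1 - x3) * (a - y3)) / det
    l3 = 1 - l1 - l2
    return l1 >= 0 and l2 >= 0 and l3 >= 0


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort with its latent truth."""
    cohort, truth = generate_cohort(GeneratorConfig(), seed=20240)
    return cohort, truth


@pytest.fixture()
def rater_pair():
    a = RaterSheet(dyad_id="d1", rater_id="r1")
    b = RaterSheet(dyad_id="d1", rater_id="r2")
    return a, b
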