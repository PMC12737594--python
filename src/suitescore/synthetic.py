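"""Seeded synthetic-cohort generator emulating the study's data structure.

Every pipeline stage is testable without any download: the generator
draws a latent suitability class per dyad (S : P : U defaulting to the
9 : 5 : 24 proportions of a 38-dyad cohort), then produces everything an
assessment session would — two raters' half-grid valence/arousal sheets
for 24 sub-phases, questionnaire section scores, a pre/post salivary
cortisol pair with no class effect on the delta, and a caregiver verdict
whose miscalibration mirrors the published caregiver-vs-test
contingency structure (caregivers of unsuitable dogs frequently answer
"Yes").

Per-class score distributions are truncated normals snapped to the
0.5-point grid, moment-matched to the published per-class means and
spreads.  Sub-phase effects are homogeneous within class by default; an
equicorrelation knob adds a shared per-dog component.  Latent labels
are returned separately from the observable data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .group_stats import CortisolPair
from .questionnaire import QuestionnaireResponse, SECTION_KEYS
from .score_model import (
    RaterSheet,
    SubPhase,
    SubPhaseScore,
    aggregate_raters,
    apply_overrides,
    ConsensusSheet,
    snap_to_grid,
)

CLASSES = ("S", "P", "U")


@dataclass(frozen=True)
class ClassScoreParams:
    """Per-class (valence, arousal) moments and behaviour-event rates."""

    valence_mean: float
    valence_sd: float
    arousal_mean: float
    arousal_sd: float
    aggression_p: float = 0.0  # per sub-phase
    refusal_p: float = 0.0  # per sub-phase


@dataclass(frozen=True)
class SectionParams:
    """Questionnaire section moments; S and P share the merged moments."""

    mean_sp: float
    sd_sp: float
    mean_u: float
    sd_u: float
    lo: float = 0.0
    hi: float | None = None

    def moments(self, cls: str) -> tuple[float, float]:
        return (self.mean_u, self.sd_u) if cls == "U" else (self.mean_sp, self.sd_sp)


def _default_score_params() -> dict[str, ClassScoreParams]:
    return {
        "S": ClassScoreParams(2.5, 1.0, 1.0, 1.3),
        "P": ClassScoreParams(2.1, 1.2, 1.2, 1.7),
        "U": ClassScoreParams(0.4, 2.2, 1.5, 1.8, aggression_p=0.01, refusal_p=0.02),
    }


def _default_sections() -> dict[str, SectionParams]:
    # Sections with a published class effect carry the merged-group
    # moments; the remaining sections are class-independent at
    # plausible ordinal-scale levels.
    return {
        "trainability_obedience": SectionParams(2.9, 0.7, 2.9, 0.7, hi=4.0),
        "separation": SectionParams(0.205, 0.223, 0.677, 0.613, hi=4.0),
        "aggression": SectionParams(8.857, 6.815, 16.750, 11.674),
        "fear_anxiety": SectionParams(0.493, 0.379, 0.903, 0.520, hi=4.0),
        "excitability": SectionParams(1.9, 0.9, 1.9, 0.9, hi=4.0),
        "attachment": SectionParams(1.857, 0.727, 2.424, 0.815, hi=4.0),
        "other": SectionParams(0.8, 0.6, 0.8, 0.6, hi=4.0),
    }


def _default_verdict_matrix() -> dict[str, tuple[float, float, float]]:
    # P(caregiver class S/P/U | latent class), column-normalized from
    # the published caregiver-vs-test contingency structure.
    return {
        "S": (1.0, 0.0, 0.0),
        "P": (3 / 5, 1 / 5, 1 / 5),
        "U": (10 / 24, 4 / 24, 10 / 24),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator, with study-scale defaults."""

    n_dyads: int = 38
    class_probs: tuple[float, float, float] = (9 / 38, 5 / 38, 24 / 38)
    score_params: dict[str, ClassScoreParams] = field(
        default_factory=_default_score_params
    )
    #: SD of each rater's independent error around the latent score;
    #: with the default class mix this puts the pooled two-rater ICC
    #: near 0.65.
    rater_error_sd: float = 1.5
    n_raters: int = 2
    #: Share of within-class score variance attributable to a per-dog
    #: random effect (0 = scores independent given class).
    equicorrelation: float = 0.0
    sections: dict[str, SectionParams] = field(default_factory=_default_sections)
    #: Four caregiver verdict categories; a caregiver-class P becomes
    #: "Maybe" with this probability, else "Yes after a training
    #: programme" (3 : 2 in the published cohort).
    verdict_matrix: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_verdict_matrix
    )
    maybe_p: float = 0.6
    #: Cortisol: log-normal marginal matched to the published overall
    #: moments (mean 1.580, SD 1.396 ng/mL), split into a per-dog level
    #: and independent per-time residuals so the delta is centred at 0
    #: with no class effect.
    cortisol_log_mean: float = 0.1690
    cortisol_log_sd_dog: float = 0.6356
    cortisol_log_sd_time: float = 0.4161
    cortisol_missing_p: float = 3 / 38
    missing_score_p: float = 1 / 912

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        """Load a generator configuration from a YAML key/value file.

        Top-level keys mirror the field names; ``score_params`` and
        ``sections`` entries update the defaults field-by-field, so a
        config file only needs to state what it changes.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        if "class_probs" in kwargs:
            kwargs["class_probs"] = tuple(kwargs["class_probs"])
        if "score_params" in kwargs:
            base = _default_score_params()
            kwargs["score_params"] = {
                k: dataclasses.replace(base[k], **v)
                for k, v in kwargs["score_params"].items()
            } | {k: v for k, v in base.items() if k not in kwargs["score_params"]}
        if "sections" in kwargs:
            base = _default_sections()
            kwargs["sections"] = {
                k: dataclasses.replace(base[k], **v)
                for k, v in kwargs["sections"].items()
            } | {k: v for k, v in base.items() if k not in kwargs["sections"]}
        if "verdict_matrix" in kwargs:
            kwargs["verdict_matrix"] = {
                k: tuple(v) for k, v in kwargs["verdict_matrix"].items()
            }
        return cls(**kwargs)

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if min(self.class_probs) < 0:
            raise ValueError("class probabilities must be non-negative")
        if not (0.0 <= self.equicorrelation < 1.0):
            raise ValueError("equicorrelation must be in [0, 1)")
        for mat in self.verdict_matrix.values():
            if abs(sum(mat) - 1.0) > 1e-9 or min(mat) < 0:
                raise ValueError("verdict matrix rows must be distributions")


@dataclass
class DyadAssessment:
    """One dog-caregiver unit's complete observable record."""

    dyad_id: str
    rater_sheets: list[RaterSheet]
    consensus: ConsensusSheet
    questionnaire: QuestionnaireResponse
    cortisol: CortisolPair


@dataclass
class Cohort:
    dyads: list[DyadAssessment]

    def __len__(self) -> int:
        return len(self.dyads)


def _draw_score(rng: np.random.Generator, mean: float, sd: float) -> float:
    return snap_to_grid(float(np.clip(rng.normal(mean, sd), -5.0, 5.0)))


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[Cohort, dict[str, str]]:
    """Draw a complete synthetic cohort.

    Returns the observable cohort and, separately, the latent class per
    dyad (the ground truth for recovery tests).  Identical seed and
    config give identical output.
    """
    rng = np.random.default_rng(seed)
    params = config.score_params
    rho = config.equicorrelation

    dyads: list[DyadAssessment] = []
    truth: dict[str, str] = {}

    latent = rng.choice(len(CLASSES), size=config.n_dyads, p=config.class_probs)
    for i, cls_idx in enumerate(latent):
        dyad_id = f"dyad{i + 1:03d}"
        cls = CLASSES[cls_idx]
        truth[dyad_id] = cls
        p = params[cls]

        dog_v = rng.normal(0.0, 1.0)
        dog_a = rng.normal(0.0, 1.0)
        sheets = [
            RaterSheet(dyad_id=dyad_id, rater_id=f"rater{r + 1}")
            for r in range(config.n_raters)
        ]
        for sp in SubPhase:
            if rng.random() < config.missing_score_p:
                continue
            true_v = p.valence_mean + p.valence_sd * (
                math.sqrt(rho) * dog_v + math.sqrt(1 - rho) * rng.normal()
            )
            true_a = p.arousal_mean + p.arousal_sd * (
                math.sqrt(rho) * dog_a + math.sqrt(1 - rho) * rng.normal()
            )
            aggression = rng.random() < p.aggression_p
            refusal = (not aggression) and rng.random() < p.refusal_p
            for sheet in sheets:
                score = SubPhaseScore(
                    subphase=sp,
                    valence=_draw_score(
                        rng, true_v, config.rater_error_sd
                    ),
                    arousal=_draw_score(
                        rng, true_a, config.rater_error_sd
                    ),
                    aggression=aggression,
                    refusal=refusal,
                )
                sheet.add(apply_overrides(score))
        consensus = aggregate_raters(sheets)

        items = {}
        for section in SECTION_KEYS:
            sp_params = config.sections[section]
            mean, sd = sp_params.moments(cls)
            value = float(rng.normal(mean, sd))
            value = max(sp_params.lo, value)
            if sp_params.hi is not None:
                value = min(sp_params.hi, value)
            items[section] = [value]

        caregiver_cls = CLASSES[
            rng.choice(3, p=np.asarray(config.verdict_matrix[cls]))
        ]
        if caregiver_cls == "S":
            category = "Yes"
        elif caregiver_cls == "U":
            category = "No"
        else:
            category = (
                "Maybe"
                if rng.random() < config.maybe_p
                else "Yes after a training programme"
            )
        questionnaire = QuestionnaireResponse(
            dyad_id=dyad_id, items=items, open_ended=category
        )

        if rng.random() < config.cortisol_missing_p:
            t0 = t1 = float("nan")
        else:
            dog_level = rng.normal(0.0, config.cortisol_log_sd_dog)
            t0 = math.exp(
                config.cortisol_log_mean
                + dog_level
                + rng.normal(0.0, config.cortisol_log_sd_time)
            )
            t1 = math.exp(
                config.cortisol_log_mean
                + dog_level
                + rng.normal(0.0, config.cortisol_log_sd_time)
            )
        cortisol = CortisolPair(dyad_id=dyad_id, t0=t0, t1=t1)

        dyads.append(
            DyadAssessment(
                dyad_id=dyad_id,
                rater_sheets=sheets,
                consensus=consensus,
                questionnaire=questionnaire,
                cortisol=cortisol,
            )
        )

    return Cohort(dyads=dyads), truth


def expected_icc(config: GeneratorConfig, dimension: str = "valence") -> float:
    """Analytic variance-ratio implied by the generator configuration.

    The single-rater consistency ICC estimates
    ``sigma_b^2 / (sigma_b^2 + sigma_e^2)`` where the between-item
    variance ``sigma_b^2`` pools the within-class score variance and the
    between-class mean spread (mixture variance), and ``sigma_e^2`` is
    the rater-error variance.  Clipping and grid-snapping perturb this
    slightly; the ratio is an oracle for recovery tests, not an exact
    expectation.
    """
    probs = dict(zip(CLASSES, config.class_probs))
    means, variances = [], []
    for cls, p in probs.items():
        sp = config.score_params[cls]
        mean = getattr(sp, f"{dimension}_mean")
        sd = getattr(sp, f"{dimension}_sd")
        means.append((p, mean))
        variances.append((p, sd**2))
    grand_mean = sum(p * m for p, m in means)
    sigma_b2 = sum(p * v for p, v in variances) + sum(
        p * (m - grand_mean) ** 2 for p, m in means
    )
    sigma_e2 = config.rater_error_sd**2
    return sigma_b2 / (sigma_b2 + sigma_e2)


def rater_score_matrix(cohort: Cohort, dimension: str = "valence") -> np.ndarray:
    """Pooled (dyad, sub-phase) x rater matrix for ICC computation."""
    if dimension not in ("valence", "arousal"):
        raise ValueError("dimension must be 'valence' or 'arousal'")
    rows = []
    for dyad in cohort.dyads:
        for sp in SubPhase:
            row = [
                getattr(sheet.scores[sp], dimension)
                for sheet in dyad.rater_sheets
                if sp in sheet.scores
            ]
            if len(row) == len(dyad.rater_sheets):
                rows.append(row)
    return np.asarray(rows, dtype=float)


def cohort_to_files(
    cohort: Cohort,
    truth: dict[str, str],
    outdir,
    config: GeneratorConfig | None = None,
) -> dict[str, str]:
    """Write a cohort to plain-text files (CSV + truth JSON).

    Returns a mapping of logical name -> path.  Files round-trip
    losslessly through :mod:`suitescore.fileio`.
    """
    from . import fileio  # local import to keep fileio -> synthetic one-way

    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": str(outdir / "scores.csv"),
        "questionnaire": str(outdir / "questionnaire.csv"),
        "cortisol": str(outdir / "cortisol.csv"),
        "truth": str(outdir / "truth.json"),
    }
    sheets = [sheet for dyad in cohort.dyads for sheet in dyad.rater_sheets]
    fileio.write_scores(sheets, paths["scores"])
    fileio.write_questionnaires(
        [d.questionnaire for d in cohort.dyads], paths["questionnaire"]
    )
    fileio.write_cortisol([d.cortisol for d in cohort.dyads], paths["cortisol"])
    truth_doc = {"latent_classes": truth}
    if config is not None:
        truth_doc["generator_config"] = _config_to_jsonable(config)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
    return paths


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    return asdict(config)  # asdict recurses into nested dataclasses
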