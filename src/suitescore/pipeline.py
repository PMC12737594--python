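"""End-to-end analysis pipeline: files in, structured report out.

Stage order follows the analysis plan of the validation study design:
descriptives, inter-rater reliability, classification, caregiver
agreement, group statistics on test scores and questionnaire sections,
and the cortisol battery.  Every number in the report is produced by a
stage operation — the presentation layer never recomputes anything.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio
from .agreement import build_contingency, cohens_kappa, icc_two_rater
from .classifier import ClassificationConfig, classify, in_region, summarize
from .group_stats import (
    delta_cortisol,
    dunn_holm,
    kruskal_wallis,
    mann_whitney,
    shapiro_gate,
    wilcoxon_paired,
)
from .questionnaire import SECTION_KEYS, map_open_ended
from .score_model import SubPhase, aggregate_raters

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    scores_path: str
    questionnaire_path: str | None = None
    cortisol_path: str | None = None
    override_classes_path: str | None = None
    outdir: str = "suitescore_out"
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    section_aggregation: str = "mean"
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML key/value file.

        The optional ``classification`` block maps onto
        :class:`ClassificationConfig`; ``critical`` and ``food_exempt``
        are given as sub-phase letter codes.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        block = kwargs.pop("classification", None)
        if block:
            if "critical" in block:
                block["critical"] = frozenset(
                    SubPhase.from_code(c) for c in block["critical"]
                )
            if "food_exempt" in block:
                block["food_exempt"] = SubPhase.from_code(block["food_exempt"])
            kwargs["classification"] = ClassificationConfig(**block)
        return cls(**kwargs)


def _result_row(r) -> dict:
    return {
        "test": r.test,
        "comparison": r.comparison,
        "statistic_name": r.statistic_name,
        "statistic": r.statistic,
        "df": r.df,
        "p": r.p,
        "p_adjusted": r.p_adjusted,
        "effect_size_name": r.effect_size_name,
        "effect_size": r.effect_size,
        "magnitude": r.magnitude,
        "significance": r.significance_code,
    }


def _grouped(values: dict[str, float], classes: dict[str, str]) -> dict[str, list]:
    groups: dict[str, list] = {}
    for dyad, value in values.items():
        if dyad in classes:
            groups.setdefault(classes[dyad], []).append(value)
    return groups


def _merged(groups: dict[str, list]) -> tuple[list, list]:
    sp = groups.get("S", []) + groups.get("P", [])
    return sp, groups.get("U", [])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report; returns the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    stats_rows: list[dict] = []

    def stage(name: str) -> None:
        logger.info("stage: %s", name)
        report["stages"].append(name)

    # ---- scores and consensus -------------------------------------------
    stage("read_scores")
    sheets = fileio.read_scores(config.scores_path)
    by_dyad: dict[str, list] = {}
    for sheet in sheets:
        by_dyad.setdefault(sheet.dyad_id, []).append(sheet)
    consensus = {d: aggregate_raters(s) for d, s in sorted(by_dyad.items())}
    report["n_dyads"] = len(consensus)
    report["n_rater_sheets"] = len(sheets)

    stage("descriptives")
    summaries = {d: summarize(c) for d, c in consensus.items()}
    report["per_dyad_summary"] = {
        d: dataclasses.asdict(s) for d, s in summaries.items()
    }

    # ---- inter-rater reliability ----------------------------------------
    stage("icc")
    report["icc"] = {}
    for dimension in ("valence", "arousal"):
        rows = []
        for dyad_sheets in by_dyad.values():
            if len(dyad_sheets) < 2:
                continue
            for sp in SubPhase:
                row = [
                    getattr(s.scores[sp], dimension)
                    for s in dyad_sheets
                    if sp in s.scores
                ]
                if len(row) == len(dyad_sheets):
                    rows.append(row)
        if len(rows) >= 5:
            icc = icc_two_rater(np.asarray(rows))
            report["icc"][dimension] = dataclasses.asdict(icc)
        else:
            report["icc"][dimension] = None
            logger.info("icc skipped for %s: fewer than 2 raters", dimension)

    # ---- classification --------------------------------------------------
    stage("classification")
    if config.override_classes_path:
        classes = fileio.read_class_overrides(config.override_classes_path)
        report["classification_source"] = "override file"
        report["classifications"] = {d: {"suitability": c} for d, c in classes.items()}
    else:
        results = {d: classify(c, config.classification) for d, c in consensus.items()}
        classes = {d: r.suitability for d, r in results.items()}
        report["classification_source"] = "classifier"
        report["classifications"] = {
            d: {
                "suitability": r.suitability,
                "inside_fraction": r.inside_fraction,
                "median_valence": r.median_valence,
                "median_arousal": r.median_arousal,
                "triggered_rules": r.triggered_rules,
            }
            for d, r in results.items()
        }
    counts = {c: sum(1 for v in classes.values() if v == c) for c in ("S", "P", "U")}
    report["class_counts"] = counts

    # plot data: one row per (dyad, sub-phase) with region membership
    plot_rows = [
        {
            "dyad_id": d,
            "subphase": sp.code,
            "valence": s.valence,
            "arousal": s.arousal,
            "inside": int(in_region(s.valence, s.arousal, config.classification.region)),
        }
        for d, c in consensus.items()
        for sp, s in c.scores.items()
    ]
    pd.DataFrame(plot_rows).to_csv(outdir / "plot_data.csv", index=False)

    # ---- caregiver agreement --------------------------------------------
    questionnaires = (
        fileio.read_questionnaires(config.questionnaire_path)
        if config.questionnaire_path
        else []
    )
    if questionnaires and all(q.open_ended for q in questionnaires):
        stage("agreement")
        aligned = [q for q in questionnaires if q.dyad_id in classes]
        expected = [map_open_ended(q.open_ended) for q in aligned]
        observed = [classes[q.dyad_id] for q in aligned]
        table = build_contingency(expected, observed)
        agreement = cohens_kappa(table)
        report["agreement"] = {
            "contingency": table.counts.tolist(),
            "n": table.n,
            "kappa": round(agreement.kappa, 3),
            "p_observed": agreement.p_observed,
            "p_expected": agreement.p_expected,
            "label": agreement.label,
            "row_concordance_pct": {
                k: (None if v is None else round(v, 1))
                for k, v in agreement.row_concordance_pct.items()
            },
            "overall_concordance_pct": round(agreement.overall_concordance_pct, 1),
        }
        fileio.write_contingency(table, outdir / "contingency.csv")

    # ---- group statistics on test scores --------------------------------
    stage("score_group_stats")
    for dimension in ("valence", "arousal"):
        medians = {
            d: getattr(s, f"median_{dimension}") for d, s in summaries.items()
        }
        groups = _grouped(medians, classes)
        nonempty = {g: v for g, v in groups.items() if v}
        if len(nonempty) >= 2:
            kw = kruskal_wallis(nonempty, comparison=f"median {dimension}: S vs P vs U")
            stats_rows.append(_result_row(kw))
            if len(nonempty) >= 3:
                try:
                    for r in dunn_holm(nonempty):
                        r.comparison = f"median {dimension}: {r.comparison}"
                        stats_rows.append(_result_row(r))
                except ValueError as err:
                    logger.info("dunn skipped for %s: %s", dimension, err)
        sp_vals, u_vals = _merged(groups)
        if sp_vals and u_vals:
            mw = mann_whitney(
                u_vals, sp_vals, comparison=f"median {dimension}: U vs S+P"
            )
            stats_rows.append(_result_row(mw))

    # ---- questionnaire sections ------------------------------------------
    if questionnaires:
        stage("questionnaire_stats")
        for section in SECTION_KEYS:
            scores = {
                q.dyad_id: q.section_score(section, config.section_aggregation)
                for q in questionnaires
                if section in q.items and q.dyad_id in classes
            }
            if not scores:
                continue
            groups = _grouped(scores, classes)
            nonempty = {g: v for g, v in groups.items() if v}
            if len(nonempty) >= 2:
                kw = kruskal_wallis(nonempty, comparison=f"{section}: S vs P vs U")
                stats_rows.append(_result_row(kw))
                if len(nonempty) >= 3 and kw.p < 0.1:
                    try:
                        for r in dunn_holm(nonempty):
                            r.comparison = f"{section}: {r.comparison}"
                            stats_rows.append(_result_row(r))
                    except ValueError as err:
                        logger.info("dunn skipped for %s: %s", section, err)
            sp_vals, u_vals = _merged(groups)
            if sp_vals and u_vals:
                mw = mann_whitney(u_vals, sp_vals, comparison=f"{section}: U vs S+P")
                stats_rows.append(_result_row(mw))

    # ---- cortisol ---------------------------------------------------------
    if config.cortisol_path:
        stage("cortisol")
        pairs = fileio.read_cortisol(config.cortisol_path)
        complete = [p for p in pairs if p.complete]
        report["cortisol"] = {
            "n_pairs": len(pairs),
            "n_complete": len(complete),
            "n_samples": 2 * len(complete),
        }
        t0 = [p.t0 for p in complete]
        t1 = [p.t1 for p in complete]
        for label, values in (("T0", t0), ("T1", t1)):
            w, p, normal = shapiro_gate(values)
            report["cortisol"][f"shapiro_{label}"] = {
                "W": w, "p": p, "normal": normal,
            }
        stats_rows.append(
            _result_row(wilcoxon_paired(t0, t1, comparison="cortisol: T1 vs T0 (all)"))
        )
        deltas = delta_cortisol(pairs, classes)
        nonempty = {g: v for g, v in deltas.items() if len(v)}
        if len(nonempty) >= 2:
            stats_rows.append(
                _result_row(
                    kruskal_wallis(nonempty, comparison="delta cortisol: S vs P vs U")
                )
            )
        sp_vals, u_vals = _merged({g: list(v) for g, v in deltas.items()})
        if len(sp_vals) >= 2 and len(u_vals) >= 2:
            stats_rows.append(
                _result_row(
                    mann_whitney(u_vals, sp_vals, comparison="delta cortisol: U vs S+P")
                )
            )

    # ---- write report -----------------------------------------------------
    stage("write_report")
    report["group_tests"] = stats_rows
    report["provenance"] = _provenance(config)
    pd.DataFrame(stats_rows).to_csv(outdir / "group_tests.csv", index=False)
    pd.DataFrame(
        [
            {"dyad_id": d, **{k: v for k, v in c.items() if k != "triggered_rules"},
             "triggered_rules": "; ".join(c.get("triggered_rules", []))}
            for d, c in report["classifications"].items()
        ]
    ).to_csv(outdir / "classifications.csv", index=False)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _provenance(config: RunConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["classification"]["critical"] = sorted(
        sp.code for sp in config.classification.critical
    )
    doc["classification"]["food_exempt"] = config.classification.food_exempt.code
    doc["classification"]["region"] = dataclasses.asdict(config.classification.region)
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "seed": config.seed,
        "config": doc,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
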