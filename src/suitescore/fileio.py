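"""Readers and writers for the pipeline's plain-text formats.

Formats (all UTF-8 CSV with header, decimal point):

* **score sheet** — long format, one row per
  ``(dyad_id, rater_id, subphase, valence, arousal, aggression,
  refusal, note)``;
* **questionnaire** — one row per dyad, section-prefixed item columns
  (``separation__item1`` ...) plus an ``open_ended`` controlled-
  vocabulary column;
* **cortisol** — ``dyad_id, t0, t1`` with blanks for missing samples;
* **contingency** — 3x3 S/P/U count table;
* **classification overrides** — ``dyad_id, suitability`` pairs for
  running the agreement stage on externally determined classes.

Malformed rows are rejected with their line number.  All writers
round-trip losslessly through their readers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import CLASSES, ContingencyTable3x3
from .group_stats import CortisolPair
from .questionnaire import QuestionnaireResponse, SECTION_KEYS
from .score_model import (
    RaterSheet,
    ScoreValidationError,
    SubPhase,
    SubPhaseScore,
)

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "dyad_id", "rater_id", "subphase", "valence", "arousal",
    "aggression", "refusal", "note",
]


class SchemaError(ValueError):
    """A file does not conform to its schema; the message names the row."""


def write_scores(sheets: Iterable[RaterSheet], path) -> None:
    rows = []
    for sheet in sheets:
        for sp in SubPhase:
            if sp not in sheet.scores:
                continue
            s = sheet.scores[sp]
            rows.append(
                {
                    "dyad_id": sheet.dyad_id,
                    "rater_id": sheet.rater_id,
                    "subphase": sp.code,
                    "valence": s.valence,
                    "arousal": s.arousal,
                    "aggression": int(s.aggression),
                    "refusal": int(s.refusal),
                    "note": s.note,
                }
            )
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def read_scores(path) -> list[RaterSheet]:
    """Parse a long-format score CSV into per-(dyad, rater) sheets."""
    df = pd.read_csv(path, dtype={"dyad_id": str, "rater_id": str})
    missing_cols = set(SCORE_COLUMNS[:-1]) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"score file missing columns: {sorted(missing_cols)}")
    if df.empty:
        logger.warning("score file %s contains a header but no rows", path)
        return []

    sheets: dict[tuple[str, str], RaterSheet] = {}
    for row in df.itertuples():
        line = row.Index + 2  # header is line 1
        try:
            subphase = SubPhase.from_code(str(row.subphase))
            score = SubPhaseScore(
                subphase=subphase,
                valence=float(row.valence),
                arousal=float(row.arousal),
                aggression=bool(int(row.aggression)),
                refusal=bool(int(row.refusal)),
                note="" if pd.isna(getattr(row, "note", "")) else str(row.note),
            )
        except (ScoreValidationError, ValueError) as err:
            raise SchemaError(f"{path}, line {line}: {err}") from None
        key = (row.dyad_id, row.rater_id)
        sheet = sheets.setdefault(
            key, RaterSheet(dyad_id=row.dyad_id, rater_id=row.rater_id)
        )
        try:
            sheet.add(score)
        except ScoreValidationError as err:
            raise SchemaError(f"{path}, line {line}: {err}") from None
    return list(sheets.values())


def write_questionnaires(
    responses: Sequence[QuestionnaireResponse], path
) -> None:
    rows = []
    for q in responses:
        row: dict = {"dyad_id": q.dyad_id, "open_ended": q.open_ended}
        for section in SECTION_KEYS:
            for i, item in enumerate(q.items.get(section, []), start=1):
                row[f"{section}__item{i}"] = item
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_questionnaires(path) -> list[QuestionnaireResponse]:
    df = pd.read_csv(path, dtype={"dyad_id": str})
    if "dyad_id" not in df.columns:
        raise SchemaError("questionnaire file missing 'dyad_id' column")
    item_cols: dict[str, list[str]] = {s: [] for s in SECTION_KEYS}
    for col in df.columns:
        if "__item" in col:
            section = col.split("__item")[0]
            if section not in item_cols:
                raise SchemaError(f"unknown questionnaire section {section!r}")
            item_cols[section].append(col)
    responses = []
    for row in df.itertuples():
        items = {
            section: [getattr(row, col) for col in cols]
            for section, cols in item_cols.items()
            if cols
        }
        open_ended = getattr(row, "open_ended", None)
        responses.append(
            QuestionnaireResponse(
                dyad_id=row.dyad_id,
                items=items,
                open_ended=None if pd.isna(open_ended) else str(open_ended),
            )
        )
    return responses


def write_cortisol(pairs: Sequence[CortisolPair], path) -> None:
    pd.DataFrame(
        [{"dyad_id": p.dyad_id, "t0": p.t0, "t1": p.t1} for p in pairs]
    ).to_csv(path, index=False)


def read_cortisol(path) -> list[CortisolPair]:
    df = pd.read_csv(path, dtype={"dyad_id": str})
    for col in ("dyad_id", "t0", "t1"):
        if col not in df.columns:
            raise SchemaError(f"cortisol file missing {col!r} column")
    return [
        CortisolPair(dyad_id=row.dyad_id, t0=float(row.t0), t1=float(row.t1))
        for row in df.itertuples()
    ]


def write_contingency(table: ContingencyTable3x3, path) -> None:
    table.to_frame().to_csv(path, index_label="expected\\observed")


def read_contingency(path) -> ContingencyTable3x3:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(CLASSES) or list(df.columns) != list(CLASSES):
        raise SchemaError("contingency table must have S, P, U rows and columns")
    return ContingencyTable3x3(df.to_numpy())


def read_class_overrides(path) -> dict[str, str]:
    """Externally determined S/P/U labels, one ``dyad_id, suitability`` row each."""
    df = pd.read_csv(path, dtype=str)
    for col in ("dyad_id", "suitability"):
        if col not in df.columns:
            raise SchemaError(f"override file missing {col!r} column")
    bad = set(df["suitability"]) - set(CLASSES)
    if bad:
        raise SchemaError(f"override file has unknown classes: {sorted(bad)}")
    return dict(zip(df["dyad_id"], df["suitability"]))


def read_truth(path) -> dict[str, str]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)["latent_classes"]
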