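"""Agreement analysis: contingency tables, Cohen's kappa, concordance, ICC.

Two distinct questions of agreement arise in validating the test:

* Do caregivers' expectations (from the questionnaire's open-ended
  verdict) agree with the test's outcome?  Answered with a 3x3
  contingency table over S/P/U, unweighted Cohen's kappa and per-class
  concordance percentages.
* Do the two independent video evaluators agree with each other?
  Answered with a two-way intraclass correlation over all pooled
  (dyad, sub-phase) scores, one dimension at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg

CLASSES = ("S", "P", "U")

#: Landis-Koch interpretation bands for kappa, attached informationally.
_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0 + 1e-12, "almost perfect"),
)


def kappa_label(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    for upper, label in _KAPPA_BANDS[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"


@dataclass
class ContingencyTable3x3:
    """Counts of (expected class row, observed class column) pairs."""

    counts: np.ndarray  # shape (3, 3), rows/cols ordered S, P, U

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("contingency table must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASSES), columns=list(CLASSES))


def build_contingency(
    expected: Sequence[str], observed: Sequence[str]
) -> ContingencyTable3x3:
    """Tally aligned (expected, observed) class pairs into a 3x3 table."""
    if len(expected) != len(observed):
        raise ValueError(
            f"length mismatch: {len(expected)} expected vs {len(observed)} observed"
        )
    if len(expected) == 0:
        raise ValueError("cannot build a contingency table from empty lists")
    idx = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((3, 3), dtype=int)
    for e, o in zip(expected, observed):
        try:
            counts[idx[e], idx[o]] += 1
        except KeyError as err:
            raise ValueError(f"unknown class label {err.args[0]!r}") from None
    return ContingencyTable3x3(counts)


@dataclass
class AgreementResult:
    kappa: float
    p_observed: float
    p_expected: float
    row_concordance_pct: dict[str, float | None]
    overall_concordance_pct: float
    label: str


def cohens_kappa(table: ContingencyTable3x3) -> AgreementResult:
    """Unweighted Cohen's kappa with observed/expected agreement.

    kappa = (p_o - p_e) / (1 - p_e) with p_o = trace/N and
    p_e = sum_i row_i * col_i / N^2.  Degenerate tables with p_e = 1
    (all mass in one row and one column) have undefined kappa.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    p_o = float(np.trace(table.counts)) / n
    p_e = float(table.row_totals @ table.col_totals) / n**2
    if p_e >= 1.0:
        raise ValueError("degenerate table: expected agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    rows, overall = concordance(table)
    return AgreementResult(
        kappa=kappa,
        p_observed=p_o,
        p_expected=p_e,
        row_concordance_pct=rows,
        overall_concordance_pct=overall,
        label=kappa_label(kappa),
    )


def concordance(
    table: ContingencyTable3x3,
) -> tuple[dict[str, float | None], float]:
    """Per-row and overall concordance percentages.

    Row concordance is 100 * diagonal / row total (``None`` for empty
    rows); overall is 100 * trace / N.
    """
    if table.n == 0:
        raise ValueError("empty table")
    rows: dict[str, float | None] = {}
    for i, cls in enumerate(CLASSES):
        total = table.row_totals[i]
        rows[cls] = 100.0 * table.counts[i, i] / total if total else None
    overall = 100.0 * float(np.trace(table.counts)) / table.n
    return rows, overall


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    p: float

    def __post_init__(self) -> None:
        # bounds may be rounded by the backend; allow half a rounding unit
        if not (self.ci_low - 0.006 <= self.icc <= self.ci_high + 0.006):
            raise ValueError("ICC confidence interval does not contain the estimate")


#: Friendly model name -> (pingouin Type label, description).
_ICC_MODELS = {
    "ICC1": ("ICC(1,1)", "one-way random, single rater"),
    "ICC2": ("ICC(A,1)", "two-way random, single rater, absolute agreement"),
    "ICC3": ("ICC(C,1)", "two-way mixed, single rater, consistency"),
    "ICC1k": ("ICC(1,k)", "one-way random, average of k raters"),
    "ICC2k": ("ICC(A,k)", "two-way random, average of k raters, absolute agreement"),
    "ICC3k": ("ICC(C,k)", "two-way mixed, average of k raters, consistency"),
}


def icc_two_rater(scores: np.ndarray, model: str = "ICC3") -> ICCResult:
    """Intraclass correlation for an (items x raters) score matrix.

    Items are all pooled (dyad, sub-phase) pairs for one dimension
    (valence or arousal).  The default model is two-way, single-rater,
    consistency — ICC(3,1) — with the model descriptor always surfaced
    in the result.  Rows containing missing values are dropped.
    """
    if model not in _ICC_MODELS:
        raise ValueError(f"unknown ICC model {model!r}")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("need an (items x raters) matrix with >= 2 raters")
    scores = scores[~np.isnan(scores).any(axis=1)]
    if scores.shape[0] < 5:
        raise ValueError("need >= 5 complete items")
    if np.ptp(scores) == 0 or np.allclose(np.var(scores.mean(axis=1)), 0):
        raise ValueError("constant data: between-item variance is zero")

    n_items, n_raters = scores.shape
    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n_items), n_raters),
            "rater": np.tile(np.arange(n_raters), n_items),
            "score": scores.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="item", raters="rater", ratings="score"
    ).set_index("Type")
    type_label, description = _ICC_MODELS[model]
    row = res.loc[type_label]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = (float(b) for b in row[ci_col])
    return ICCResult(
        icc=float(row["ICC"]),
        ci_low=ci_low,
        ci_high=ci_high,
        model=f"{model} ({description})",
        p=float(row["pval"]),
    )
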