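"""Nonparametric comparison battery over per-dyad summaries.

All group comparisons are rank-based, mirroring an analysis plan where
Shapiro-Wilk rejects normality and the nonparametric path is taken
throughout: Kruskal-Wallis across the three suitability classes with an
eta-squared effect size and Dunn-Holm post hocs, Mann-Whitney for the
merged two-group design (S+P vs U) with a rank-biserial-style r, paired
Wilcoxon for pre/post cortisol, plus the cortisol delta construction.

Effect-size conventions
-----------------------
For Kruskal-Wallis, ``eta2 = (H - k + 1) / (n - k)`` (rank epsilon-
squared family); it can be slightly negative when H < k - 1.  Magnitude
bands: small < 0.06 <= moderate < 0.14 <= large.  For Mann-Whitney,
``r = |z| / sqrt(n1 + n2)`` with bands 0.1 / 0.3 / 0.5.  These bands are
this package's convention and are reported alongside every statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass
class GroupTestResult:
    test: str
    comparison: str
    statistic: float
    statistic_name: str
    df: int | None
    p: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    magnitude: str | None = None

    @property
    def significance_code(self) -> str:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return significance_code(p)


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "ns"


def eta_squared_h(h: float, k: int, n: int) -> float:
    """Rank eta-squared from the Kruskal-Wallis H statistic."""
    if n <= k:
        raise ValueError("need n > k")
    return (h - k + 1) / (n - k)


def eta_squared_magnitude(eta2: float) -> str:
    if eta2 < 0.06:
        return "small"
    if eta2 < 0.14:
        return "moderate"
    return "large"


def r_magnitude(r: float) -> str:
    r = abs(r)
    if r < 0.1:
        return "negligible"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "moderate"
    return "large"


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], comparison: str | None = None
) -> GroupTestResult:
    """Kruskal-Wallis H test (tie-corrected) with rank eta-squared."""
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(v.size for v in arrays.values())
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0  # all observations tied: no evidence of any difference
    else:
        h, p = stats.kruskal(*arrays.values())
    eta2 = eta_squared_h(float(h), k, n)
    return GroupTestResult(
        test="kruskal_wallis",
        comparison=comparison or " vs ".join(arrays),
        statistic=float(h),
        statistic_name="H",
        df=k - 1,
        p=float(p),
        effect_size=eta2,
        effect_size_name="eta2",
        magnitude=eta_squared_magnitude(eta2),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (order preserved)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def dunn_holm(groups: Mapping[str, Sequence[float]]) -> list[GroupTestResult]:
    """All pairwise Dunn z-tests on pooled ranks, Holm-adjusted.

    The pairwise statistic is the difference of mean ranks divided by
    its tie-corrected standard error,
    ``sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j))``,
    with a two-sided normal p-value.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 3:
        raise ValueError("Dunn post hoc needs >= 3 groups")
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
    labels = list(arrays)
    pooled = np.concatenate([arrays[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in labels:
        size = arrays[g].size
        mean_ranks[g] = float(ranks[start : start + size].mean())
        sizes[g] = size
        start += size

    tie_var = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )
    if tie_var <= 0:
        raise ValueError("all pooled observations are tied")
    results = []
    for g1, g2 in combinations(labels, 2):
        se = math.sqrt(tie_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        results.append(
            GroupTestResult(
                test="dunn",
                comparison=f"{g1} vs {g2}",
                statistic=z,
                statistic_name="z",
                df=None,
                p=p,
            )
        )
    adjusted = holm_adjust([r.p for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def mann_whitney(
    g1: Sequence[float],
    g2: Sequence[float],
    comparison: str = "g1 vs g2",
    method: str = "asymptotic",
) -> GroupTestResult:
    """Mann-Whitney U with tie-corrected normal z and r = |z|/sqrt(n).

    ``method`` controls the p-value only ("asymptotic" or "exact"; the
    exact method is valid for small tie-free samples).  The effect size
    always uses the tie-corrected normal approximation without
    continuity correction.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # all observations tied: U at its null mean, no effect
        u, p_value, z = n1 * n2 / 2.0, 1.0, 0.0
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        u = float(res.statistic)
        p_value = float(res.pvalue)
        var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
        z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    r = abs(z) / math.sqrt(n)
    return GroupTestResult(
        test="mann_whitney",
        comparison=comparison,
        statistic=u,
        statistic_name="U",
        df=None,
        p=p_value,
        effect_size=r,
        effect_size_name="r",
        magnitude=r_magnitude(r),
    )


def mann_whitney_r(u: float, n1: int, n2: int) -> float:
    """r = |z|/sqrt(n) from a U statistic, tie-free normal approximation."""
    var = n1 * n2 * (n1 + n2 + 1) / 12.0
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    return abs(z) / math.sqrt(n1 + n2)


def wilcoxon_paired(
    t0: Sequence[float], t1: Sequence[float], comparison: str = "T1 vs T0"
) -> GroupTestResult:
    """Paired Wilcoxon signed-rank test on T1 - T0.

    Zero differences are dropped before ranking; the reported statistic
    is V, the sum of ranks of positive differences.
    """
    d = np.asarray(t1, dtype=float) - np.asarray(t0, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return GroupTestResult(
        test="wilcoxon_paired",
        comparison=comparison,
        statistic=v,
        statistic_name="V",
        df=None,
        p=float(res.pvalue),
    )


def shapiro_gate(values: Sequence[float]) -> tuple[float, float, bool]:
    """Shapiro-Wilk W, p, and a normality flag (p >= 0.05).

    The flag documents why the nonparametric path is justified; it is
    never used to switch methods silently.
    """
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no defined W statistic")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p >= 0.05)


@dataclass(frozen=True)
class CortisolPair:
    """Pre/post salivary cortisol for one dyad (ng/mL)."""

    dyad_id: str
    t0: float
    t1: float

    @property
    def delta(self) -> float:
        return self.t1 - self.t0

    @property
    def complete(self) -> bool:
        return not (math.isnan(self.t0) or math.isnan(self.t1))


def delta_cortisol(
    pairs: Sequence[CortisolPair],
    classes: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-dyad T1 - T0 deltas, grouped by suitability class.

    Pairs with a missing member (NaN) are excluded and logged, mirroring
    swab failures in practice.  With ``classes=None`` all deltas land in
    a single ``"all"`` group.
    """
    excluded = [p.dyad_id for p in pairs if not p.complete]
    if excluded:
        logger.info(
            "excluding %d incomplete cortisol pair(s): %s",
            len(excluded), ", ".join(excluded),
        )
    kept = [p for p in pairs if p.complete]
    for p in kept:
        if p.t0 < 0 or p.t1 < 0:
            raise ValueError(f"dyad {p.dyad_id}: negative cortisol concentration")
    groups: dict[str, list[float]] = {}
    for p in kept:
        g = classes[p.dyad_id] if classes is not None else "all"
        groups.setdefault(g, []).append(p.delta)
    return {g: np.asarray(v) for g, v in groups.items()}
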