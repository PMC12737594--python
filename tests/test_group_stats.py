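import numpy as np
import pytest
from scipy import stats

from suitescore.group_stats import (
    CortisolPair,
    delta_cortisol,
    dunn_holm,
    eta_squared_h,
    eta_squared_magnitude,
    holm_adjust,
    kruskal_wallis,
    mann_whitney,
    mann_whitney_r,
    shapiro_gate,
    significance_code,
    wilcoxon_paired,
)


class TestEtaSquared:
    @pytest.mark.parametrize(
        "h,expected",
        [(8.06, 0.173), (1.35, -0.0186), (6.34, 0.124), (5.41, 0.0974)],
    )
    def test_three_group_values(self, h, expected):
        # to one unit in the last quoted digit
        tol = 10.0 ** -(len(str(expected).split(".")[1]))
        assert eta_squared_h(h, k=3, n=38) == pytest.approx(expected, abs=tol)

    def test_magnitude_bands(self):
        assert eta_squared_magnitude(-0.0186) == "small"
        assert eta_squared_magnitude(0.0865) == "moderate"
        assert eta_squared_magnitude(0.173) == "large"


class TestKruskalWallis:
    def test_identical_groups_yield_null(self):
        r = kruskal_wallis({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4], "C": [1, 2, 3, 4]})
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p > 0.99
        assert r.df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no observations"):
            kruskal_wallis({"A": [1.0], "B": []})

    def test_two_groups_match_mann_whitney_z(self):
        # on tie-free data, H = z^2 so the chi2(1) and normal p agree
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=15), rng.normal(1.0, 1, size=20)
        kw = kruskal_wallis({"A": a, "B": b})
        mw = mann_whitney(a, b)
        var = 15 * 20 * 36 / 12
        z = (mw.statistic - 150) / np.sqrt(var)
        assert kw.statistic == pytest.approx(z**2, abs=1e-9)
        assert kw.p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(m, 1, 12) for g, m in [("A", 0), ("B", 0.5), ("C", 1)]}
        base = kruskal_wallis(groups)
        warped = kruskal_wallis({g: np.exp(v) for g, v in groups.items()})
        assert warped.statistic == pytest.approx(base.statistic)
        assert warped.p == pytest.approx(base.p)


class TestHolm:
    def test_step_down_example(self):
        adjusted = holm_adjust([0.00004, 0.01365, 0.481])
        assert adjusted == pytest.approx([0.00012, 0.0273, 0.481])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_single_comparison_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(9)
        raw = rng.uniform(size=8)
        adjusted = holm_adjust(raw)
        assert (adjusted >= raw - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(adjusted[order]) >= -1e-15).all()


class TestDunn:
    def test_pairwise_count_and_adjustment(self):
        rng = np.random.default_rng(1)
        groups = {
            "S": rng.normal(2, 1, 9),
            "P": rng.normal(2, 1, 5),
            "U": rng.normal(0, 1, 24),
        }
        results = dunn_holm(groups)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted >= r.p - 1e-15
            assert r.p_adjusted <= 1.0

    def test_matches_hand_computed_rank_oracle(self):
        # tie-free data with hand-computed mean ranks: A -> 4.2, B -> 7,
        # C -> 12.8; SE = sqrt(N(N+1)/12 * (1/5 + 1/5)) = sqrt(8).
        groups = {
            "A": [1.0, 2.0, 3.0, 4.0, 5.0],
            "B": [2.5, 3.5, 4.5, 5.5, 6.5],
            "C": [6.0, 7.0, 8.0, 9.0, 10.0],
        }
        se = np.sqrt(8.0)
        by_pair = {r.comparison: r.statistic for r in dunn_holm(groups)}
        assert by_pair["A vs B"] == pytest.approx((4.2 - 7.0) / se)
        assert by_pair["A vs C"] == pytest.approx((4.2 - 12.8) / se)
        assert by_pair["B vs C"] == pytest.approx((7.0 - 12.8) / se)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError, match=">= 3"):
            dunn_holm({"A": [1.0], "B": [2.0]})


class TestMannWhitney:
    def test_identical_multisets_give_half_max_u(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_separated_groups_small_u_small_p(self):
        r = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert r.statistic == 0.0
        assert r.p < 0.05
        assert r.magnitude == "large"

    def test_effect_size_from_u(self):
        assert mann_whitney_r(25.5, 14, 24) == pytest.approx(0.70, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_uniform_shift_gives_maximal_v(self):
        t0 = np.arange(1, 11, dtype=float)
        r = wilcoxon_paired(t0, t0 + 0.5)
        assert r.statistic == 10 * 11 / 2

    def test_antisymmetric_differences_near_null(self):
        t0 = np.zeros(10)
        t1 = np.array([1, -1, 2, -2, 3, -3, 4, -4, 5, -5], dtype=float)
        assert wilcoxon_paired(t0, t1).p > 0.9

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired([1.0] * 6, [1.0] * 6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_paired([1, 2, 3], [2, 3, 4])


class TestShapiroGate:
    def test_lognormal_sample_fails_gate(self):
        x = np.exp(np.random.default_rng(0).normal(size=35))
        w, p, normal = shapiro_gate(x)
        assert not normal and p < 0.05

    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(1)
        passed = sum(shapiro_gate(rng.normal(size=200))[2] for _ in range(40))
        assert passed >= 32  # ~95% expected pass rate at alpha 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_gate([2.0] * 10)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])


class TestDeltaCortisol:
    def test_deltas_and_grouping(self):
        pairs = [
            CortisolPair("d1", 1.0, 1.5),
            CortisolPair("d2", 2.0, 2.0),
            CortisolPair("d3", 1.2, 0.7),
        ]
        groups = delta_cortisol(pairs, {"d1": "S", "d2": "S", "d3": "U"})
        assert groups["S"] == pytest.approx([0.5, 0.0])
        assert groups["U"] == pytest.approx([-0.5])

    def test_incomplete_pairs_excluded(self):
        pairs = [CortisolPair(f"d{i}", 1.0, 1.1) for i in range(35)]
        pairs += [CortisolPair(f"x{i}", float("nan"), 1.0) for i in range(3)]
        groups = delta_cortisol(pairs)
        assert len(groups["all"]) == 35

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            delta_cortisol([CortisolPair("d1", -0.1, 1.0)])


def test_significance_codes():
    assert [significance_code(p) for p in (0.0001, 0.005, 0.02, 0.07, 0.5)] == [
        "***", "**", "*", ".", "ns",
    ]
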