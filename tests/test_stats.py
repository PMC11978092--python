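"""The two bespoke statistics, checked against independent oracles.

The Mann–Whitney feature is validated against (i) brute-force enumeration
of all rank assignments for small samples and (ii) scipy's rank-sum
implementation for the asymptotic branch. The hybrid Pearson/G statistic
is validated against scipy's chi2_contingency in both branches.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hs

from pathdrug.stats import (
    ContingencyTable2x2,
    absolute_copy_number,
    chi_square_g,
    cnv_contingency,
    exact_u_sf,
    mann_whitney_diff,
    mutation_contingency,
)


def brute_force_exact_p(within, outside):
    """Two-sided exact p by enumerating every C(n+m, n) rank assignment."""
    n, m = len(within), len(outside)
    pooled = np.concatenate([within, outside])
    ranks = st.rankdata(pooled)
    r1 = ranks[:n].sum()
    u1 = r1 - n * (n + 1) / 2
    u_obs = max(u1, n * m - u1)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = sum(range(1, n + m + 1)[i] for i in combo) - n * (n + 1) / 2
        total += 1
        count += u >= u_obs
    return min(1.0, 2 * count / total)


class TestMannWhitney:
    def test_balanced_tie_gives_p_one_feature_zero(self):
        res = mann_whitney_diff([5], [5])
        assert res.U1 == res.U2 == 0.5
        assert res.p == 1.0
        assert res.feature == 0.0

    def test_small_sample_exact_example(self):
        # within {1,2} vs outside {3,4}: U=4, two-sided p = 2/6
        res = mann_whitney_diff([1, 2], [3, 4], mode="exact")
        assert (res.U1, res.U2, res.U) == (0, 4, 4)
        assert res.p == pytest.approx(2 / 6, abs=1e-12)
        assert res.feature == pytest.approx(abs(math.log10(2 / 6)), abs=1e-9)

    def test_empty_side_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_diff([], [1.0])

    def test_exact_with_ties_falls_back_to_asymptotic(self, caplog):
        res = mann_whitney_diff([1, 1, 2], [2, 3, 4], mode="exact")
        assert res.method_used == "asymptotic"

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 4), (5, 5), (1, 6), (6, 3)])
    def test_exact_branch_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(25):
            pooled = rng.permutation(np.arange(1.0, n + m + 1))
            within, outside = pooled[:n], pooled[n:]
            res = mann_whitney_diff(within, outside, mode="exact")
            assert res.p == pytest.approx(
                brute_force_exact_p(within, outside), abs=1e-12
            )

    def test_asymptotic_matches_reference_rank_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a = rng.normal(size=30)
            b = rng.normal(0.4, size=30)
            res = mann_whitney_diff(a, b, mode="asymptotic")
            ref = st.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_asymptotic_agree_in_normal_regime(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        p_exact = mann_whitney_diff(a, b, mode="exact").p
        p_asym = mann_whitney_diff(a, b, mode="asymptotic").p
        assert p_exact == pytest.approx(p_asym, abs=0.01)

    @given(
        hs.lists(hs.floats(-50, 50), min_size=1, max_size=12),
        hs.lists(hs.floats(-50, 50), min_size=1, max_size=12),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_u1_plus_u2_is_nm(self, within, outside):
        res = mann_whitney_diff(within, outside)
        assert res.U1 + res.U2 == pytest.approx(len(within) * len(outside))
        assert 0.0 < res.p <= 1.0
        assert res.feature >= 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=15)
            b = rng.normal(1.0, size=10)
            base = mann_whitney_diff(a, b)
            trans = mann_whitney_diff(np.exp(a / 4), np.exp(b / 4))
            assert trans.p == pytest.approx(base.p, rel=1e-12)

    def test_exact_sf_boundaries(self):
        assert exact_u_sf(0, 3, 3) == 1.0
        assert exact_u_sf(10, 3, 3) == 0.0
        assert exact_u_sf(9, 3, 3) == pytest.approx(1 / 20)


class TestChiSquareG:
    def test_independence_table_is_zero(self):
        assert chi_square_g(ContingencyTable2x2(10, 10, 10, 10)) == 0.0

    def test_pearson_branch_hand_value(self):
        # [[10,20],[20,10]]: all E = 15 > 5 -> sum (O-E)^2/E = 20/3
        assert chi_square_g(ContingencyTable2x2(10, 20, 20, 10)) == pytest.approx(20 / 3)

    def test_g_branch_hand_value(self):
        # [[1,9],[2,8]]: min E = 1.5 <= 5 -> G = 2 sum O ln(O/E)
        obs = np.array([[1, 9], [2, 8]], dtype=float)
        e = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        g = 2 * (obs * np.log(obs / e)).sum()
        assert chi_square_g(ContingencyTable2x2(1, 9, 2, 8)) == pytest.approx(g)
        assert chi_square_g(ContingencyTable2x2(1, 9, 2, 8)) == pytest.approx(0.3986, abs=1e-4)

    def test_zero_expected_cell_returns_zero(self):
        assert chi_square_g(ContingencyTable2x2(5, 0, 7, 0)) == 0.0
        assert chi_square_g(ContingencyTable2x2(0, 0, 0, 0)) == 0.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            chi_square_g(np.array([[-1, 2], [3, 4]]))

    def test_zero_observed_in_g_branch_contributes_nothing(self):
        # O = 0 cells use the 0 * ln(0/E) = 0 convention
        val = chi_square_g(ContingencyTable2x2(0, 3, 4, 5))
        assert np.isfinite(val) and val >= 0

    def test_matches_scipy_in_both_branches(self):
        rng = np.random.default_rng(3)
        checked = {"pearson": 0, "g": 0}
        for _ in range(400):
            obs = rng.integers(0, 40, size=(2, 2)).astype(float)
            expected = np.outer(obs.sum(1), obs.sum(0)) / max(obs.sum(), 1)
            ours = chi_square_g(obs)
            if (expected == 0).any():
                assert ours == 0.0
                continue
            lam = "pearson" if expected.min() > 5 else "log-likelihood"
            ref = st.chi2_contingency(
                obs, correction=False,
                lambda_=lam if lam != "pearson" else 1,
            )[0]
            assert ours == pytest.approx(ref, rel=1e-10, abs=1e-12)
            checked["pearson" if lam == "pearson" else "g"] += 1
        assert min(checked.values()) > 20  # both branches exercised

    def test_row_swap_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            t1 = chi_square_g(ContingencyTable2x2(a, b, c, d))
            t2 = chi_square_g(ContingencyTable2x2(c, d, a, b))
            assert t1 == pytest.approx(t2, rel=1e-12, abs=1e-12)


class TestContingencyBuilders:
    UNIVERSE = ["g1", "g2", "g3", "g4"]

    def test_mutation_counts_small_example(self):
        statuses = {"g1": 1, "g2": 0, "g3": 0, "g4": 2}
        t = mutation_contingency(statuses, ["g1", "g2"], self.UNIVERSE)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_normal_statuses_zero_statistic(self):
        statuses = {g: 0 for g in self.UNIVERSE}
        t = mutation_contingency(statuses, ["g1", "g2"], self.UNIVERSE)
        assert t.b == t.d == 0
        assert chi_square_g(t) == 0.0

    def test_empty_overlap_errors_with_set_name(self):
        with pytest.raises(ValueError, match="SETX"):
            mutation_contingency({"g1": 0}, ["gZ"], self.UNIVERSE, set_name="SETX")

    def test_mutation_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(200)]
        statuses = {g: int(rng.integers(0, 3)) for g in universe}
        gene_set = list(rng.choice(universe, size=30, replace=False))
        t = mutation_contingency(statuses, gene_set, universe)
        a = sum(1 for g in gene_set if statuses[g] == 0)
        b = sum(1 for g in gene_set if statuses[g] >= 1)
        c = sum(1 for g in universe if g not in gene_set and statuses[g] == 0)
        d = sum(1 for g in universe if g not in gene_set and statuses[g] >= 1)
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_cnv_diploid_neutral_all_normal(self):
        ratios = {g: 1.0 for g in self.UNIVERSE}
        t = cnv_contingency(ratios, 2.0, ["g1"], self.UNIVERSE)
        assert t.b == t.d == 0
        assert chi_square_g(t) == 0.0

    def test_cnv_amplification_threshold(self):
        # ploidy 2, ratio 1.6 -> absolute round(3.2) = 3 -> altered
        t = cnv_contingency({"g1": 1.6, "g2": 1.0}, 2.0, ["g1"], ["g1", "g2"])
        assert (t.a, t.b, t.c, t.d) == (0, 1, 1, 0)

    def test_cnv_matches_brute_force_classifier(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(150)]
        ratios = {g: float(rng.uniform(0, 2.5)) for g in universe}
        ploidy = 3.1
        gene_set = list(rng.choice(universe, size=25, replace=False))
        t = cnv_contingency(ratios, ploidy, gene_set, universe)
        def classify(g):
            absolute = np.rint(ratios[g] * ploidy)
            return "normal" if absolute == 2 else "altered"
        a = sum(1 for g in gene_set if classify(g) == "normal")
        b = sum(1 for g in gene_set if classify(g) == "altered")
        c = sum(1 for g in universe if g not in gene_set and classify(g) == "normal")
        d = sum(1 for g in universe if g not in gene_set and classify(g) == "altered")
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_rounding_modes_differ_at_half(self):
        assert absolute_copy_number(np.array([1.25]), 2.0, "half_even")[0] == 2
        assert absolute_copy_number(np.array([1.25]), 2.0, "half_up")[0] == 3

    def test_nonpositive_ploidy_rejected(self):
        with pytest.raises(ValueError):
            absolute_copy_number(np.array([1.0]), 0.0)
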