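"""Statistical battery vs enumeration/hand oracles and calibration checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    bh_adjust_oracle,
    normal_two_tailed_oracle,
    ranksum_exact_oracle,
    signed_rank_less_oracle,
)
from netpert import (
    REDMatrix,
    compare_paired_one_tailed,
    compare_unpaired,
    fdr_adjust,
    omnibus_three_group,
    regionwise_tests,
    top_decile_regions,
)
from netpert.stats import cohens_d, significance_marker


class TestCompareUnpaired:
    def test_identical_groups_zero_effect(self, rng):
        a = rng.standard_normal(12)
        res = compare_unpaired(a, a.copy())
        assert res.effect_size_d == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_exact_p_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_unpaired(np.array(a), np.array(b))
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(ranksum_exact_oracle(a, b))

    def test_exact_p_random_small_samples(self, rng):
        for _ in range(5):
            a = rng.standard_normal(5)
            b = rng.standard_normal(4) + 0.5
            res = compare_unpaired(a, b)
            assert res.p_value == pytest.approx(ranksum_exact_oracle(a, b), abs=1e-12)

    def test_population_effect_size_recovered(self, rng):
        a = rng.standard_normal(10_000)
        b = rng.standard_normal(10_000) + 1.0
        res = compare_unpaired(a, b)
        assert abs(res.effect_size_d + 1.0) < 0.05
        assert res.p_value < 1e-10

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_unpaired(np.full(5, 2.0), np.full(6, 2.0))

    def test_d_antisymmetry_and_affine_invariance(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.3
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert cohens_d(3 * a + 7, 3 * b + 7) == pytest.approx(cohens_d(a, b))


class TestComparePaired:
    def test_uniform_negative_shift_exact_p(self):
        before = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        after = before - 1.0
        res = compare_paired_one_tailed(before, after)
        assert res.p_value == pytest.approx(1 / 32)
        assert res.p_value == pytest.approx(signed_rank_less_oracle(before, after))

    def test_uniform_positive_shift_large_p(self):
        before = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        res = compare_paired_one_tailed(before, before + 1.0)
        assert res.p_value >= 0.95

    def test_mixed_shift_matches_enumeration(self, rng):
        before = rng.standard_normal(8)
        after = before + rng.standard_normal(8) - 0.5
        res = compare_paired_one_tailed(before, after)
        assert res.p_value == pytest.approx(
            signed_rank_less_oracle(before, after), abs=1e-12
        )

    def test_all_zero_differences_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError, match="informative"):
            compare_paired_one_tailed(x, x.copy())

    def test_too_few_informative_pairs_rejected(self):
        before = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        after = before.copy()
        after[0] -= 1.0
        with pytest.raises(ValueError, match="at least 5"):
            compare_paired_one_tailed(before, after)


class TestFDR:
    def test_bh_arithmetic_example(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_from_definition_oracle(self, ps):
        ps = np.asarray(ps)
        np.testing.assert_allclose(fdr_adjust(ps), bh_adjust_oracle(ps), atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance(self, ps, pyrandom):
        ps = np.asarray(ps)
        perm = list(range(len(ps)))
        pyrandom.shuffle(perm)
        perm = np.asarray(perm)
        np.testing.assert_allclose(fdr_adjust(ps)[perm], fdr_adjust(ps[perm]), atol=1e-15)

    def test_adjusted_not_below_raw(self, rng):
        ps = rng.random(30)
        assert np.all(fdr_adjust(ps) >= ps - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))


class TestOmnibus:
    def test_null_calibration(self, rng):
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            g = rng.standard_normal((3, 20))
            hits += omnibus_three_group(*g).kw_p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_shifted_group_detected(self, rng):
        g1, g2 = rng.standard_normal(50), rng.standard_normal(50)
        g3 = rng.standard_normal(50) + 5.0
        rep = omnibus_three_group(g1, g2, g3, names=("a", "b", "c"))
        assert rep.kw_p < 0.001
        by_pair = {d.pair: d.adj_p for d in rep.pairwise}
        assert by_pair[("a", "c")] < 0.05
        assert by_pair[("b", "c")] < 0.05
        assert by_pair[("a", "b")] > 0.05

    def test_dunn_matches_hand_computation(self):
        # tie-free groups {1,2,3}, {4,5,6}, {7,8,9}: pooled mean ranks 2/5/8,
        # se = sqrt((9*10/12)*(2/3)) = sqrt(5)
        rep = omnibus_three_group(
            np.array([1.0, 2.0, 3.0]),
            np.array([4.0, 5.0, 6.0]),
            np.array([7.0, 8.0, 9.0]),
            names=("g1", "g2", "g3"),
        )
        se = np.sqrt(5.0)
        expected_z = {
            ("g1", "g2"): -3.0 / se,
            ("g1", "g3"): -6.0 / se,
            ("g2", "g3"): -3.0 / se,
        }
        raw = {}
        for d in rep.pairwise:
            assert d.dunn_z == pytest.approx(expected_z[d.pair], abs=1e-12)
            assert d.raw_p == pytest.approx(normal_two_tailed_oracle(d.dunn_z), rel=1e-10)
            raw[d.pair] = d.raw_p
        expected_adj = bh_adjust_oracle(np.array([raw[p] for p in sorted(raw)]))
        for pair, exp in zip(sorted(raw), expected_adj):
            got = next(d.adj_p for d in rep.pairwise if d.pair == pair)
            assert got == pytest.approx(exp, abs=1e-12)

    def test_constant_pooled_rejected(self):
        c = np.full(5, 1.0)
        with pytest.raises(ValueError, match="constant"):
            omnibus_three_group(c, c, c)


class TestRegionwise:
    def _red(self, values, prefix="s"):
        values = np.asarray(values, float)
        return REDMatrix(
            values,
            [f"{prefix}{i}" for i in range(values.shape[0])],
            [f"r{j}" for j in range(values.shape[1])],
        )

    def test_identical_groups_nothing_significant(self, rng):
        red = self._red(rng.random((20, 10)))
        rep = regionwise_tests(red, self._red(red.red.copy(), prefix="t"))
        assert not rep.significant.any()

    def test_single_shifted_region_found(self, rng):
        # the shifted region must always be flagged; BH controls the false
        # discovery *rate*, so an occasional extra region may ride along once
        # one p-value is extreme -- exact uniqueness holds in a clear majority
        exact = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.standard_normal((30, 83))
            b = r.standard_normal((30, 83))
            b[:, 17] += 10.0
            rep = regionwise_tests(self._red(a), self._red(b, prefix="t"))
            sig = set(np.flatnonzero(rep.significant))
            assert 17 in sig and len(sig) <= 2
            exact += sig == {17}
        assert exact >= 7

    def test_all_zero_inputs_give_p_one(self):
        rep = regionwise_tests(
            self._red(np.zeros((5, 4))), self._red(np.zeros((6, 4)), prefix="t")
        )
        np.testing.assert_array_equal(rep.raw_p, 1.0)
        np.testing.assert_array_equal(rep.adj_p, 1.0)
        assert not rep.significant.any()

    def test_adjusted_consistent_with_mask(self, rng):
        a = rng.standard_normal((15, 12))
        b = rng.standard_normal((15, 12)) + 0.8
        rep = regionwise_tests(self._red(a), self._red(b, prefix="t"))
        np.testing.assert_array_equal(rep.significant, rep.adj_p < 0.05)
        assert np.all(rep.adj_p >= rep.raw_p - 1e-15)


class TestTopDecile:
    def _red(self, values):
        values = np.asarray(values, float)
        return REDMatrix(
            values,
            [f"s{i}" for i in range(values.shape[0])],
            [f"r{j}" for j in range(values.shape[1])],
        )

    def test_floor_rule_83_regions(self, rng):
        top = top_decile_regions(self._red(rng.random((4, 83))))
        assert len(top) == 8

    def test_constructed_means_selected_in_order(self):
        vals = np.zeros((3, 83))
        vals[:, :8] = np.linspace(10, 3, 8)[None, :]
        top = top_decile_regions(self._red(vals))
        assert top == [f"r{j}" for j in range(8)]

    def test_tie_at_cutoff_prefers_lower_index(self):
        vals = np.zeros((2, 20))
        vals[:, 5:14] = 1.0  # nine tied columns, floor(0.1*20)=2 slots
        top = top_decile_regions(self._red(vals))
        assert top == ["r5", "r6"]


def test_significance_markers():
    assert significance_marker(0.2) == ""
    assert significance_marker(0.04) == "*"
    assert significance_marker(0.004) == "**"
    assert significance_marker(0.0004) == "***"
    assert significance_marker(0.00004) == "****"
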