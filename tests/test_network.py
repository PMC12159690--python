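"""Reference-network and perturbation tests against independent oracles."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from helpers import (
    brute_force_deviation,
    normal_two_tailed_oracle,
    pairwise_corr_oracle,
    residualize_oracle,
)
from netpert import (
    CohortSpec,
    CovariateTable,
    RegionalUptakeTable,
    build_reference_network,
    edge_pvalues,
    make_reference_cohort,
    perturb_network,
    residualize_covariates,
)


def _random_instance(rng, n, m, with_cov):
    values = rng.normal(1.5, 0.3, size=(n, m)) + 0.2 * rng.standard_normal((n, 1))
    ids = [f"S{i}" for i in range(n)]
    labels = [f"r{j}" for j in range(m)]
    table = RegionalUptakeTable(ids, labels, values)
    cov = None
    if with_cov:
        cov = CovariateTable(ids, rng.uniform(20, 70, n), rng.integers(0, 2, n))
    subj = rng.normal(1.5, 0.5, size=m)
    subj_cov = np.array([rng.uniform(25, 65), float(rng.integers(0, 2))]) if with_cov else None
    return table, cov, subj, subj_cov


class TestResidualize:
    def test_intercept_only_is_mean_centering(self, rng):
        values = rng.standard_normal((9, 4))
        out = residualize_covariates(values, None)
        np.testing.assert_allclose(out, values - values.mean(axis=0), atol=1e-12)

    def test_column_equal_to_covariate_vanishes(self, rng):
        values = rng.standard_normal((10, 3))
        cov = values[:, 1].copy()
        out = residualize_covariates(values, cov[:, None])
        assert np.max(np.abs(out[:, 1])) < 1e-10

    def test_orthogonality_and_normal_equations_oracle(self, rng):
        values = rng.standard_normal((6, 3))
        cov = rng.standard_normal((6, 1))
        out = residualize_covariates(values, cov)
        assert np.max(np.abs(out.T @ cov)) < 1e-10
        assert np.max(np.abs(out.sum(axis=0))) < 1e-10
        np.testing.assert_allclose(out, residualize_oracle(values, cov), atol=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        values = rng.standard_normal((10, 2))
        c = rng.standard_normal(10)
        with pytest.raises(ValueError, match="covariate 1"):
            residualize_covariates(values, np.column_stack([c, 2 * c]))

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError, match="rows"):
            residualize_covariates(rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))


class TestBuildReference:
    def test_affine_duplicate_region_rejected(self, rng):
        base = rng.standard_normal(20)
        values = np.column_stack([base, 2 * base + 5, rng.standard_normal(20)])
        table = RegionalUptakeTable([f"S{i}" for i in range(20)], ["a", "b", "c"], values)
        with pytest.raises(ValueError, match="degenerate"):
            build_reference_network(table)

    def test_near_perfect_anticorrelation_rejected(self, rng):
        base = rng.standard_normal(20)
        values = np.column_stack([base, -base + 1e-9 * rng.standard_normal(20)])
        table = RegionalUptakeTable([f"S{i}" for i in range(20)], ["a", "b"], values)
        with pytest.raises(ValueError, match="degenerate"):
            build_reference_network(table)

    def test_zero_variance_region_rejected(self):
        values = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        table = RegionalUptakeTable([f"S{i}" for i in range(10)], ["a", "b"], values)
        with pytest.raises(ValueError, match="variance"):
            build_reference_network(table)

    def test_matches_pairwise_brute_force_with_covariates(self):
        spec = CohortSpec(n_subjects=20, n_regions=6, seed=11)
        table, cov = make_reference_cohort(spec)
        net = build_reference_network(table, cov)
        expected = pairwise_corr_oracle(residualize_oracle(table.values, cov.design()))
        assert np.max(np.abs(net.pcc - expected)) < 1e-12
        assert net.n_ref == 20

    def test_network_invariants(self, small_results):
        pcc = small_results.pcc
        np.testing.assert_allclose(pcc, pcc.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(pcc), 1.0)
        off = pcc[~np.eye(pcc.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 1)


class TestPerturb:
    def test_two_region_z_matches_hand_formula(self, rng):
        # m=2: the z formula can be checked against two plain pearsonr calls
        n = 25
        values = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        table = RegionalUptakeTable([f"S{i}" for i in range(n)], ["a", "b"], values)
        subj = np.array([3.0, -2.0])
        dev = perturb_network(table, None, subj)
        r_n = pearsonr(values[:, 0] - values[:, 0].mean(), values[:, 1] - values[:, 1].mean()).statistic
        stacked = np.vstack([values, subj])
        r_n1 = pearsonr(
            stacked[:, 0] - stacked[:, 0].mean(), stacked[:, 1] - stacked[:, 1].mean()
        ).statistic
        expected = (r_n1 - r_n) * (n - 1) / (1 - r_n**2)
        assert dev.z[1, 0] == pytest.approx(expected, abs=1e-10)
        assert dev.z[0, 0] == 0.0

    @pytest.mark.parametrize("with_cov", [False, True])
    def test_equals_two_build_brute_force(self, rng, with_cov):
        for _ in range(10):
            n = int(rng.integers(10, 41))
            m = int(rng.integers(4, 13))
            table, cov, subj, subj_cov = _random_instance(rng, n, m, with_cov)
            dev = perturb_network(table, cov, subj, subj_cov)
            expected = brute_force_deviation(
                table.values, None if cov is None else cov.design(), subj, subj_cov
            )
            assert np.max(np.abs(dev.z - expected)) < 1e-10

    def test_region_permutation_equivariance(self, rng):
        table, cov, subj, subj_cov = _random_instance(rng, 20, 6, True)
        dev = perturb_network(table, cov, subj, subj_cov)
        perm = rng.permutation(6)
        table_p = RegionalUptakeTable(
            table.subject_ids,
            [table.region_labels[i] for i in perm],
            table.values[:, perm],
        )
        dev_p = perturb_network(table_p, cov, subj[perm], subj_cov)
        np.testing.assert_allclose(dev_p.z, dev.z[np.ix_(perm, perm)], atol=1e-12)

    def test_non_finite_subject_rejected(self, rng):
        table, cov, subj, subj_cov = _random_instance(rng, 15, 5, True)
        subj[2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            perturb_network(table, cov, subj, subj_cov)

    def test_region_label_mismatch_rejected(self, rng):
        table, cov, subj, subj_cov = _random_instance(rng, 15, 5, True)
        with pytest.raises(ValueError, match="region labels"):
            perturb_network(
                table, cov, subj, subj_cov, subject_region_labels=["x"] * 5
            )

    def test_covariate_extrapolation_warns(self, rng):
        table, cov, subj, _ = _random_instance(rng, 20, 5, True)
        with pytest.warns(UserWarning, match="extrapolates"):
            perturb_network(table, cov, subj, np.array([99.0, 1.0]))

    def test_missing_subject_covariates_rejected(self, rng):
        table, cov, subj, _ = _random_instance(rng, 20, 5, True)
        with pytest.raises(ValueError, match="subject_cov"):
            perturb_network(table, cov, subj, None)

    def test_exchangeability_of_heldout_controls(self, study):
        # two held-out halves of the same null distribution give exchangeable SED
        from netpert import compare_unpaired, sed_table, threshold_extreme

        results = study["results"]
        held = CohortSpec(n_subjects=40, n_regions=83, seed=9001)
        ht, hc = make_reference_cohort(held, id_prefix="HO")
        devs = results.perturb_cohort(ht, hc)
        sed = sed_table(threshold_extreme(d, tau=2.0) for d in devs)
        p = compare_unpaired(sed.iloc[:20], sed.iloc[20:]).p_value
        assert p > 0.01


class TestEdgePvalues:
    def test_reference_values_and_oracle(self, rng):
        table, cov, subj, subj_cov = _random_instance(rng, 20, 5, True)
        dev = perturb_network(table, cov, subj, subj_cov)
        p = edge_pvalues(dev)
        np.testing.assert_allclose(np.diag(p), 1.0)
        np.testing.assert_allclose(p, p.T)
        for i, j in [(1, 0), (3, 2), (4, 1)]:
            assert p[i, j] == pytest.approx(normal_two_tailed_oracle(dev.z[i, j]), rel=1e-10)

    def test_known_quantiles(self):
        from netpert import DeviationMatrix

        z = np.zeros((2, 2))
        z[0, 1] = z[1, 0] = 1.959964
        dev = DeviationMatrix(z, "s", 30, ["a", "b"])
        p = edge_pvalues(dev)
        assert p[0, 1] == pytest.approx(0.05, abs=1e-6)
        z2 = np.zeros((2, 2))
        dev2 = DeviationMatrix(z2, "s", 30, ["a", "b"])
        assert edge_pvalues(dev2)[0, 1] == 1.0
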