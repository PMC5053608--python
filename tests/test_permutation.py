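"""Permutation engine: p-value contract, consistency with the scalar
statistics, dependency factors, and the power-law extrapolation."""

import numpy as np
import pytest
from scipy import stats

from fisherset import (ExpressionMatrix, GeneSet, PermutationOutcome,
                       RegressionFit, build_modified_null,
                       dependency_factors, extrapolate_pvalue, fisher_F,
                       fit_extrapolation, hotelling_T2, ks_statistic,
                       permute_set, samgs_statistic, stouffer_Z,
                       t_test_per_gene, tail_strength)
from fisherset import _engine

from conftest import make_matrix


class TestPermutationContract:
    def test_rank_one_gives_reciprocal(self):
        # overwhelming shift: no permutation can match the observed F
        mat = make_matrix(K=5, n1=10, n2=10, seed=1, shift=50.0)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=99, seed=7)
        assert out.count_ge == 0
        assert out.p_perm == pytest.approx(1 / 100)

    def test_add_one_arithmetic(self):
        out = PermutationOutcome(
            observed=fisher_F([0.5]), B=9, count_ge=4, p_perm=0.5, seed=0,
            permuted=np.zeros(9), gene_ids=["g"], lam=0.05,
            sig_counts=np.zeros(1, int), joint_counts=np.zeros((1, 1), int))
        assert out.p_perm == 0.5
        with pytest.raises(ValueError, match="p_perm"):
            PermutationOutcome(
                observed=fisher_F([0.5]), B=9, count_ge=4, p_perm=0.4, seed=0,
                permuted=np.zeros(9), gene_ids=["g"], lam=0.05,
                sig_counts=np.zeros(1, int), joint_counts=np.zeros((1, 1), int))

    def test_empty_set_and_zero_budget_error(self, small_mat):
        with pytest.raises(ValueError, match="empty gene set"):
            permute_set(small_mat, GeneSet("s", gene_ids=["nope"]), B=10)
        with pytest.raises(ValueError, match="B must be"):
            permute_set(small_mat, GeneSet("s", gene_ids=["g0", "g1"]), B=0)

    def test_exhaustive_mode_enumerates_all(self):
        mat = make_matrix(K=3, n1=3, n2=3, seed=2)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          exhaustive=True, B=1)
        assert out.B == 20  # C(6,3)

    def test_pperm_uniform_under_null(self):
        """Across replicate null datasets the permutation p-value is
        (discretely) uniform: the permutation test is valid."""
        reps, B = 300, 199
        ps = []
        for i in range(reps):
            mat = make_matrix(K=5, n1=10, n2=10, seed=1000 + i)
            out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                              B=B, seed=i)
            ps.append(out.p_perm)
        d = stats.kstest(ps, "uniform").statistic
        # 1% critical value plus the 1/(B+1) discretization allowance
        assert d < 1.63 / np.sqrt(reps) + 1 / (B + 1)

    def test_seed_spread_matches_binomial_error(self):
        """p_perm over seeds on fixed data scatters like a binomial
        proportion with B trials."""
        mat = make_matrix(K=5, n1=10, n2=10, seed=3, shift=0.35)
        B = 2000
        ps = [permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=B, seed=s).p_perm for s in range(30)]
        p_bar = np.mean(ps)
        se = np.sqrt(p_bar * (1 - p_bar) / B)
        assert np.std(ps) < 3 * se


class TestScalarConsistency:
    """The vectorized kernels must agree with the scalar statistics column
    by column, for every method and for both observed and permuted labels."""

    @pytest.mark.parametrize("method", ["fisher", "stouffer", "tail_strength",
                                        "ks", "samgs", "hotelling"])
    def test_observed_column_matches_scalar(self, method):
        mat = make_matrix(K=6, n1=8, n2=7, seed=11, shift=0.3)
        gs = GeneSet("s", gene_ids=mat.gene_ids)
        out = permute_set(mat, gs, method=method, B=20, seed=0, p_min=0.02)
        p = t_test_per_gene(mat)
        scalar = {
            "fisher": lambda: fisher_F(p, 0.02).value,
            "stouffer": lambda: stouffer_Z(p, two_sided=True).value,
            "tail_strength": lambda: tail_strength(p).value,
            "ks": lambda: ks_statistic(p).value,
            "samgs": lambda: samgs_statistic(mat, gs).value,
            "hotelling": lambda: hotelling_T2(mat, gs).value,
        }[method]()
        assert out.observed.value == pytest.approx(scalar, rel=1e-9)

    def test_permuted_columns_match_relabelled_scalar(self):
        mat = make_matrix(K=4, n1=5, n2=5, seed=12)
        masks = _engine.permutation_masks(10, 5, 8, np.random.default_rng(1))
        P = _engine.t_pvalues(mat.values, masks)
        for b in range(8):
            labels = np.where(masks[b], "a", "b")
            relabelled = ExpressionMatrix(mat.values, mat.gene_ids,
                                          mat.sample_ids, labels)
            np.testing.assert_allclose(P[:, b], t_test_per_gene(relabelled).p,
                                       rtol=1e-9)

    def test_wilcoxon_kernel_matches_large_sample(self):
        mat = make_matrix(K=5, n1=15, n2=15, seed=13, shift=0.5)
        masks = _engine.observed_mask(mat.group1_mask)
        P = _engine.wilcoxon_pvalues(mat.values, masks)[:, 0]
        from fisherset import wilcoxon_test_per_gene

        np.testing.assert_allclose(P, wilcoxon_test_per_gene(mat).p, rtol=1e-9)


class TestDependencyFactors:
    def test_factor_exactly_symmetric(self):
        mat = make_matrix(K=6, n1=8, n2=8, seed=21)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=500, seed=3)
        dep = dependency_factors(out)
        defined = dep.defined
        assert np.nanmax(np.abs(dep.factor - dep.factor.T)) == 0.0
        assert np.all(dep.joint <= np.minimum.outer(dep.P_single,
                                                    dep.P_single) + 1e-12)
        assert defined.shape == (6, 6)

    def test_duplicate_gene_factor_is_reciprocal_marginal(self):
        rng = np.random.default_rng(31)
        values = rng.standard_normal((3, 24))
        values[1] = values[0]  # gene g1 is an exact copy of g0
        mat = ExpressionMatrix(values, ["g0", "g1", "g2"],
                               [f"s{i}" for i in range(24)],
                               np.array(["a"] * 12 + ["b"] * 12))
        out = permute_set(mat, GeneSet("s", gene_ids=["g0", "g1", "g2"]),
                          B=4000, seed=4, lam=0.05)
        dep = dependency_factors(out)
        pa = dep.P_single[0]
        assert dep.factor[0, 1] == pytest.approx(1 / pa, rel=1e-12)
        assert 12 < dep.factor[0, 1] < 33  # ~1/lam = 20 up to MC error

    def test_independent_genes_factor_near_one(self):
        mat = make_matrix(K=10, n1=12, n2=12, seed=41)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=4000, seed=5)
        dep = dependency_factors(out)
        off = dep.factor[~np.eye(10, dtype=bool)]
        assert abs(np.nanmean(off) - 1.0) < 0.1


class TestExtrapolation:
    def test_identity_fit_returns_input(self):
        fit = RegressionFit(m=1.0, b=1.0, n_points=100, fit_range=(0.001, 0.5))
        for p in (1e-8, 0.01, 0.4):
            assert extrapolate_pvalue(fit, p) == pytest.approx(p)

    def test_published_power_law_examples(self):
        fit = RegressionFit(m=0.27, b=0.40, n_points=100, fit_range=(0.001, 0.5))
        p1 = extrapolate_pvalue(fit, 1e-2)
        assert p1 == pytest.approx(0.115, abs=0.001)
        assert p1 / 1e-2 == pytest.approx(12, abs=0.5)  # two significant figures
        p2 = extrapolate_pvalue(fit, 1e-8)
        assert p2 == pytest.approx(0.003, abs=0.0005)   # one significant figure

    def test_extrapolation_capped_at_one(self):
        fit = RegressionFit(m=0.27, b=0.40, n_points=100, fit_range=(0.001, 0.5))
        assert extrapolate_pvalue(fit, 0.999) <= 1.0

    def test_independent_data_recovers_identity(self):
        mat = make_matrix(K=20, n1=25, n2=25, seed=51)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=4000, seed=6)
        fit = fit_extrapolation(out)
        assert abs(fit.m - 1.0) < 0.25
        assert 0.5 < fit.b < 2.0

    def test_truncated_statistic_needs_matching_null(self):
        mat = make_matrix(K=10, n1=10, n2=10, seed=52)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=1000, seed=7, p_min=0.05)
        with pytest.raises(ValueError, match="truncated null"):
            fit_extrapolation(out)
        null = build_modified_null(10, 0.05, n_draws=50_000, seed=1)
        fit = fit_extrapolation(out, null=null)
        assert np.isfinite(fit.m) and fit.b > 0

    def test_too_few_pairs_errors(self):
        mat = make_matrix(K=5, n1=6, n2=6, seed=53)
        out = permute_set(mat, GeneSet("s", gene_ids=mat.gene_ids),
                          B=60, seed=8)
        with pytest.raises(ValueError, match="increase B"):
            fit_extrapolation(out)
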