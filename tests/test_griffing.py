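import numpy as np
import pandas as pd
import pytest

from diallelkit import (
    DiallelDesign,
    TruthParams,
    baker_ratio,
    combining_abilities,
    entry_means,
    griffing_anova,
    group_summary,
    heritabilities,
    relative_sca,
    simulate_diallel,
    variance_components_mom,
)
from diallelkit.simulate import PLOT_COLUMNS


def plots_from_means(x, parents, blocks=2, block_shift=None, trait="trait"):
    """Construct a complete RCBD plot table whose entry means equal ``x``."""
    p = len(parents)
    if block_shift is None:
        block_shift = np.zeros(blocks)
    assert abs(sum(block_shift)) < 1e-12
    rows = []
    for k in range(blocks):
        for i in range(p):
            for j in range(i, p):
                rows.append((k + 1, parents[i], parents[j], trait,
                             x[i][j] + block_shift[k]))
    return pd.DataFrame(rows, columns=PLOT_COLUMNS)


def ols_oracle(x, b):
    """Sequential least-squares oracle for the Method 2 partition.

    Projects the vector of distinct entry means onto {intercept} then onto
    {intercept + additive parent effects}; the sequential sums of squares
    (times b) are the GCA and SCA sums of squares.
    """
    p = x.shape[0]
    cells = [(i, j) for i in range(p) for j in range(i, p)]
    y = np.array([x[i, j] for i, j in cells])
    n = len(cells)
    Z = np.zeros((n, p))
    for k, (i, j) in enumerate(cells):
        Z[k, i] += 1
        Z[k, j] += 1
    X1 = np.ones((n, 1))
    Xa = np.hstack([X1, Z])
    P1 = X1 @ np.linalg.pinv(X1)
    Pa = Xa @ np.linalg.pinv(Xa)
    ss_gca = y @ (Pa - P1) @ y
    ss_sca = y @ (np.eye(n) - Pa) @ y
    return b * ss_gca, b * ss_sca


def constrained_ls_oracle(x):
    """Normal-equations oracle for mu and the GCA vector.

    Minimises sum over distinct cells of (x_ij - mu - g_i - g_j)^2 subject
    to sum(g) = 0, via the bordered normal equations; SCA effects are the
    residuals of that fit.
    """
    p = x.shape[0]
    cells = [(i, j) for i in range(p) for j in range(i, p)]
    n = len(cells)
    X = np.zeros((n, p + 1))
    X[:, 0] = 1.0
    y = np.empty(n)
    for k, (i, j) in enumerate(cells):
        X[k, 1 + i] += 1
        X[k, 1 + j] += 1
        y[k] = x[i, j]
    A = np.zeros((p + 2, p + 2))
    A[:p + 1, :p + 1] = X.T @ X
    A[p + 1, 1:p + 1] = 1.0
    A[1:p + 1, p + 1] = 1.0
    rhs = np.append(X.T @ y, 0.0)
    sol = np.linalg.solve(A, rhs)
    mu, g = sol[0], sol[1:p + 1]
    s = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            s[i, j] = s[j, i] = x[i, j] - mu - g[i] - g[j]
    return mu, g, s


class TestEntryMeans:
    def test_constant_table(self):
        parents = ["A", "B", "C"]
        plots = plots_from_means(np.full((3, 3), 7.0), parents)
        x = entry_means(plots, "trait")
        assert np.allclose(x.x, 7.0)
        assert x.b == 2

    def test_two_blocks_average(self):
        parents = ["A", "B", "C"]
        v = np.arange(9.0).reshape(3, 3)
        v = (v + v.T) / 2
        plots = plots_from_means(v, parents, blocks=2, block_shift=[-1.0, 1.0])
        x = entry_means(plots, "trait")
        assert np.allclose(x.x, v)

    def test_matches_groupby_oracle(self, design5, plots5):
        x = entry_means(plots5, "trait", design5)
        grouped = plots5.groupby(["parent_a", "parent_b"])["value"].mean()
        for (a, b), v in grouped.items():
            i, j = design5.index_of(a), design5.index_of(b)
            assert x.x[i, j] == pytest.approx(v)
            assert x.x[j, i] == pytest.approx(v)

    def test_missing_cell_is_an_error_listing_the_cell(self, plots5):
        broken = plots5.drop(plots5.index[3])
        with pytest.raises(ValueError, match="missing plots"):
            entry_means(broken, "trait")


class TestAnova:
    def test_degrees_of_freedom_for_ten_parent_three_block_design(self, design10):
        params = TruthParams(mu=10, sigma2_g=1, sigma2_s=1, sigma2_block=0.1,
                             sigma2_e=1)
        plots = simulate_diallel(design10, params, seed=3)
        anova = griffing_anova(plots, "trait", design10)
        assert anova.loc["gca", "df"] == 9
        assert anova.loc["sca", "df"] == 45
        assert anova.loc["error", "df"] == 108
        assert anova.loc["block", "df"] == 2
        assert anova.loc["genotype", "df"] == 54

    def test_zero_variance_data_all_ss_zero_f_undefined(self, design5):
        params = TruthParams(mu=10, sigma2_g=0, sigma2_s=0, sigma2_block=0,
                             sigma2_e=0)
        plots = simulate_diallel(design5, params, seed=0)
        anova = griffing_anova(plots, "trait", design5)
        assert np.allclose(anova["ss"], 0.0)
        assert np.isnan(anova.loc["gca", "F"])
        assert np.isnan(anova.loc["sca", "F"])

    def test_partition_matches_sequential_ols_oracle(self):
        rng = np.random.default_rng(5)
        parents = ["A", "B", "C", "D"]
        x = rng.normal(10, 3, size=(4, 4))
        x = (x + x.T) / 2
        plots = plots_from_means(x, parents, blocks=2, block_shift=[-0.5, 0.5])
        anova = griffing_anova(plots, "trait")
        ss_gca, ss_sca = ols_oracle(x, b=2)
        assert anova.loc["gca", "ss"] == pytest.approx(ss_gca)
        assert anova.loc["sca", "ss"] == pytest.approx(ss_sca)
        assert (anova.loc["genotype", "ss"]
                == pytest.approx(ss_gca + ss_sca, rel=1e-10))

    def test_genotype_ms_is_df_weighted_combination(self, plots5, design5):
        anova = griffing_anova(plots5, "trait", design5)
        combined = ((anova.loc["gca", "df"] * anova.loc["gca", "ms"]
                     + anova.loc["sca", "df"] * anova.loc["sca", "ms"])
                    / anova.loc["genotype", "df"])
        assert anova.loc["genotype", "ms"] == pytest.approx(combined, rel=1e-10)

    def test_too_few_parents_rejected(self):
        plots = plots_from_means(np.array([[1.0, 2.0], [2.0, 3.0]]), ["A", "B"])
        with pytest.raises(ValueError, match="SCA stratum"):
            griffing_anova(plots, "trait")


class TestCombiningAbilities:
    def test_all_equal_means_give_zero_effects(self):
        plots = plots_from_means(np.full((4, 4), 3.5), list("ABCD"))
        x = entry_means(plots, "trait")
        res = combining_abilities(x, ms_error=1.0)
        assert np.allclose(res.gca, 0.0)
        assert np.allclose(res.sca, 0.0)
        assert res.mu_hat == pytest.approx(3.5)

    @pytest.mark.parametrize("p, seed", [(3, 0), (5, 1), (8, 2)])
    def test_matches_constrained_least_squares_oracle(self, p, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(20, 4, size=(p, p))
        x = (x + x.T) / 2
        parents = [f"P{i}" for i in range(p)]
        plots = plots_from_means(x, parents)
        xm = entry_means(plots, "trait")
        res = combining_abilities(xm, ms_error=1.0)
        mu, g, s = constrained_ls_oracle(x)
        assert res.mu_hat == pytest.approx(mu)
        assert np.allclose(res.gca.to_numpy(), g)
        assert np.allclose(res.sca.to_numpy(), s)

    def test_saturated_fit_and_sum_zero(self, design5, plots5):
        x = entry_means(plots5, "trait", design5)
        res = combining_abilities(x, ms_error=1.0)
        assert res.gca.sum() == pytest.approx(0.0, abs=1e-10)
        assert np.abs(res.fitted().to_numpy() - x.x).max() < 1e-10

    def test_gca_standard_error_closed_form(self, design5, plots5):
        # Var(g_i) = (p-1)/(p(p+2)) * MS_error / b for every parent
        anova = griffing_anova(plots5, "trait", design5)
        x = entry_means(plots5, "trait", design5)
        ms_error = anova.loc["error", "ms"]
        res = combining_abilities(x, ms_error)
        p, b = x.p, x.b
        expected = np.sqrt((p - 1) / (p * (p + 2)) * ms_error / b)
        assert np.allclose(res.gca_se, expected)

    def test_permutation_equivariance(self, design5, plots5):
        perm = {"P1": "P3", "P2": "P5", "P3": "P1", "P4": "P2", "P5": "P4"}
        relabelled = plots5.assign(parent_a=plots5["parent_a"].map(perm),
                                   parent_b=plots5["parent_b"].map(perm))
        res = combining_abilities(entry_means(plots5, "trait"), 1.0)
        res2 = combining_abilities(entry_means(relabelled, "trait"), 1.0)
        for old, new in perm.items():
            assert res2.gca[new] == pytest.approx(res.gca[old])
        for a_old, a_new in perm.items():
            for b_old, b_new in perm.items():
                assert (res2.sca.loc[a_new, b_new]
                        == pytest.approx(res.sca.loc[a_old, b_old]))

    def test_negative_ms_error_rejected(self, design5, plots5):
        x = entry_means(plots5, "trait", design5)
        with pytest.raises(ValueError):
            combining_abilities(x, ms_error=-1.0)


class TestBakerRatio:
    def test_pure_additivity_gives_one(self):
        assert baker_ratio(5.0, 0.0) == 1.0

    def test_both_zero_undefined(self):
        assert np.isnan(baker_ratio(0.0, 0.0))

    def test_increases_with_gca_variance(self, design10):
        ratios = []
        for s2g in (0.5, 2.0, 8.0):
            params = TruthParams(mu=10, sigma2_g=s2g, sigma2_s=1.0,
                                 sigma2_block=0.1, sigma2_e=1.0)
            plots = simulate_diallel(design10, params, seed=77)
            anova = griffing_anova(plots, "trait", design10)
            ratios.append(baker_ratio(anova.loc["gca", "ms"],
                                      anova.loc["sca", "ms"]))
        assert ratios == sorted(ratios)

    def test_varcomp_mode_differs_from_ms_mode(self):
        assert (baker_ratio(10.0, 4.0, mode="varcomp", p=10, b=3)
                != baker_ratio(10.0, 4.0))


class TestHeritabilities:
    def test_equal_mean_squares_give_zero_narrow_heritability(self):
        h2n, _ = heritabilities(1.0, 1.0, 1.0, p=10)
        assert h2n == 0.0

    def test_negative_component_truncated_with_warning(self):
        with pytest.warns(UserWarning):
            h2n, _ = heritabilities(0.5, 1.0, 1.0, p=10)
        assert h2n == 0.0

    def test_additive_dominated_case_has_high_narrow_heritability(self):
        # strong GCA, weak SCA, tiny error
        h2n, h2b = heritabilities(50.0, 2.0, 1.0, p=10)
        assert h2b >= h2n
        assert h2n > 0.7


class TestVarianceComponents:
    def test_mom_inverts_expected_mean_squares_exactly(self):
        # E[MS_error]=ve; E[MS_SCA]=ve+b*vs; E[MS_GCA]=ve+b*vs+b(p+2)*vg
        vg, vs, ve, p, b = 4.0, 1.0, 1.0, 10, 3
        ms_error = ve
        ms_sca = ve + b * vs
        ms_gca = ms_sca + b * (p + 2) * vg
        est = variance_components_mom(ms_gca, ms_sca, ms_error, p, b)
        assert est["sigma2_g"] == pytest.approx(vg)
        assert est["sigma2_s"] == pytest.approx(vs)
        assert est["sigma2_e"] == pytest.approx(ve)


class TestRelativeScaAndGroups:
    def test_relative_sca_scaling_and_sign(self):
        sca = pd.DataFrame([[0.0, 1.0], [1.0, -2.0]], index=list("AB"),
                           columns=list("AB"))
        rel = relative_sca(sca, 10.0)
        assert rel.loc["A", "B"] == pytest.approx(10.0)
        assert rel.loc["B", "B"] == pytest.approx(-20.0)
        with pytest.raises(ValueError):
            relative_sca(sca, 0.0)

    def test_group_summary_cv_and_equal_groups(self):
        parents = ["A", "B", "C"]
        x = np.array([[8.0, 8.0, 10.0],
                      [8.0, 10.0, 12.0],
                      [10.0, 12.0, 12.0]])
        plots = plots_from_means(x, parents)
        table = group_summary(plots, "trait")
        assert table.loc["parents", "mean"] == pytest.approx(10.0)
        assert table.loc["parents", "cv_pct"] == pytest.approx(20.0)
        # parent and hybrid means are the same multiset -> t = 0, p = 1
        assert table.attrs["t_p"] == pytest.approx(1.0)

    def test_group_shift_detected_by_t_test(self, design10):
        # hybrids boosted by a constant SCA-free offset via the truth matrix
        p = design10.p
        s = np.full((p, p), 3.0)
        np.fill_diagonal(s, 0.0)
        params = TruthParams(mu=10, sigma2_g=0.0, sigma2_s=0.0,
                             sigma2_block=0.0, sigma2_e=0.25,
                             g=np.zeros(p), s=s)
        plots = simulate_diallel(design10, params, seed=2)
        table = group_summary(plots, "trait", design10)
        assert table.attrs["t_p"] < 0.05
        assert table.loc["hybrids", "mean"] > table.loc["parents", "mean"]
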