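import numpy as np
import pandas as pd
import pytest

import gxetools as g
from gxetools.data import ValidationError


def _df(anova, term):
    return int(anova[term]["df"])


class TestDegreesOfFreedom:
    """Structural DF identities that hold on any complete I x J table."""

    @pytest.mark.parametrize("i,j", [(5, 4), (12, 5), (211, 8)])
    def test_additive(self, random_table, i, j):
        anova = g.fit_additive(random_table(i, j))
        assert _df(anova, "E") == j - 1
        assert _df(anova, "G") == i - 1
        assert _df(anova, "residual") == (i - 1) * (j - 1)
        assert _df(anova, "total") == i * j - 1

    @pytest.mark.parametrize("i,j", [(5, 4), (211, 8)])
    def test_finlay_wilkinson_split(self, random_table, i, j):
        anova = g.fit_finlay_wilkinson(random_table(i, j)).anova
        assert _df(anova, "heterogeneity") == i - 1
        assert _df(anova, "residual") == (i - 1) * (j - 2)

    @pytest.mark.parametrize("i,j,k", [(12, 5, 2), (211, 8, 2)])
    def test_ammi_gollob(self, random_table, i, j, k):
        fit = g.fit_ammi(random_table(i, j), k)
        for axis in range(k):
            assert fit.axis_df[axis] == i + j - 1 - 2 * (axis + 1)
        assert fit.residual_df == (i - 1) * (j - 1) - fit.axis_df.sum()

    def test_factorial(self, random_table):
        i, j = 211, 8
        table = random_table(i, j)
        rng = np.random.default_rng(1)
        covs = g.EnvCovariates(
            pd.DataFrame(rng.normal(size=(j, 2)), index=table.environments,
                         columns=["minTF", "radiationGF"])
        ).center()
        anova = g.fit_factorial_regression(table, covs).anova
        assert _df(anova, "G.minTF") == i - 1
        assert _df(anova, "G.radiationGF") == i - 1
        assert _df(anova, "residual") == (i - 1) * (j - 1 - 2)


class TestAdditive:
    def test_exactly_additive_has_zero_residual(self, additive_table):
        anova = g.fit_additive(additive_table)
        assert anova["residual"]["ss"] == pytest.approx(0.0, abs=1e-12)

    def test_ss_match_marginal_mean_loop_oracle(self, random_table):
        table = random_table(6, 4, seed=9)
        y = table.values()
        grand = y.mean()
        ss_e = sum(
            6 * (y[:, j].mean() - grand) ** 2 for j in range(4)
        )
        ss_g = sum(
            4 * (y[i, :].mean() - grand) ** 2 for i in range(6)
        )
        anova = g.fit_additive(table)
        assert anova["E"]["ss"] == pytest.approx(ss_e, rel=1e-10)
        assert anova["G"]["ss"] == pytest.approx(ss_g, rel=1e-10)
        # MS = SS / DF and components sum to the total
        rows = anova.to_frame()
        body = rows[rows["term"] != "total"]
        assert np.allclose(body["ms"], body["ss"] / body["df"])
        assert body["ss"].sum() == pytest.approx(anova["total"]["ss"], rel=1e-10)

    def test_effects_sum_to_zero(self, random_table):
        mu, gi, ej = g.additive_effects(random_table(8, 5))
        assert abs(gi.sum()) < 1e-10
        assert abs(ej.sum()) < 1e-10


class TestFinlayWilkinson:
    def test_recovers_constructed_slopes_exactly(self):
        rng = np.random.default_rng(4)
        i, j = 9, 6
        gi = rng.normal(size=i)
        ej = rng.normal(size=j)
        ej -= ej.mean()
        bprime = 1.0 + rng.normal(scale=0.3, size=i)
        bprime += 1.0 - bprime.mean()  # exact mean 1
        y = 3.0 + gi[:, None] + np.outer(bprime, ej)
        table = g.GxETable(
            pd.DataFrame(y, index=[f"g{k}" for k in range(i)],
                         columns=[f"e{k}" for k in range(j)])
        )
        fit = g.fit_finlay_wilkinson(table)
        assert np.allclose(fit.slopes_prime.to_numpy(), bprime, atol=1e-9)
        assert fit.anova["residual"]["ss"] == pytest.approx(0.0, abs=1e-9)

    def test_slope_constraints_on_balanced_data(self, random_table):
        fit = g.fit_finlay_wilkinson(random_table(15, 6, seed=2))
        assert fit.slopes_prime.mean() == pytest.approx(1.0, abs=1e-8)
        assert fit.slopes.sum() == pytest.approx(0.0, abs=1e-8)

    def test_ss_split_matches_per_genotype_regressions(self, random_table):
        table = random_table(10, 5, seed=7)
        fit = g.fit_finlay_wilkinson(table)
        y = table.values()
        e = fit.env_index.to_numpy()
        # per-row least squares of (y_ij - rowmean) on e
        ss_het, ss_res = 0.0, 0.0
        for i in range(10):
            resid = y[i] - y[i].mean()
            b = resid @ e / (e @ e)
            ss_het += (b - 1.0) ** 2 * (e @ e)
            ss_res += float(np.sum((resid - b * e) ** 2))
        assert fit.anova["heterogeneity"]["ss"] == pytest.approx(ss_het, rel=1e-10)
        assert fit.anova["residual"]["ss"] == pytest.approx(ss_res, rel=1e-10)
        # interaction SS of the additive model splits exactly
        add = g.fit_additive(table)
        assert add["residual"]["ss"] == pytest.approx(ss_het + ss_res, rel=1e-10)

    def test_zero_environment_variance_errors(self):
        y = np.outer(np.arange(4.0), np.ones(4)) + 1.0
        table = g.GxETable(
            pd.DataFrame(y, index=list("abcd"), columns=list("wxyz"))
        )
        with pytest.raises(ValidationError, match="slopes"):
            g.fit_finlay_wilkinson(table)


class TestBilinear:
    def test_rank_one_interaction_on_first_axis(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        u -= u.mean()
        v -= v.mean()
        y = 2.0 + np.outer(u, v)
        table = g.GxETable(
            pd.DataFrame(y, index=[f"g{k}" for k in range(8)],
                         columns=[f"e{k}" for k in range(5)])
        )
        fit = g.fit_ammi(table, 2)
        total_int = fit.axis_ss.sum() + fit.residual_ss
        assert fit.axis_ss[0] == pytest.approx(total_int, rel=1e-10)
        assert fit.axis_ss[1] == pytest.approx(0.0, abs=1e-16)

    def test_axis_ss_match_eigen_oracle(self, random_table):
        table = random_table(10, 6, seed=13)
        fit = g.fit_ammi(table, 4)
        centered = g.two_way_center(table).to_numpy()
        eig = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
        assert np.allclose(fit.axis_ss, eig[:4], rtol=1e-10)
        assert fit.singular_values[0] >= fit.singular_values[-1] >= 0
        # orthogonality of score vectors across axes
        gs = fit.gen_scores.to_numpy()
        assert np.allclose(gs.T @ gs, np.eye(4), atol=1e-10)

    def test_no_interaction_gives_zero_singular_values(self, additive_table):
        fit = g.fit_ammi(additive_table, 2)
        assert np.allclose(fit.singular_values, 0.0, atol=1e-10)

    def test_gge_identical_genotypes_have_no_signal(self):
        y = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (6, 1))
        table = g.GxETable(
            pd.DataFrame(y, index=[f"g{k}" for k in range(6)],
                         columns=list("wxyz"))
        )
        fit = g.fit_gge(table, 2)
        assert np.allclose(fit.singular_values, 0.0, atol=1e-10)
        assert np.allclose(fit.reconstruct().to_numpy(), 0.0, atol=1e-10)

    def test_gge_first_axis_at_least_ammi(self, random_table):
        for seed in range(5):
            table = random_table(9, 5, seed=seed)
            assert (
                g.fit_gge(table, 1).axis_ss[0]
                >= g.fit_ammi(table, 1).axis_ss[0] - 1e-10
            )

    def test_full_rank_reconstruction(self, random_table):
        table = random_table(7, 5, seed=21)
        fit = g.fit_gge(table, 5)
        y = table.values()
        centered = y - y.mean(axis=0, keepdims=True)
        assert np.allclose(fit.reconstruct().to_numpy(), centered, atol=1e-9)

    def test_k_too_large_errors(self, random_table):
        with pytest.raises(ValidationError, match="K"):
            g.fit_ammi(random_table(6, 4), 4)


class TestBiplot:
    def test_inner_product_identity(self, random_table):
        table = random_table(8, 6, seed=17)
        fit = g.fit_ammi(table, 3)
        for scaling in ("symmetric", "genotype", "environment"):
            gc, ec, _ = g.biplot_coords(fit, scaling)
            inner = gc.to_numpy() @ ec.to_numpy().T
            assert np.allclose(inner, fit.reconstruct(2).to_numpy(), atol=1e-8)

    def test_positive_projection_means_positive_interaction(self, random_table):
        table = random_table(10, 5, seed=23)
        fit = g.fit_ammi(table, 2)
        gc, ec, edir = g.biplot_coords(fit)
        rank2 = fit.reconstruct(2).to_numpy()
        proj = gc.to_numpy() @ edir.to_numpy().T
        scale = np.linalg.norm(ec.to_numpy(), axis=1)
        assert np.allclose(np.sign(proj * scale), np.sign(rank2))

    def test_env_axis_angle_equals_rank2_correlation(self, random_table):
        table = random_table(12, 5, seed=29)
        fit = g.fit_ammi(table, 2)
        _, ec, _ = g.biplot_coords(fit, "environment")  # gamma=0: env carry lambda
        rank2 = fit.reconstruct(2).to_numpy()
        e = ec.to_numpy()
        for a, b in [(0, 1), (1, 3), (2, 4)]:
            cosang = e[a] @ e[b] / (np.linalg.norm(e[a]) * np.linalg.norm(e[b]))
            ra, rb = rank2[:, a], rank2[:, b]
            corr = ra @ rb / np.sqrt((ra @ ra) * (rb @ rb))
            assert cosang == pytest.approx(corr, abs=1e-8)

    def test_needs_two_axes(self, random_table):
        fit = g.fit_ammi(random_table(6, 4), 1)
        with pytest.raises(ValidationError):
            g.biplot_coords(fit)


class TestFactorialRegression:
    def test_env_index_covariate_reproduces_fw_heterogeneity(self, random_table):
        table = random_table(10, 6, seed=31)
        idx = g.environment_index(table)
        covs = g.EnvCovariates(pd.DataFrame({"quality": idx}))
        fit = g.fit_factorial_regression(table, covs)
        fw = g.fit_finlay_wilkinson(table)
        assert fit.anova["G.quality"]["ss"] == pytest.approx(
            fw.anova["heterogeneity"]["ss"], rel=1e-10
        )

    def test_sequential_ss_match_incremental_lstsq_oracle(self, random_table):
        table = random_table(9, 6, seed=37)
        rng = np.random.default_rng(41)
        z = rng.normal(size=(6, 2))
        z -= z.mean(axis=0)
        covs = g.EnvCovariates(
            pd.DataFrame(z, index=table.environments, columns=["a", "b"])
        )
        fit = g.fit_factorial_regression(table, covs, order=["a", "b"])
        r = g.two_way_center(table).to_numpy().T  # J x I
        rss = [float(np.sum(r**2))]
        for k in (1, 2):
            beta, *_ = np.linalg.lstsq(z[:, :k], r, rcond=None)
            rss.append(float(np.sum((r - z[:, :k] @ beta) ** 2)))
        assert fit.anova["G.a"]["ss"] == pytest.approx(rss[0] - rss[1], rel=1e-9)
        assert fit.anova["G.b"]["ss"] == pytest.approx(rss[1] - rss[2], rel=1e-9)
        assert fit.anova["residual"]["ss"] == pytest.approx(rss[2], rel=1e-9)

    def test_collinear_covariate_named(self, random_table):
        table = random_table(8, 6)
        z = np.arange(6.0) - 2.5
        covs = g.EnvCovariates(
            pd.DataFrame({"a": z, "twice_a": 2 * z}, index=table.environments)
        )
        with pytest.raises(ValidationError, match="twice_a"):
            g.fit_factorial_regression(table, covs)
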