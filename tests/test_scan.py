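import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxetools as g
from gxetools.data import ValidationError
from gxetools.scan import ScanResult


def pipeline_inputs(spec):
    gmap, markers, table, truth = g.simulate_dataset(spec)
    grid = g.make_grid(gmap, 5.0)
    preds = g.genetic_predictors(markers, gmap, grid)
    return table, preds, truth


@pytest.fixture(scope="module")
def scanned(small_cross_spec=None):
    # module-scoped: one simulated crossover-QTL data set and its SIM scan
    import gxetools as g

    spec = g.SimulationSpec(
        population_type="F2",
        n_individuals=200,
        chromosomes=[g.ChromosomeSpec(f"C{c + 1}", 100.0, 11) for c in range(3)],
        qtls=[g.QTL("C1", 50.0, np.array([0.4] * 5 + [-0.3] * 3))],
        sigma2_G=0.3,
        residual=0.55,
        seed=42,
    )
    table, preds, truth = pipeline_inputs(spec)
    vspec = g.VarianceStructureSpec("cs")
    sim = g.sim_scan(table, preds, vspec, fit_dominance=True)
    return spec, table, preds, truth, vspec, sim


class TestScanStructure:
    def test_wald_df_bookkeeping(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        j = table.n_environments
        assert (sim.profile["df"] == j).all()
        assert (sim.dom_profile["df"].dropna() == j).all()
        assert (sim.profile["neglog10p"] >= 0).all()

    def test_cim_with_no_cofactors_equals_sim_exactly(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        cim = g.cim_scan(table, preds, [], vspec, sigma=sim.sigma)
        sim2 = g.sim_scan(table, preds, vspec, sigma=sim.sigma)
        assert (cim.profile["wald"] == sim2.profile["wald"]).all()
        assert np.array_equal(cim.effects.to_numpy(), sim2.effects.to_numpy())

    def test_same_chromosome_cofactor_is_inert(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        # a cofactor on C1 is excluded at every C1 position under the
        # restricted rule, so the C1 part of the profile is unchanged
        cim = g.cim_scan(table, preds, [("C1", 50.0)], vspec, sigma=sim.sigma)
        on_c1 = sim.profile["chromosome"] == "C1"
        assert np.allclose(
            cim.profile.loc[on_c1, "wald"], sim.profile.loc[on_c1, "wald"]
        )
        # but it does change the other chromosomes (background absorbed)
        assert not np.allclose(
            cim.profile.loc[~on_c1, "wald"], sim.profile.loc[~on_c1, "wald"]
        )

    def test_window_restriction(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        cim = g.cim_scan(
            table, preds, [("C1", 50.0)], vspec, restriction=("window", 20.0),
            sigma=sim.sigma,
        )
        prof = cim.profile.set_index(["chromosome", "position_cM"])
        simprof = sim.profile.set_index(["chromosome", "position_cM"])
        # inside the window the cofactor is dropped: identical to SIM
        assert prof.loc[("C1", 40.0), "wald"] == pytest.approx(
            simprof.loc[("C1", 40.0), "wald"]
        )
        # far away the cofactor stays in the model
        assert prof.loc[("C1", 0.0), "wald"] != pytest.approx(
            simprof.loc[("C1", 0.0), "wald"]
        )

    def test_peak_near_true_qtl(self, scanned):
        spec, *_ , sim = scanned
        chrom, pos = sim.peak()
        assert chrom == "C1"
        assert abs(pos - 50.0) <= 10.0

    def test_monomorphic_position_skipped(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        x = preds.x_add.copy()
        x.iloc[:, 0] = 1.0  # make the first position monomorphic
        broken = g.PredictorSet(
            positions=preds.positions, probs=preds.probs, x_add=x,
            x_dom=preds.x_dom, population_type=preds.population_type,
        )
        res = g.sim_scan(table, broken, vspec, sigma=sim.sigma)
        assert len(res.profile) == len(preds.positions) - 1
        assert res.skipped and res.skipped[0][2] == "monomorphic predictor"


class TestThresholds:
    def test_bonferroni_and_liji_ordering(self, scanned):
        *_, sim = scanned
        bon = g.significance_threshold(sim, "bonferroni", 0.05)
        lj = g.significance_threshold(sim, "li-ji", 0.05)
        n, n_star = sim.threshold["n"], sim.threshold["n_star"]
        assert bon == pytest.approx(0.05 / n)
        assert lj == pytest.approx(0.05 / n_star)
        assert 1.0 <= n_star <= n
        assert bon <= lj

    def test_identical_columns_one_effective_test(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        x = preds.x_add.copy()
        for c in x.columns:
            x[c] = x.iloc[:, 0]
        clone = ScanResult(
            profile=sim.profile, effects=sim.effects, std_errors=sim.std_errors,
            dom_profile=None, dom_effects=None, cofactors=[], restriction=None,
            skipped=[], x_add_tested=x[sim.x_add_tested.columns],
            sigma=sim.sigma, spec=vspec,
        )
        cutoff = g.significance_threshold(clone, "li-ji", 0.05)
        assert clone.threshold["n_star"] == pytest.approx(1.0, abs=1e-8)
        assert cutoff == pytest.approx(0.05)

    def test_too_few_positions(self, scanned):
        *_, sim = scanned
        short = ScanResult(
            profile=sim.profile.iloc[:1], effects=sim.effects.iloc[:1],
            std_errors=sim.std_errors.iloc[:1], dom_profile=None,
            dom_effects=None, cofactors=[], restriction=None, skipped=[],
            x_add_tested=sim.x_add_tested.iloc[:, :1], sigma=sim.sigma,
            spec=sim.spec,
        )
        with pytest.raises(ValidationError):
            g.significance_threshold(short, "bonferroni", 0.05)


class TestCofactorSelection:
    def _result_from_profile(self, rows, scanned):
        *_, sim = scanned
        profile = pd.DataFrame(
            rows, columns=["chromosome", "position_cM", "p"]
        )
        profile["wald"] = 1.0
        profile["df"] = 8
        profile["neglog10p"] = -np.log10(profile["p"])
        return ScanResult(
            profile=profile, effects=sim.effects, std_errors=sim.std_errors,
            dom_profile=None, dom_effects=None, cofactors=[], restriction=None,
            skipped=[], x_add_tested=sim.x_add_tested, sigma=sim.sigma,
            spec=sim.spec,
        )

    def test_nothing_above_cutoff_empty(self, scanned):
        res = self._result_from_profile(
            [("C1", 0.0, 0.5), ("C1", 10.0, 0.2), ("C2", 0.0, 0.9)], scanned
        )
        assert g.select_cofactors(res, cutoff=1e-4) == []

    def test_close_peaks_keep_stronger(self, scanned):
        res = self._result_from_profile(
            [("C1", 0.0, 0.5), ("C1", 45.0, 1e-6), ("C1", 50.0, 1e-9),
             ("C1", 55.0, 0.5)],
            scanned,
        )
        assert g.select_cofactors(res, cutoff=1e-3, min_separation=30.0) == [
            ("C1", 50.0)
        ]

    def test_matches_brute_force_greedy_oracle(self, scanned):
        rng = np.random.default_rng(0)
        rows = []
        for chrom in ("C1", "C2"):
            for pos in np.arange(0.0, 101.0, 10.0):
                rows.append((chrom, float(pos), float(10 ** -(3 * rng.random()))))
        res = self._result_from_profile(rows, scanned)
        got = g.select_cofactors(res, cutoff=0.05, min_separation=25.0)

        # independent re-implementation of the documented rule
        prof = res.profile
        cands = []
        for chrom in ("C1", "C2"):
            sub = prof[prof["chromosome"] == chrom].reset_index(drop=True)
            for k in range(len(sub)):
                if sub.loc[k, "p"] > 0.05:
                    continue
                v = sub["neglog10p"]
                if (k == 0 or v[k] >= v[k - 1]) and (
                    k == len(sub) - 1 or v[k] >= v[k + 1]
                ):
                    cands.append((v[k], chrom, sub.loc[k, "position_cM"]))
        cands.sort(reverse=True)
        kept = []
        for _, chrom, pos in cands:
            if all(c != chrom or abs(p - pos) >= 25.0 for c, p in kept):
                kept.append((chrom, pos))
        assert got == sorted(kept, key=str)


class TestMultiQTL:
    def test_single_candidate_matches_direct_scan_fit(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        peak = sim.peak()
        final = g.fit_multi_qtl(table, preds, [peak], vspec, sigma=sim.sigma)
        label = final.qtl_label(peak)
        assert np.allclose(
            final.effects.loc[label].to_numpy(),
            sim.effects.loc[label].to_numpy(),
            atol=1e-10,
        )
        assert final.qtls == [peak]

    def test_spurious_candidates_dropped(self, scanned):
        spec, table, preds, truth, vspec, sim = scanned
        candidates = [("C1", 50.0), ("C2", 30.0), ("C3", 70.0)]
        final = g.fit_multi_qtl(
            table, preds, candidates, vspec, drop_alpha=0.05, sigma=sim.sigma
        )
        assert ("C1", 50.0) in final.qtls
        assert len(final.qtls) < 3

    def test_significance_flags_follow_two_se_rule(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        final = g.fit_multi_qtl(table, preds, [sim.peak()], vspec, sigma=sim.sigma)
        expected = final.effects.abs() > 2 * final.std_errors
        pd.testing.assert_frame_equal(final.significant, expected)

    def test_effect_partition_identity_and_df(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        final = g.fit_multi_qtl(table, preds, [sim.peak()], vspec, sigma=sim.sigma)
        part = g.partition_qei(final, final.qtls[0])
        j = table.n_environments
        assert part.wald_main[1] == 1
        assert part.wald_qei[1] == j - 1
        # alpha_j = alpha_main + alpha_qei_j exactly
        label = final.qtl_label(final.qtls[0])
        recon = part.alpha_main + part.alpha_qei
        assert np.allclose(recon, final.effects.loc[label], atol=1e-8)
        # crossover truth: QEI strongly significant
        assert part.wald_qei[2] < 1e-6

    def test_empty_candidates_error(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        with pytest.raises(ValidationError):
            g.fit_multi_qtl(table, preds, [], vspec, sigma=sim.sigma)


class TestNullCalibration:
    def test_wald_p_roughly_uniform_under_null(self):
        # widely spaced positions on separate chromosomes are nearly
        # independent; pool P values over several null simulations
        pvals = []
        for seed in range(15):
            spec = g.SimulationSpec(
                n_individuals=300,
                chromosomes=[g.ChromosomeSpec(f"C{c}", 40.0, 2) for c in range(4)],
                qtls=[], sigma2_G=0.3, residual=0.55, seed=1000 + seed,
            )
            gmap, markers, table, _ = g.simulate_dataset(spec)
            preds = g.genetic_predictors(markers, gmap, g.make_grid(gmap, 40.0))
            res = g.sim_scan(table, preds, g.VarianceStructureSpec("cs"))
            pvals.extend(res.profile["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestCovariateModel:
    def test_exact_linear_effects_recovered(self):
        z = np.array([-3.0, -2.0, -1.0, 0.0, 0.0, 1.0, 2.0, 3.0])
        alpha, beta = 0.25, -0.1
        spec = g.SimulationSpec(
            n_individuals=250,
            chromosomes=[g.ChromosomeSpec("C1", 80.0, 9)],
            qtls=[g.QTL("C1", 40.0, (alpha, beta, z))],
            sigma2_G=0.0, residual=1e-12, seed=5,
        )
        table, preds, truth = pipeline_inputs(spec)
        vspec = g.VarianceStructureSpec("cs")
        sigma = pd.DataFrame(
            np.eye(8) * 1e-6, index=table.environments, columns=table.environments
        )
        final = g.fit_multi_qtl(table, preds, [("C1", 40.0)], vspec, sigma=sigma)
        zc = pd.Series(z, index=table.environments, name="covar")
        fit = g.qtl_covariate_model(table, preds, final, ("C1", 40.0), zc)
        assert fit.beta_star == pytest.approx(beta, abs=1e-6)
        assert fit.alpha_star == pytest.approx(alpha, abs=1e-6)
        assert fit.sigma2_a == pytest.approx(0.0, abs=1e-6)
        # centered covariate: fitted effects average to alpha*
        assert fit.env_effects.mean() == pytest.approx(fit.alpha_star, abs=1e-10)

    def test_noisy_slope_recovery_within_three_se(self):
        z = np.linspace(-4, 4, 8)
        spec = g.SimulationSpec(
            n_individuals=300,
            chromosomes=[g.ChromosomeSpec("C1", 80.0, 9)],
            qtls=[g.QTL("C1", 40.0, (0.2, -0.04, z))],
            sigma2_G=0.2, residual=0.4, seed=11,
        )
        table, preds, _ = pipeline_inputs(spec)
        vspec = g.VarianceStructureSpec("cs")
        final = g.fit_multi_qtl(table, preds, [("C1", 40.0)], vspec)
        zc = pd.Series(z, index=table.environments, name="covar")
        fit = g.qtl_covariate_model(table, preds, final, ("C1", 40.0), zc)
        assert abs(fit.beta_star - (-0.04)) < 3 * fit.se_beta

    def test_recentering_shifts_only_intercept(self):
        z = np.linspace(-4, 4, 8)
        spec = g.SimulationSpec(
            n_individuals=150,
            chromosomes=[g.ChromosomeSpec("C1", 80.0, 9)],
            qtls=[g.QTL("C1", 40.0, (0.2, -0.05, z))],
            sigma2_G=0.2, residual=0.4, seed=13,
        )
        table, preds, _ = pipeline_inputs(spec)
        final = g.fit_multi_qtl(
            table, preds, [("C1", 40.0)], g.VarianceStructureSpec("cs")
        )
        zc = pd.Series(z, index=table.environments, name="covar")
        fit0 = g.qtl_covariate_model(table, preds, final, ("C1", 40.0), zc)
        with pytest.warns(UserWarning, match="not centered"):
            fit1 = g.qtl_covariate_model(
                table, preds, final, ("C1", 40.0), zc + 2.0
            )
        assert fit1.beta_star == pytest.approx(fit0.beta_star, abs=1e-6)
        assert fit1.alpha_star == pytest.approx(
            fit0.alpha_star - 2.0 * fit0.beta_star, abs=1e-5
        )

    def test_constant_covariate_errors(self, scanned):
        _, table, preds, _, vspec, sim = scanned
        final = g.fit_multi_qtl(table, preds, [sim.peak()], vspec, sigma=sim.sigma)
        zc = pd.Series(np.zeros(8), index=table.environments, name="flat")
        with pytest.raises(ValidationError, match="constant"):
            g.qtl_covariate_model(table, preds, final, sim.peak(), zc)
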