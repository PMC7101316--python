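"""Simulator: ZTNB estimation, dropout surface, truth assignment, DE stage."""

import numpy as np
import pytest
from scipy import stats as sps

from ssgse.gse import genomic_control_lambda
from ssgse.simulate import (
    DropoutModel,
    assign_truth,
    ave_log_cpm,
    fit_dropout_model,
    internal_de_test,
    reference_free_params,
    simulate_counts,
    simulate_summary_stats,
    ztnb_mom_estimate,
)


class TestZtnbEstimation:
    def test_parameter_recovery_on_truncated_nb(self):
        # NB counts with zeros discarded: the truncation-corrected moments
        # recover (lambda, phi) reasonably
        lam_true, phi_true, n_cells = 1e-3, 2.0, 500
        errs_lam, errs_phi = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            depths = np.full(n_cells, 5000.0)
            mu = lam_true * depths
            y = rng.negative_binomial(phi_true, phi_true / (phi_true + mu))
            est = ztnb_mom_estimate(y[None, :].astype(float), depths)
            errs_lam.append(est.lambda_[0] / lam_true - 1)
            errs_phi.append(est.phi[0] / phi_true - 1)
        assert abs(np.mean(errs_lam)) < 0.15
        assert abs(np.mean(errs_phi)) < 0.15

    def test_low_dispersion_limit(self):
        depths = np.full(100, 1000.0)
        counts = np.full((1, 100), 50.0)  # constant, truncation negligible
        est = ztnb_mom_estimate(counts, depths)
        assert est.lambda_[0] == pytest.approx(0.05, rel=0.05)
        assert est.phi[0] > 100  # effectively Poisson

    def test_too_few_nonzeros_excluded(self):
        depths = np.full(10, 100.0)
        counts = np.zeros((1, 10)); counts[0, 0] = 5
        est = ztnb_mom_estimate(counts, depths, min_nonzero=3)
        assert est.excluded[0]
        assert np.isnan(est.lambda_[0])


class TestDropoutModel:
    def _zeroinflated_counts(self, rng, n_genes=300, n_cells=80):
        params, dropout, depths = reference_free_params(n_genes, n_cells, rng)
        truth = assign_truth(n_genes, 0.1, -2.0, 0.0, effect_sd=0.0, rng=rng)
        counts, labels, depths = simulate_counts(params, dropout, truth,
                                                 (n_cells // 2, n_cells - n_cells // 2),
                                                 depths, rng)
        return counts, depths, dropout, params

    def test_recovers_known_logistic_surface(self, rng):
        counts, depths, dropout, params = self._zeroinflated_counts(rng)
        model = fit_dropout_model(counts, depths)
        A = ave_log_cpm(counts, depths)
        p_hat = model.predict(A, depths)
        p_true = dropout.predict(np.log2(params.lambda_ / params.lambda_.sum() * 1e6),
                                 depths)
        # NB zeros are part of what the fit sees, so compare against the
        # total zero probability of the generative process
        mu = params.lambda_[:, None] * depths[None, :]
        nb0 = (params.phi[:, None] / (params.phi[:, None] + mu)) ** params.phi[:, None]
        total0 = p_true + (1 - p_true) * nb0
        rmse = np.sqrt(np.mean((p_hat - total0) ** 2))
        assert rmse < 0.1

    def test_monotone_decreasing_in_expression(self, rng):
        counts, depths, _, _ = self._zeroinflated_counts(rng)
        model = fit_dropout_model(counts, depths)
        A_grid = np.linspace(0, 10, 25)
        p_grid = model.predict(A_grid, np.full(1, np.exp(model.logn_center)))
        assert p_grid[-1, 0] < p_grid[0, 0]

    def test_no_zeros_predicts_near_zero(self, rng):
        counts = rng.poisson(500, size=(60, 30)).astype(np.int64) + 1
        depths = counts.sum(axis=0).astype(float)
        model = fit_dropout_model(counts, depths)
        p = model.predict(ave_log_cpm(counts, depths), depths)
        assert p.max() <= 2e-6 + 1e-9
        assert model.flagged

    def test_predictions_in_open_interval(self, rng):
        counts, depths, _, _ = self._zeroinflated_counts(rng)
        model = fit_dropout_model(counts, depths)
        p = model.predict(ave_log_cpm(counts, depths), depths)
        assert np.all((p > 0) & (p < 1))


class TestAssignTruth:
    @pytest.mark.parametrize("tau0,expected", [(-2.0, 0.1192), (-3.0, 0.0474)])
    def test_de_fraction_matches_logistic_prior(self, tau0, expected):
        rng = np.random.default_rng(0)
        truth = assign_truth(50_000, 0.1, tau0, 0.0, rng=rng)
        assert truth.gamma_true.mean() == pytest.approx(expected, abs=0.006)

    def test_membership_count_and_zero_effect_mode(self, rng):
        truth = assign_truth(1000, 0.05, -2.0, 1.0, effect_sd=0.0, rng=rng)
        assert truth.a.sum() == 50
        np.testing.assert_array_equal(truth.fc, np.ones(1000))

    def test_enrichment_raises_in_set_de_rate(self):
        rng = np.random.default_rng(1)
        truth = assign_truth(50_000, 0.1, -2.0, 1.0, rng=rng)
        rate_in = truth.gamma_true[truth.a == 1].mean()
        rate_out = truth.gamma_true[truth.a == 0].mean()
        assert rate_in == pytest.approx(1 / (1 + np.exp(1.0)), abs=0.02)
        assert rate_out == pytest.approx(0.1192, abs=0.01)

    def test_beta_zero_iff_not_de(self, rng):
        truth = assign_truth(2000, 0.1, -1.0, 0.5, rng=rng)
        assert np.all((truth.beta_true == 0) == ~truth.gamma_true)
        np.testing.assert_allclose(truth.fc, np.exp(truth.beta_true))


class TestSimulateCounts:
    def test_null_groups_exchangeable(self):
        rng = np.random.default_rng(3)
        params, dropout, depths = reference_free_params(500, 60, rng)
        truth = assign_truth(500, 0.1, -2.0, 0.0, effect_sd=0.0, rng=rng)
        counts, labels, depths = simulate_counts(params, dropout, truth,
                                                 (30, 30), depths, rng)
        # two-sample t on CPM of a random subset of genes: uniform p-values
        cpm = counts / depths * 1e6
        ps = [sps.ttest_ind(cpm[j, labels == 1], cpm[j, labels == 0]).pvalue
              for j in range(0, 500, 10)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_moment_oracle_without_dropout(self):
        rng = np.random.default_rng(4)
        n_genes, n_cells = 2000, 400
        lam = np.full(n_genes, 1e-4)
        phi = np.full(n_genes, 1e6)       # effectively Poisson
        from ssgse.simulate import ZTNBGeneParams
        params = ZTNBGeneParams(lam, phi)
        depths = np.full(n_cells, 1e6)
        truth = assign_truth(n_genes, 0.1, -2.0, 0.0, effect_sd=0.0, rng=rng)
        counts, labels, _ = simulate_counts(params, None, truth,
                                            (200, 200), depths, rng)
        assert counts.mean() == pytest.approx(100.0, rel=0.02)

    def test_dropout_only_adds_zeros(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        params, dropout, depths = reference_free_params(300, 40, rng1)
        _params2, _d2, _dep2 = reference_free_params(300, 40, rng2)
        truth = assign_truth(300, 0.1, -2.0, 0.0, effect_sd=0.0,
                             rng=np.random.default_rng(6))
        c_with, _, _ = simulate_counts(params, dropout, truth, (20, 20), depths,
                                       np.random.default_rng(7))
        c_without, _, _ = simulate_counts(_params2, None, truth, (20, 20), _dep2,
                                          np.random.default_rng(7))
        assert (c_with == 0).mean() >= (c_without == 0).mean()


class TestInternalDeTest:
    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        params, dropout, depths = reference_free_params(10_000, 174, rng)
        truth = assign_truth(10_000, 0.1, -2.0, 0.0, effect_sd=0.0, rng=rng)
        counts, labels, depths = simulate_counts(params, dropout, truth,
                                                 (105, 69), depths, rng)
        stats_t = internal_de_test(counts, labels, depths)
        lam = genomic_control_lambda(stats_t.p)
        assert 0.85 <= lam <= 1.2

    def test_strong_fold_change_detected_with_sign(self):
        rng = np.random.default_rng(9)
        params, dropout, depths = reference_free_params(200, 80, rng)
        truth = assign_truth(200, 0.1, -2.0, 0.0, effect_sd=0.0, rng=rng)
        truth.beta_true[0] = 3.0
        truth.fc = np.exp(truth.beta_true)
        params.lambda_[0] = 1e-4  # solidly expressed
        counts, labels, depths = simulate_counts(params, dropout, truth,
                                                 (40, 40), depths, rng)
        stats_t = internal_de_test(counts, labels, depths)
        j = list(stats_t.gene_id).index("g00000")
        assert stats_t.z[j] > 5
        assert stats_t.beta_hat[j] == pytest.approx(3.0, abs=0.8)

    def test_all_zero_gene_excluded(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(5.0, size=(50, 20)).astype(np.int64)
        counts[7] = 0
        depths = counts.sum(axis=0).astype(float) + 1
        labels = np.array([1] * 10 + [0] * 10)
        stats_t = internal_de_test(counts, labels, depths)
        assert "g00007" not in set(stats_t.gene_id)

    def test_group_size_validation(self):
        counts = np.ones((10, 3))
        with pytest.raises(ValueError):
            internal_de_test(counts, np.array([1, 0, 0]), np.ones(3))


class TestSimulateSummaryStats:
    def test_null_z_standard_normal(self, rng):
        truth = assign_truth(10_000, 0.1, -25.0, 0.0, rng=rng)  # gamma ~ 0
        stats_t = simulate_summary_stats(truth, sigma_beta2=9.0, rng=rng)
        assert sps.kstest(stats_t.z, "norm").pvalue > 0.01

    def test_de_gene_variance_inflated(self, rng):
        truth = assign_truth(12_000, 0.1, 25.0, 0.0, rng=rng)  # gamma ~ 1
        stats_t = simulate_summary_stats(truth, sigma_beta2=9.0, rng=rng)
        assert np.var(stats_t.z) == pytest.approx(10.0, rel=0.05)

    def test_degenerate_slab_gives_standard_normal(self, rng):
        truth = assign_truth(10_000, 0.1, 25.0, 0.0, rng=rng)
        stats_t = simulate_summary_stats(truth, sigma_beta2=1e-12, rng=rng)
        assert sps.kstest(stats_t.z, "norm").pvalue > 0.01


class TestDeAgainstEdgeR:
    def test_log_fold_changes_match_edger_oracle(self, tmp_path):
        """Dropout-free NB counts: our Wald effect sizes track edgeR's."""
        import subprocess

        rng = np.random.default_rng(17)
        n_genes, n1, n2 = 150, 15, 15
        from ssgse.simulate import ZTNBGeneParams
        lam = np.exp(rng.normal(np.log(3e-4), 1.0, size=n_genes))
        phi = np.full(n_genes, 5.0)
        params = ZTNBGeneParams(lam, phi)
        truth = assign_truth(n_genes, 0.1, -2.0, 0.0, effect_sd=1.5, rng=rng)
        depths = np.exp(rng.normal(np.log(2e5), 0.2, size=n1 + n2))
        counts, labels, depths = simulate_counts(params, None, truth,
                                                 (n1, n2), depths, rng)
        ours = internal_de_test(counts, labels, depths)

        import pandas as pd
        cfile, out = tmp_path / "c.csv", tmp_path / "edger.csv"
        pd.DataFrame(counts).to_csv(cfile, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages(library(edgeR))
counts <- as.matrix(read.csv("{cfile}"))
group <- factor(c(rep(1, {n1}), rep(0, {n2})), levels=c(0, 1))
depths <- c({", ".join(f"{d:.6f}" for d in depths)})
y <- DGEList(counts=counts, group=group, lib.size=depths)
y <- estimateDisp(y, model.matrix(~group))
fit <- glmFit(y, model.matrix(~group))
res <- glmLRT(fit, coef=2)
write.csv(data.frame(logFC=res$table$logFC), "{out}", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        edger = pd.read_csv(out)["logFC"].to_numpy() * np.log(2.0)  # to ln
        kept = np.array([int(g[1:]) for g in ours.gene_id])
        r = np.corrcoef(ours.beta_hat, edger[kept])[0, 1]
        assert r > 0.95
        slope = np.polyfit(edger[kept], ours.beta_hat, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
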