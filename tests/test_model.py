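"""Repeated-measures model: oracles, recovery, LSMs and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rccpipe import (GeneExpressionModel, ModelSpec, StudyDesign,
                     contrast_vs_baseline, fit_all_genes, fit_gene)
from rccpipe.errors import EstimationError, InsufficientDataError
from rccpipe.simulate import default_design, SimConfig, \
    simulate_gaussian_linear


def ols_oracle(y, X):
    """Independent normal-equations solution."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    n, p = X.shape
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov


class TestGLSOracles:
    def test_independence_equals_ols(self):
        """At rho = 0 the GLS fit must equal ordinary least squares."""
        y, design = simulate_gaussian_linear(seed=3, rho=0.4)
        spec = ModelSpec(correlation="independence")
        model = GeneExpressionModel(y, design, spec)
        fit = model.fit()
        beta, cov = ols_oracle(model.endog, model.exog)
        assert np.allclose(fit.beta, beta, atol=1e-8)
        assert np.allclose(fit.cov_beta, cov, atol=1e-8)

    def test_vs_baseline_equals_paired_t(self):
        """One group, two time points: the AR1 GLS contrast collapses to a
        paired t-test (estimated correlation reproduces the difference SD).
        """
        rng = np.random.default_rng(42)
        n = 10
        rows, values = [], {}
        for i in range(n):
            a, b = rng.normal(50, 8), rng.normal(55, 8)
            for t, v in ((0.0, a), (4.0, b)):
                sid = f"A{i:02d}_t{t:g}"
                rows.append({"sample_id": sid, "animal_id": f"A{i:02d}",
                             "group": "control", "time_h": t})
                values[sid] = v
        design = StudyDesign(pd.DataFrame(rows))
        y = pd.Series(values)
        spec = ModelSpec(times_modeled=(4.0,))
        c = contrast_vs_baseline(y, design, spec, "control", 4.0)

        base = np.array([values[f"A{i:02d}_t0"] for i in range(n)])
        post = np.array([values[f"A{i:02d}_t4"] for i in range(n)])
        t_oracle, p_oracle = stats.ttest_rel(post, base)
        assert c.estimate == pytest.approx(float(np.mean(post - base)),
                                           abs=1e-8)
        assert abs(c.t) == pytest.approx(abs(t_oracle), abs=1e-6)
        assert c.df == n - 1
        assert c.p_value == pytest.approx(p_oracle, abs=1e-6)

    def test_balanced_two_way_cell_means_without_covariate(self):
        """With independence and no covariate, LSMs are the cell means."""
        y, design = simulate_gaussian_linear(seed=11, rho=0.0)
        spec = ModelSpec(baseline_as_covariate=False,
                         correlation="independence")
        fit = GeneExpressionModel(y, design, spec).fit()
        frame = design.rows.merge(y.rename("y"), left_on="sample_id",
                                  right_index=True)
        for _, row in fit.lsmeans().iterrows():
            cell = frame[(frame["group"] == row["group"])
                         & (frame["time_h"] == row["time_h"])]["y"]
            assert row["estimate"] == pytest.approx(cell.mean(), abs=1e-8)


class TestFitBehaviour:
    def test_reml_optimum_is_local_maximum(self):
        y, design = simulate_gaussian_linear(seed=5, rho=0.5)
        model = GeneExpressionModel(y, design, ModelSpec())
        fit = model.fit()
        for eps in (-0.05, 0.05):
            r = np.clip(fit.rho + eps, -0.98, 0.98)
            assert model._reml(r) <= fit.reml_loglik + 1e-9

    def test_rho_recovery_at_large_n(self):
        """Median AR1 estimate within +-0.1 of truth for 200 animals."""
        estimates = []
        for s in range(100):
            y, design = simulate_gaussian_linear(
                n_per_group=100, times=(0.0, 4.0, 8.0, 12.0), rho=0.6,
                seed=900 + s)
            fit = GeneExpressionModel(y, design, ModelSpec(
                times_modeled=(4.0, 8.0, 12.0))).fit()
            estimates.append(fit.rho)
        assert abs(np.median(estimates) - 0.6) < 0.1

    def test_identical_groups_give_zero_contrast(self):
        y, design = simulate_gaussian_linear(seed=21)
        # duplicate control responses onto the treatment animals
        mirrored = y.copy()
        for sid in y.index:
            if sid.startswith("T"):
                mirrored[sid] = y["C" + sid[1:]]
        fit = GeneExpressionModel(mirrored, design, ModelSpec()).fit()
        assert fit.contrast_between_groups(4.0).estimate == \
            pytest.approx(0.0, abs=1e-10)

    def test_missing_baseline_is_estimation_error(self):
        y, design = simulate_gaussian_linear(seed=2)
        keep = design.rows["sample_id"] != "C01_t0"
        design2 = StudyDesign(design.rows[keep])
        with pytest.raises(EstimationError, match="C01"):
            GeneExpressionModel(y[y.index != "C01_t0"], design2,
                                ModelSpec())

    def test_single_animal_group_rejected(self):
        y, design = simulate_gaussian_linear(n_per_group=2, seed=2)
        drop = design.rows["animal_id"] != "T02"
        with pytest.raises(EstimationError, match="fewer than 2"):
            GeneExpressionModel(
                y[[s for s in y.index if not s.startswith("T02")]],
                StudyDesign(design.rows[drop]), ModelSpec())

    def test_sample_order_invariance(self):
        y, design = simulate_gaussian_linear(seed=8, rho=0.3)
        fit1 = fit_gene(y, design)
        perm = y.sample(frac=1.0, random_state=1)
        design_perm = StudyDesign(
            design.rows.sample(frac=1.0, random_state=2))
        fit2 = fit_gene(perm, design_perm)
        assert np.allclose(fit1.beta, fit2.beta)
        assert fit1.rho == pytest.approx(fit2.rho, abs=1e-9)


class TestLSMeans:
    def test_structural_cell_count(self):
        y, design = simulate_gaussian_linear(seed=4)
        fit = fit_gene(y, design)
        lsm = fit.lsmeans()
        assert len(lsm) == 4  # 2 groups x 2 modeled times
        assert set(lsm["group"]) == {"control", "treatment"}

    def test_balanced_null_groups_close(self):
        y, design = simulate_gaussian_linear(seed=12, sigma=5.0)
        lsm = fit_gene(y, design).lsmeans()
        by_group = lsm.groupby("group")["estimate"].mean()
        assert abs(by_group["control"] - by_group["treatment"]) < 10.0


class TestPanelFit:
    def test_twelve_gene_panel(self, normalized, clean_runset):
        panel = fit_all_genes(normalized, clean_runset.design)
        assert len(panel.fits) == 12
        assert set(panel.contrasts["gene"]) == set(
            normalized.endogenous_genes)
        # per gene: 2 between-group + 2 groups x 2 times vs baseline
        assert len(panel.contrasts) == 12 * 6
        assert len(panel.lsmeans) == 12 * 6  # 2 groups x 3 times

    def test_constant_gene_flagged_not_dropped_silently(self, normalized,
                                                        clean_runset):
        from rccpipe.normalize import ExpressionMatrix
        values = normalized.values.copy()
        values.loc["IL6"] = 5.0
        m = ExpressionMatrix(values=values, stage="fully_normalized",
                             factors=normalized.factors,
                             endogenous_genes=normalized.endogenous_genes,
                             reference_genes=normalized.reference_genes)
        panel = fit_all_genes(m, clean_runset.design)
        assert "IL6" in panel.failed
        assert "degenerate" in panel.failed["IL6"]
        assert "IL6" not in set(panel.contrasts["gene"])

    def test_bh_adjustment_column(self, normalized, clean_runset):
        panel = fit_all_genes(normalized, clean_runset.design,
                              adjust="bh")
        assert "p_bh" in panel.contrasts
        assert (panel.contrasts["p_bh"] >= panel.contrasts["p"]
                - 1e-12).all()

    def test_summary_mentions_gene_and_rho(self, normalized, clean_runset):
        fit = fit_all_genes(normalized, clean_runset.design).fits["IL8"]
        text = fit.summary()
        assert "IL8" in text and "rho" in text


class TestResidualNormality:
    def test_gaussian_residuals_have_uniform_p(self):
        """Shapiro p-values approximately uniform under Gaussian errors."""
        ps = []
        for s in range(200):
            y, design = simulate_gaussian_linear(seed=5000 + s)
            ps.append(fit_gene(y, design).residual_normality()["shapiro_p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_skewed_residuals_detected(self):
        rng = np.random.default_rng(77)
        detected = 0
        reps = 50
        spec = ModelSpec(times_modeled=(0.0, 4.0, 24.0),
                         baseline_as_covariate=False)
        for s in range(reps):
            y, design = simulate_gaussian_linear(seed=6000 + s, sigma=1e-6,
                                                 baseline_sd=1e-6)
            noisy = y + pd.Series(rng.exponential(10.0, len(y)),
                                  index=y.index)
            r = fit_gene(noisy, design, spec).residual_normality()
            detected += r["shapiro_p"] < 0.05
        assert detected / reps > 0.8

    def test_constant_residuals_flagged(self):
        y, design = simulate_gaussian_linear(seed=1, sigma=0.0,
                                             baseline_sd=0.0)
        y = y + pd.Series(
            {s: (0.5 if s.endswith("t4") else 0.0) for s in y.index})
        # exact fit -> residuals constant (zero)
        with pytest.raises((InsufficientDataError, EstimationError)):
            fit_gene(y, design).residual_normality()
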