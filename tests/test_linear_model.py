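"""Voom weights, weighted fits, variance moderation and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dieldas.linear_model import (
    ModelError,
    benjamini_hochberg,
    build_design_matrix,
    contrast_stats,
    ebayes_moderate,
    estimate_prior,
    fit_wls,
    posterior_variances,
    voom_weights,
)
from dieldas.preprocess import NormFactors, tmm_factors
from dieldas.quant_io import counts_from_tpm
from dieldas.study_design import build_contrasts, build_default_design
from dieldas.synthetic_data import NoiseModel, generate_dataset, simulate_genes


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"f{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestDesignMatrix:
    def test_one_column_per_timepoint(self):
        d = build_default_design()
        x = build_design_matrix(d)
        assert x.shape == (78, 26)
        assert np.allclose(x.sum(axis=1), 1.0)

    def test_batch_factors_appended(self):
        d = build_default_design()
        bf = pd.DataFrame(
            {"ruv1": np.linspace(-1, 1, 78)}, index=d.sample_ids
        )
        x = build_design_matrix(d, bf)
        assert x.shape == (78, 27)

    def test_rank_deficiency_names_columns(self):
        d = build_default_design()
        bf = pd.DataFrame(
            {"dup": [1.0] * 78}, index=d.sample_ids
        )  # constant column == sum of indicators
        with pytest.raises(ModelError, match="rank deficient"):
            build_design_matrix(d, bf)


class TestVoom:
    def _simulated(self, dispersion=0.05):
        design = build_default_design()
        genes = simulate_genes({"null": 80}, seed=11)
        ds = generate_dataset(
            genes, design, NoiseModel(nb_dispersion=dispersion), seed=11
        )
        counts = counts_from_tpm(ds.quant_tables)
        norm = tmm_factors(counts)
        x = build_design_matrix(design)
        return counts, norm, x

    def test_weights_positive_and_finite(self):
        counts, norm, x = self._simulated()
        res = voom_weights(counts, norm, x)
        w = res.weights.to_numpy()
        assert (w > 0).all() and np.isfinite(w).all()

    def test_flat_variance_gives_flat_weights(self):
        # Gaussian log-counts: variance independent of the mean
        rng = np.random.default_rng(5)
        design = build_default_design()
        x = build_design_matrix(design)
        mu = rng.uniform(4, 12, size=200)
        y = 2.0 ** (mu[:, None] + rng.normal(0, 0.3, size=(200, 78)))
        counts = _frame(y)
        counts.columns = design.sample_ids
        norm = NormFactors(
            factors=pd.Series(1.0, index=design.sample_ids),
            lib_sizes=pd.Series(1e6, index=design.sample_ids),
        )
        res = voom_weights(counts, norm, x)
        w = res.weights.to_numpy()
        assert w.max() / w.min() < 2.0

    def test_doubling_counts_keeps_weight_rank_order(self):
        counts, norm, x = self._simulated()
        r1 = voom_weights(counts, norm, x)
        norm2 = NormFactors(
            factors=norm.factors, lib_sizes=norm.lib_sizes * 2
        )
        r2 = voom_weights(counts * 2, norm2, x)
        m1 = r1.weights.mean(axis=1)
        m2 = r2.weights.mean(axis=1)
        rho = stats.spearmanr(m1, m2).statistic
        assert rho > 0.95

    def test_too_few_features_is_an_error(self):
        counts, norm, x = self._simulated()
        with pytest.raises(ModelError, match="at least 10"):
            voom_weights(counts.iloc[:5], norm, x)


class TestFitWls:
    def test_intercept_only_recovers_mean(self):
        y = _frame([[1.0, 2.0, 3.0, 4.0]])
        w = _frame([[1.0, 1.0, 1.0, 1.0]])
        x = pd.DataFrame({"mu": [1.0] * 4}, index=y.columns)
        fit = fit_wls(y, w, x)
        assert fit.coefficients.loc["f0", "mu"] == pytest.approx(2.5)
        assert fit.df_residual == 3

    def test_doubled_weight_equals_duplicated_sample(self):
        rng = np.random.default_rng(2)
        yv = rng.normal(size=5)
        xv = np.column_stack([np.ones(5), rng.normal(size=5)])
        # weighted: sample 0 has weight 2
        y_w = _frame(yv[None, :])
        w_w = _frame(np.array([[2.0, 1.0, 1.0, 1.0, 1.0]]))
        x_w = pd.DataFrame(xv, index=y_w.columns, columns=["c0", "c1"])
        fit_weighted = fit_wls(y_w, w_w, x_w)
        # unweighted equivalent: sample 0 appears twice
        yd = np.concatenate([[yv[0]], yv])
        xd = np.vstack([xv[0], xv])
        y_d = _frame(yd[None, :])
        w_d = _frame(np.ones((1, 6)))
        x_d = pd.DataFrame(xd, index=y_d.columns, columns=["c0", "c1"])
        fit_dup = fit_wls(y_d, w_d, x_d)
        assert np.allclose(
            fit_weighted.coefficients.to_numpy(),
            fit_dup.coefficients.to_numpy(),
            atol=1e-10,
        )

    def test_zero_residual_data_gives_zero_sigma(self):
        y = _frame([[1.0, 1.0, 1.0]])
        w = _frame([[1.0, 1.0, 1.0]])
        x = pd.DataFrame({"mu": [1.0] * 3}, index=y.columns)
        fit = fit_wls(y, w, x)
        assert fit.sigma["f0"] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_weights_rejected(self):
        y = _frame([[1.0, 2.0]])
        w = _frame([[1.0, 0.0]])
        x = pd.DataFrame({"mu": [1.0] * 2}, index=y.columns)
        with pytest.raises(ModelError, match="positive"):
            fit_wls(y, w, x)


class TestEbayes:
    def test_limit_prior_df_zero_keeps_sample_variances(self):
        s2 = np.array([0.5, 1.0, 2.0])
        assert np.allclose(posterior_variances(s2, 10, 0.0, 3.0), s2)

    def test_limit_prior_df_infinite_collapses_to_prior(self):
        s2 = np.array([0.5, 1.0, 2.0])
        out = posterior_variances(s2, 10, np.inf, 3.0)
        assert np.allclose(out, 3.0)

    def test_identical_variances_trigger_infinite_prior_df(self):
        from scipy.special import digamma

        d0, s0 = estimate_prior(np.full(50, 2.0), df=10)
        assert np.isinf(d0)
        # point-mass prior carries the chi-square log-bias correction
        expected = 2.0 * np.exp(np.log(5.0) - digamma(5.0))
        assert s0 == pytest.approx(expected, rel=1e-9)

    def test_moment_estimator_recovers_prior(self):
        # variances ~ s0^2 * d0 / chi2(d0), scaled by chi2 sampling with df
        rng = np.random.default_rng(8)
        d0_true, s0_true, df = 8.0, 0.7, 20.0
        true_var = (
            s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        )
        s2 = true_var * rng.chisquare(df, size=5000) / df
        d0_hat, s0_hat = estimate_prior(s2, df)
        assert d0_hat == pytest.approx(d0_true, rel=0.3)
        assert s0_hat == pytest.approx(s0_true, rel=0.15)

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(3)
        y = _frame(rng.normal(size=(40, 8)))
        w = _frame(np.ones((40, 8)))
        x = pd.DataFrame({"mu": [1.0] * 8}, index=y.columns)
        fit = ebayes_moderate(fit_wls(y, w, x))
        s2 = fit.sigma**2
        lo = np.minimum(s2, fit.prior_var)
        hi = np.maximum(s2, fit.prior_var)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()


class TestContrasts:
    def test_hand_computed_bh(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 1.0]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        assert (benjamini_hochberg(p) >= p - 1e-12).all()

    def test_true_fold_change_recovered_at_low_noise(self):
        design = build_default_design()
        genes = simulate_genes(
            {"de_up": 10, "null": 40}, seed=13, cold_log2fc=1.0
        )
        ds = generate_dataset(
            genes,
            design,
            NoiseModel(nb_dispersion=1e-4, batch_sd=0.0),
            seed=13,
        )
        counts = counts_from_tpm(ds.quant_tables)
        norm = tmm_factors(counts)
        x = build_design_matrix(design)
        voom = voom_weights(counts, norm, x)
        fit = ebayes_moderate(fit_wls(voom.log2cpm, voom.weights, x))
        res = contrast_stats(fit, build_contrasts(design))
        up_tx = [
            t for g in ds.truth.genes if g.params.archetype == "de_up"
            for t in g.transcript_ids
        ]
        # acclimated-day contrasts carry the full programmed effect
        last = res.contrasts[-1].label
        lfc = res.log2fc.loc[up_tx, last]
        assert np.allclose(lfc, 1.0, atol=0.1)

    def test_null_contrast_pvalues_roughly_uniform(self):
        design = build_default_design()
        genes = simulate_genes({"null": 150}, seed=17)
        ds = generate_dataset(genes, design, seed=17)
        counts = counts_from_tpm(ds.quant_tables)
        norm = tmm_factors(counts)
        x = build_design_matrix(design)
        voom = voom_weights(counts, norm, x)
        fit = ebayes_moderate(fit_wls(voom.log2cpm, voom.weights, x))
        res = contrast_stats(fit, build_contrasts(design))
        ks_p = [
            stats.kstest(res.pvalue[lab].dropna(), "uniform").pvalue
            for lab in res.pvalue.columns
        ]
        assert np.median(ks_p) > 0.01
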