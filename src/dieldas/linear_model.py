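"""Precision-weighted linear modelling of log2-CPM with variance moderation.

The model is a cell-means design: one indicator column per (block, time)
cell plus optional batch-factor covariates.  Observation weights come from a
fitted mean-variance trend on log-counts (inverse predicted variance), the
per-feature weighted least-squares variances are shrunk toward a common
prior by inverse-chi-square empirical Bayes (prior df and variance estimated
by moments on the log sample variances), and per-contrast moderated
t-statistics are corrected with Benjamini-Hochberg within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .preprocess import NormFactors, PreprocessError
from .study_design import ContrastGroup, TimeSeriesDesign, timepoint_key


class ModelError(ValueError):
    pass


def build_design_matrix(
    design: TimeSeriesDesign,
    batch_factors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Samples x columns indicator matrix: one column per time-point cell.

    Cell columns are labelled ``block@<abs>h`` (matching contrast time-point
    keys); batch-factor columns, if given, are appended unchanged.
    """
    rows = []
    keys = [timepoint_key(tp) for tp in design.timepoints]
    for s in design.samples:
        row = {k: 0.0 for k in keys}
        row[timepoint_key(s.timepoint)] = 1.0
        rows.append(row)
    x = pd.DataFrame(rows, index=design.sample_ids)
    if batch_factors is not None and batch_factors.shape[1] > 0:
        x = x.join(batch_factors.loc[x.index])
    _check_full_rank(x)
    return x


def _check_full_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(arr)
        bad = [
            str(x.columns[j])
            for j in range(arr.shape[1])
            if abs(r[j, j]) < 1e-10
        ]
        raise ModelError(f"design matrix is rank deficient (columns {bad})")


@dataclass
class VoomResult:
    log2cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray


def voom_weights(
    counts: pd.DataFrame,
    norm: NormFactors,
    design_matrix: pd.DataFrame,
    span: float = 0.5,
) -> VoomResult:
    """Log2-CPM and inverse predicted-variance observation weights.

    Per-feature sqrt residual SD from an unweighted first-pass fit is
    smoothed against average log-count by robust locally weighted regression;
    the trend evaluated at each observation's fitted log-count, raised to the
    fourth power and inverted, gives the weight.
    """
    if counts.shape[0] < 10:
        raise ModelError(
            "mean-variance trend needs at least 10 features "
            f"(got {counts.shape[0]})"
        )
    eff = norm.effective_lib_sizes[counts.columns].to_numpy(dtype=float)
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / (eff + 1.0) * 1e6)
    x = design_matrix.loc[counts.columns].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ModelError("no residual degrees of freedom for the trend fit")

    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    fitted = (x @ beta).T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))

    # mean log2 count and sqrt-SD, the trend's coordinate system
    sx = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    smooth = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)

    fitted_logcount = fitted + np.log2(eff + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    w = pred_sqrt_sd**-4.0
    return VoomResult(
        log2cpm=pd.DataFrame(y, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(w, index=counts.index, columns=counts.columns),
        trend_x=tx,
        trend_y=ty,
    )


@dataclass
class ModelFit:
    """Per-feature weighted least-squares fits (optionally moderated)."""

    coefficients: pd.DataFrame          # features x p
    sigma: pd.Series                    # residual SD per feature
    df_residual: float
    cov_unscaled: np.ndarray            # features x p x p, (X'WX)^-1
    design_columns: list[str]
    s2_post: pd.Series | None = None
    prior_df: float | None = None
    prior_var: float | None = None

    @property
    def features(self) -> pd.Index:
        return self.coefficients.index

    @property
    def moderated(self) -> bool:
        return self.s2_post is not None

    @property
    def total_df(self) -> float:
        if not self.moderated:
            return self.df_residual
        return min(self.prior_df + self.df_residual, 1e9)

    def variances(self) -> pd.Series:
        """Residual variances used for contrast statistics."""
        if self.moderated:
            return self.s2_post
        return self.sigma**2


def fit_wls(
    log2cpm: pd.DataFrame,
    weights: pd.DataFrame,
    design_matrix: pd.DataFrame,
) -> ModelFit:
    """Feature-wise weighted least squares on the full design."""
    if not log2cpm.index.equals(weights.index) or list(
        log2cpm.columns
    ) != list(weights.columns):
        raise ModelError("log2cpm and weights must share their axes")
    x = design_matrix.loc[log2cpm.columns].to_numpy(dtype=float)
    _check_full_rank(design_matrix)
    n, p = x.shape
    if n <= p:
        raise ModelError("more coefficients than samples")
    y = log2cpm.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ModelError("weights must be finite and positive")

    nfeat = y.shape[0]
    coef = np.empty((nfeat, p))
    sigma = np.empty(nfeat)
    cov = np.empty((nfeat, p, p))
    for f in range(nfeat):
        sw = np.sqrt(w[f])
        xw = x * sw[:, None]
        yw = y[f] * sw
        xtx = xw.T @ xw
        xty = xw.T @ yw
        c = np.linalg.inv(xtx)
        b = c @ xty
        resid = yw - xw @ b
        rss = float(resid @ resid)
        coef[f] = b
        cov[f] = c
        sigma[f] = np.sqrt(max(rss, 0.0) / (n - p))
    return ModelFit(
        coefficients=pd.DataFrame(
            coef, index=log2cpm.index, columns=design_matrix.columns
        ),
        sigma=pd.Series(sigma, index=log2cpm.index),
        df_residual=float(n - p),
        cov_unscaled=cov,
        design_columns=list(design_matrix.columns),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        raise ModelError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_prior(
    variances: np.ndarray, df: float
) -> tuple[float, float]:
    """Moment estimates (prior df, prior variance) for the scaled
    inverse-chi-square distribution of the sample variances.

    Works on the log variances, whose distribution under the model is a
    shifted log-F; matching mean and variance of the log gives the prior.
    Returns ``(inf, s0^2)`` when the observed spread is no larger than the
    chi-square sampling noise alone.
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ModelError("need at least two positive variances")
    z = np.log(v)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def posterior_variances(
    s2: np.ndarray, df: float, prior_df: float, prior_var: float
) -> np.ndarray:
    """Inverse-chi-square shrinkage: (d0*s0^2 + df*s2) / (d0 + df).

    prior_df = 0 returns the sample variances unchanged; prior_df = inf
    collapses every variance onto the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(prior_df):
        return np.full_like(s2, prior_var)
    return (prior_df * prior_var + df * s2) / (prior_df + df)


def ebayes_moderate(fit: ModelFit) -> ModelFit:
    """Shrink per-feature variances toward the estimated prior."""
    df = fit.df_residual
    if df <= 0:
        raise ModelError("no residual degrees of freedom to moderate")
    s2 = (fit.sigma**2).to_numpy()
    d0, s0_sq = estimate_prior(s2, df)
    post = posterior_variances(s2, df, d0, s0_sq)
    return ModelFit(
        coefficients=fit.coefficients,
        sigma=fit.sigma,
        df_residual=fit.df_residual,
        cov_unscaled=fit.cov_unscaled,
        design_columns=fit.design_columns,
        s2_post=pd.Series(post, index=fit.sigma.index),
        prior_df=d0,
        prior_var=s0_sq,
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    out = np.full_like(np.asarray(pvalues, dtype=float), np.nan)
    mask = np.isfinite(pvalues)
    if mask.any():
        out[mask] = multipletests(
            np.asarray(pvalues, dtype=float)[mask], method="fdr_bh"
        )[1]
    return out


@dataclass
class ContrastResult:
    """Per-feature x per-contrast statistics, one column per contrast label."""

    log2fc: pd.DataFrame
    se: pd.DataFrame
    t: pd.DataFrame
    pvalue: pd.DataFrame
    adj_pvalue: pd.DataFrame
    contrasts: list[ContrastGroup] = field(default_factory=list)

    @property
    def features(self) -> pd.Index:
        return self.log2fc.index


def contrast_vector(
    contrast: ContrastGroup, design_columns: Sequence[str]
) -> np.ndarray:
    treat = timepoint_key(contrast.treatment_timepoint)
    ref = timepoint_key(contrast.reference_timepoint)
    for key in (treat, ref):
        if key not in design_columns:
            raise ModelError(f"contrast column {key!r} not in the design")
    c = np.zeros(len(design_columns))
    c[list(design_columns).index(treat)] = 1.0
    c[list(design_columns).index(ref)] = -1.0
    return c


def contrast_stats(
    fit: ModelFit, contrasts: Sequence[ContrastGroup]
) -> ContrastResult:
    """Moderated t-statistics for every contrast, BH within each contrast."""
    cols = fit.design_columns
    var = fit.variances().to_numpy()
    dof = fit.total_df
    lfc = {}
    se = {}
    tstat = {}
    pval = {}
    padj = {}
    beta = fit.coefficients.to_numpy()
    for con in contrasts:
        c = contrast_vector(con, cols)
        est = beta @ c
        vu = np.einsum("i,fij,j->f", c, fit.cov_unscaled, c)
        s = np.sqrt(np.maximum(vu * var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, est / s, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        lfc[con.label] = est
        se[con.label] = s
        tstat[con.label] = t
        pval[con.label] = p
        padj[con.label] = benjamini_hochberg(p)
    idx = fit.features

    def frame(d: dict) -> pd.DataFrame:
        return pd.DataFrame(d, index=idx)

    return ContrastResult(
        log2fc=frame(lfc),
        se=frame(se),
        t=frame(tstat),
        pvalue=frame(pval),
        adj_pvalue=frame(padj),
        contrasts=list(contrasts),
    )
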