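"""Expression filtering, TMM normalization and batch-factor estimation.

The normalization follows the weighted trimmed mean of M-values (TMM)
scheme: per-sample scaling factors are computed from pairwise log-ratios
against a reference sample, with the most extreme log-ratios (M) and
abundances (A) trimmed and the remainder averaged with inverse
asymptotic-variance weights.  Batch structure between replicate experiments
is estimated residually: log-CPM is regressed on the design, and the leading
right singular vectors of the residual matrix are returned as sample-level
nuisance covariates (the residual "remove unwanted variation" approach).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class PreprocessError(ValueError):
    pass


@dataclass
class NormFactors:
    """Per-sample TMM factors and library sizes; geometric mean of factors ~1."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        eff = self.lib_sizes * self.factors
        if (eff <= 0).any():
            raise PreprocessError("non-positive effective library size")
        return eff


def unit_factors(counts: pd.DataFrame) -> NormFactors:
    """All-ones factors with library sizes from column sums."""
    lib = counts.sum(axis=0)
    return NormFactors(
        factors=pd.Series(1.0, index=counts.columns), lib_sizes=lib
    )


def cpm(
    counts: pd.DataFrame,
    norm: NormFactors | None = None,
    log2: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over effective library sizes.

    The log2 variant adds ``prior_count`` to the counts before scaling so
    zero counts map to a finite value.
    """
    norm = norm or unit_factors(counts)
    eff = norm.effective_lib_sizes[counts.columns]
    if log2:
        return np.log2((counts + prior_count).div(eff, axis=1) * 1e6)
    return counts.div(eff, axis=1) * 1e6


@dataclass
class FilterResult:
    kept_transcripts: pd.Index
    kept_genes: pd.Index
    removed_transcripts: pd.Index


def filter_low_expressed(
    counts_tx: pd.DataFrame,
    tx2gene: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> FilterResult:
    """Drop transcripts without CPM >= min_cpm in at least min_samples samples.

    CPM here is computed with unit factors (filtering precedes factor
    estimation).  A gene is kept as expressed if any member transcript
    survives.
    """
    c = cpm(counts_tx)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    kept_tx = counts_tx.index[keep]
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    kept_genes = pd.Index(sorted(set(mapping.loc[kept_tx])), name="gene_id")
    return FilterResult(
        kept_transcripts=kept_tx,
        kept_genes=kept_genes,
        removed_transcripts=counts_tx.index[~keep],
    )


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """Log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise PreprocessError(
            "sample shares no positively expressed feature with the reference"
        )
    o, r = obs[pos], ref[pos]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic variance of M (delta method on binomial counts)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0

    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (
        (rank_m >= lo_l)
        & (rank_m <= hi_l)
        & (rank_a >= lo_s)
        & (rank_a <= hi_s)
    )
    if not keep.any():
        return 0.0
    if weighted:
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    else:
        f = np.mean(m[keep])
    return float(f) if np.isfinite(f) else 0.0


def choose_tmm_reference(counts: pd.DataFrame) -> str:
    """Sample whose 75th CPM percentile is closest to the mean percentile."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise PreprocessError(f"sample(s) with zero total counts: {bad}")
    uq = counts.div(lib, axis=1).quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> NormFactors:
    """Weighted trimmed mean of M-values factors, geometric mean rescaled to 1."""
    if counts.shape[1] < 2:
        raise PreprocessError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise PreprocessError(f"sample(s) with zero total counts: {bad}")
    ref = ref_sample or choose_tmm_reference(counts)
    if ref not in counts.columns:
        raise PreprocessError(f"reference sample {ref!r} not in matrix")
    ref_col = counts[ref].to_numpy(dtype=float)
    log2f = pd.Series(
        {
            sid: _tmm_pair(
                counts[sid].to_numpy(dtype=float),
                ref_col,
                float(lib[sid]),
                float(lib[ref]),
                logratio_trim,
                sum_trim,
                weighted,
            )
            for sid in counts.columns
        }
    )
    factors = 2.0 ** (log2f - log2f.mean())
    return NormFactors(factors=factors, lib_sizes=lib.astype(float))


# ---------------------------------------------------------------------------
# residual batch factors


def ruvr_factors(
    counts: pd.DataFrame,
    design_matrix: pd.DataFrame,
    k: int = 1,
    norm: NormFactors | None = None,
) -> pd.DataFrame:
    """Residual unwanted-variation covariates.

    Fits an unweighted linear model of log2-CPM on the design, then takes the
    top-k right singular vectors of the residual matrix as samples x k
    covariates (orthonormal columns).
    """
    if k < 0:
        raise PreprocessError("k must be >= 0")
    x = design_matrix.to_numpy(dtype=float)
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if k > n - rank:
        raise PreprocessError(
            f"k={k} exceeds residual degrees of freedom ({n - rank})"
        )
    if k == 0:
        return pd.DataFrame(index=design_matrix.index)
    y = cpm(counts[design_matrix.index], norm=norm, log2=True).to_numpy()
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    if np.allclose(resid, 0.0, atol=1e-12):
        warnings.warn(
            "residual matrix is numerically zero; batch factors are "
            "uninformative",
            stacklevel=2,
        )
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    factors = vt[:k].T
    return pd.DataFrame(
        factors,
        index=design_matrix.index,
        columns=[f"ruv{i + 1}" for i in range(k)],
    )
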