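"""DE/DAS decision rules, percent-spliced statistics and gene classification.

A gene is differentially expressed (DE) when at least two contrasts at
consecutive time-points within one cold day each show an adjusted p below
the significance cut-off and at least a twofold change.  A gene is
differentially alternatively spliced (DAS) when at least one of its
transcripts diverges significantly from the gene-level log2 fold change
(adjusted p below the cut-off) with an absolute change in percent spliced
(|dPS|) of at least 0.1, again in two consecutive contrasts.  PS is a
transcript's share of its gene's abundance, computed from replicate-mean
TPM per time-point cell; dPS subtracts the matched control cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linear_model import ContrastResult, ModelFit, benjamini_hochberg
from .study_design import (
    ContrastGroup,
    TimeSeriesDesign,
    consecutive_pairs,
    timepoint_key,
)

DEFAULT_MAX_ADJ_P = 0.01
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_MIN_DELTA_PS = 0.1
DEFAULT_MIN_CONSECUTIVE = 2


class DASError(ValueError):
    pass


# ---------------------------------------------------------------------------
# percent spliced


@dataclass
class PSResult:
    """Percent-spliced values and their per-contrast differences.

    ``ps`` is transcripts x time-point cells; entries are NaN where the gene
    mean TPM is zero (PS undefined).  ``delta_ps`` is transcripts x contrast
    labels, treatment PS minus matched-control PS.
    """

    ps: pd.DataFrame
    delta_ps: pd.DataFrame
    gene_mean_tpm: pd.DataFrame


def compute_ps(
    tpm_tx: pd.DataFrame,
    tx2gene: pd.DataFrame,
    design: TimeSeriesDesign,
    contrasts: Sequence[ContrastGroup],
) -> PSResult:
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    missing = tpm_tx.index.difference(mapping.index)
    if len(missing):
        raise DASError(f"unmapped transcripts: {list(missing[:10])}")
    gene_of = mapping.loc[tpm_tx.index]

    # replicate-mean TPM per (block, absolute time) cell
    cell_means = {}
    for tp in design.timepoints:
        sids = [s.sample_id for s in design.samples_at(tp)]
        cell_means[timepoint_key(tp)] = tpm_tx[sids].mean(axis=1)
    tx_mean = pd.DataFrame(cell_means)

    gene_mean = tx_mean.groupby(gene_of.to_numpy()).sum()
    gene_mean.index.name = "gene_id"
    denom = gene_mean.loc[gene_of.to_numpy()].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = tx_mean.to_numpy() / denom
    ps = pd.DataFrame(
        np.where(denom > 0, ps, np.nan),
        index=tx_mean.index,
        columns=tx_mean.columns,
    )

    delta = {
        con.label: ps[timepoint_key(con.treatment_timepoint)]
        - ps[timepoint_key(con.reference_timepoint)]
        for con in contrasts
    }
    return PSResult(
        ps=ps, delta_ps=pd.DataFrame(delta), gene_mean_tpm=gene_mean
    )


# ---------------------------------------------------------------------------
# consecutive-run machinery


def _qualifying_runs(
    qualifies: pd.DataFrame,
    contrasts: Sequence[ContrastGroup],
    min_run: int,
) -> pd.Series:
    """Per feature, True when >= min_run consecutive contrasts qualify.

    Consecutive means ordinal difference 1 within one block; runs never span
    the block boundary.
    """
    labels = [c.label for c in contrasts]
    q = qualifies[labels].to_numpy(dtype=bool)
    pairs = consecutive_pairs(contrasts)
    if min_run < 1:
        raise DASError("min_run must be >= 1")
    if min_run == 1:
        return pd.Series(q.any(axis=1), index=qualifies.index)
    # run length per position, respecting block boundaries
    run = np.zeros(q.shape, dtype=int)
    run[:, 0] = q[:, 0]
    adjacency = {b: a for a, b in pairs}
    for j in range(1, q.shape[1]):
        linked = adjacency.get(j) == j - 1
        run[:, j] = np.where(
            q[:, j], (run[:, j - 1] if linked else 0) + 1, 0
        )
    return pd.Series((run >= min_run).any(axis=1), index=qualifies.index)


def qualifying_contrasts(
    qualifies: pd.DataFrame, feature: str
) -> list[str]:
    row = qualifies.loc[feature]
    return list(row.index[row])


# ---------------------------------------------------------------------------
# DE calls


@dataclass
class DEDecision:
    is_de: pd.Series                 # bool per feature
    qualifies: pd.DataFrame          # bool, features x contrast labels

    @property
    def de_features(self) -> pd.Index:
        return self.is_de.index[self.is_de]


def call_de(
    result: ContrastResult,
    contrasts: Sequence[ContrastGroup] | None = None,
    max_adj_p: float = DEFAULT_MAX_ADJ_P,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
) -> DEDecision:
    """Apply the consecutive-contrast DE rule to gene- or transcript-level
    contrast statistics."""
    contrasts = list(contrasts or result.contrasts)
    labels = [c.label for c in contrasts]
    qual = (result.adj_pvalue[labels] < max_adj_p) & (
        result.log2fc[labels].abs() >= min_abs_log2fc
    )
    is_de = _qualifying_runs(qual, contrasts, min_consecutive)
    return DEDecision(is_de=is_de, qualifies=qual)


# ---------------------------------------------------------------------------
# transcript-vs-gene divergence


@dataclass
class DivergenceResult:
    """Transcript log2FC minus the gene's precision-weighted log2FC."""

    divergence: pd.DataFrame         # transcripts x contrasts
    t: pd.DataFrame
    pvalue: pd.DataFrame
    adj_pvalue: pd.DataFrame
    gene_f: pd.DataFrame             # genes x contrasts, F statistic
    gene_f_pvalue: pd.DataFrame
    contrasts: list[ContrastGroup] = field(default_factory=list)


def das_divergence(
    tx_result: ContrastResult,
    fit: ModelFit,
    tx2gene: pd.DataFrame,
    contrasts: Sequence[ContrastGroup] | None = None,
) -> DivergenceResult:
    """Per-contrast divergence statistics for genes with >= 2 transcripts.

    The gene log2FC is the inverse-variance weighted mean of its transcripts'
    log2FCs; single-transcript genes are excluded (they cannot diverge).
    Moderated t uses the shrunken variances and total df of ``fit``; BH is
    applied within each contrast across all tested transcripts.
    """
    contrasts = list(contrasts or tx_result.contrasts)
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    tx_index = tx_result.features
    gene_of = mapping.loc[tx_index]
    multi = gene_of.groupby(gene_of).transform("size") >= 2
    tested = tx_index[multi.to_numpy()]
    genes = pd.Index(sorted(set(gene_of.loc[tested])), name="gene_id")
    dof = fit.total_df

    div = {}
    tstat = {}
    pval = {}
    padj = {}
    gene_f = {}
    gene_fp = {}
    gof = gene_of.loc[tested].to_numpy()
    for con in contrasts:
        lfc = tx_result.log2fc.loc[tested, con.label].to_numpy()
        se = tx_result.se.loc[tested, con.label].to_numpy()
        var = se**2
        w = np.where(var > 0, 1.0 / np.maximum(var, 1e-300), 0.0)
        df_w = pd.DataFrame({"w": w, "wl": w * lfc}, index=tested)
        grp = df_w.groupby(gof).sum()
        wsum = grp["w"].loc[gof].to_numpy()
        gene_lfc = (grp["wl"] / grp["w"]).loc[gof].to_numpy()
        d = lfc - gene_lfc
        # Var(tx - weighted gene mean) = var_tx - 1/sum(w) under independence
        var_d = np.maximum(var - 1.0 / wsum, 1e-300)
        t = d / np.sqrt(var_d)
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        div[con.label] = d
        tstat[con.label] = t
        pval[con.label] = p
        padj[con.label] = benjamini_hochberg(p)

        fdf = pd.DataFrame({"wd2": w * d**2}, index=tested).groupby(gof).sum()
        ntx = pd.Series(gof).value_counts().sort_index()
        fstat = fdf["wd2"].to_numpy() / np.maximum(ntx.to_numpy() - 1, 1)
        gene_f[con.label] = pd.Series(fstat, index=fdf.index)
        gene_fp[con.label] = pd.Series(
            stats.f.sf(fstat, np.maximum(ntx.to_numpy() - 1, 1), dof),
            index=fdf.index,
        )

    idx = pd.Index(tested, name="transcript_id")
    return DivergenceResult(
        divergence=pd.DataFrame(div, index=idx),
        t=pd.DataFrame(tstat, index=idx),
        pvalue=pd.DataFrame(pval, index=idx),
        adj_pvalue=pd.DataFrame(padj, index=idx),
        gene_f=pd.DataFrame(gene_f).loc[genes],
        gene_f_pvalue=pd.DataFrame(gene_fp).loc[genes],
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# DAS calls


@dataclass
class DASDecision:
    is_das_gene: pd.Series           # bool per gene
    is_das_transcript: pd.Series     # bool per tested transcript
    qualifies: pd.DataFrame          # bool, transcripts x contrast labels

    @property
    def das_genes(self) -> pd.Index:
        return self.is_das_gene.index[self.is_das_gene]


def call_das(
    divergence: DivergenceResult,
    ps: PSResult,
    tx2gene: pd.DataFrame,
    contrasts: Sequence[ContrastGroup] | None = None,
    max_adj_p: float = DEFAULT_MAX_ADJ_P,
    min_delta_ps: float = DEFAULT_MIN_DELTA_PS,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
) -> DASDecision:
    """Gene is DAS when some transcript passes both the divergence
    significance and |dPS| gates in enough consecutive contrasts."""
    contrasts = list(contrasts or divergence.contrasts)
    labels = [c.label for c in contrasts]
    tested = divergence.adj_pvalue.index
    dps = ps.delta_ps.reindex(tested)[labels]
    qual = (divergence.adj_pvalue[labels] < max_adj_p) & (
        dps.abs() >= min_delta_ps
    ).fillna(False)
    tx_flag = _qualifying_runs(qual, contrasts, min_consecutive)
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    gene_of = mapping.loc[tested]
    gene_flag = tx_flag.groupby(gene_of.to_numpy()).any()
    gene_flag.index.name = "gene_id"
    return DASDecision(
        is_das_gene=gene_flag, is_das_transcript=tx_flag, qualifies=qual
    )


# ---------------------------------------------------------------------------
# classification and panels


@dataclass
class GeneClassification:
    """Disjoint partition of the expressed genes."""

    de_only: set[str]
    de_and_das: set[str]
    das_only: set[str]
    not_regulated: set[str]
    not_expressed: set[str] = field(default_factory=set)

    @property
    def universe(self) -> set[str]:
        return (
            self.de_only | self.de_and_das | self.das_only | self.not_regulated
        )

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "expressed": len(self.universe),
                "DE-only": len(self.de_only),
                "DE+DAS": len(self.de_and_das),
                "DAS-only": len(self.das_only),
                "not-regulated": len(self.not_regulated),
                "not-expressed": len(self.not_expressed),
            }
        )

    def table(self) -> pd.DataFrame:
        rows = []
        for label, genes in (
            ("DE-only", self.de_only),
            ("DE+DAS", self.de_and_das),
            ("DAS-only", self.das_only),
            ("not-regulated", self.not_regulated),
        ):
            rows.extend((g, label) for g in sorted(genes))
        return pd.DataFrame(rows, columns=["gene_id", "category"])


def classify(
    de: DEDecision,
    das: DASDecision,
    universe: Iterable[str] | None = None,
) -> GeneClassification:
    """Partition genes into DE-only / DE+DAS / DAS-only / not-regulated."""
    de_genes = set(de.de_features)
    das_genes = set(das.das_genes)
    if universe is None:
        univ = set(de.is_de.index) | set(das.is_das_gene.index)
    else:
        univ = set(universe)
    de_genes &= univ
    das_genes &= univ
    both = de_genes & das_genes
    return GeneClassification(
        de_only=de_genes - both,
        de_and_das=both,
        das_only=das_genes - both,
        not_regulated=univ - de_genes - das_genes,
    )


def subset_by_panel(
    classification: GeneClassification, panel: Iterable[str]
) -> GeneClassification:
    """Restrict the classification to a gene-ID panel (exact match).

    Panel members absent from the expressed universe are reported in
    ``not_expressed``.
    """
    panel = set(panel)
    if not panel:
        warnings.warn("empty gene panel; result is empty", stacklevel=2)
    univ = classification.universe
    return GeneClassification(
        de_only=classification.de_only & panel,
        de_and_das=classification.de_and_das & panel,
        das_only=classification.das_only & panel,
        not_regulated=classification.not_regulated & panel,
        not_expressed=panel - univ,
    )
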