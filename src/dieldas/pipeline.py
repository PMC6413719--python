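"""End-to-end analysis workflow tying the modules together.

counts -> expression filter -> TMM -> residual batch factors -> voom
weights -> weighted fits -> variance moderation -> matched-time-point
contrasts -> DE calls -> PS/dPS -> divergence -> DAS calls ->
classification -> isoform switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import das_analysis, isoform_switch, linear_model, preprocess, quant_io
from .study_design import ContrastGroup, TimeSeriesDesign, build_contrasts


@dataclass
class Thresholds:
    max_adj_p: float = 0.01
    min_abs_log2fc: float = 1.0
    min_delta_ps: float = 0.1
    min_consecutive: int = 2
    min_switch_score: float = 0.5
    max_switch_p: float = 0.05


@dataclass
class ModelConfig:
    ruv_k: int = 1
    voom_span: float = 0.5
    min_cpm: float = 1.0
    min_cpm_samples: int = 3


@dataclass
class AnalysisResults:
    design: TimeSeriesDesign
    contrasts: list[ContrastGroup]
    filter_result: preprocess.FilterResult
    norm_tx: preprocess.NormFactors
    norm_gene: preprocess.NormFactors
    batch_factors: pd.DataFrame
    tx_result: linear_model.ContrastResult
    gene_result: linear_model.ContrastResult
    de_gene: das_analysis.DEDecision
    de_tx: das_analysis.DEDecision
    ps: das_analysis.PSResult
    divergence: das_analysis.DivergenceResult
    das: das_analysis.DASDecision
    classification: das_analysis.GeneClassification
    switches: list[isoform_switch.SwitchEvent]

    def summary(self) -> pd.Series:
        s = self.classification.summary()
        s["transcripts-kept"] = len(self.filter_result.kept_transcripts)
        s["isoform-switch-events"] = len(self.switches)
        return s


def run_analysis(
    quant_tables: Mapping[str, pd.DataFrame],
    tx2gene: pd.DataFrame,
    design: TimeSeriesDesign,
    thresholds: Thresholds | None = None,
    model: ModelConfig | None = None,
) -> AnalysisResults:
    thresholds = thresholds or Thresholds()
    model = model or ModelConfig()

    ordered = {sid: quant_tables[sid] for sid in design.sample_ids}
    counts_tx = quant_io.counts_from_tpm(ordered)
    tpm_tx = quant_io.tpm_matrix(ordered)

    filt = preprocess.filter_low_expressed(
        counts_tx,
        tx2gene,
        min_cpm=model.min_cpm,
        min_samples=model.min_cpm_samples,
    )
    counts_kept = counts_tx.loc[filt.kept_transcripts]
    tpm_kept = tpm_tx.loc[filt.kept_transcripts]
    map_kept = tx2gene[tx2gene["transcript_id"].isin(filt.kept_transcripts)]

    norm_tx = preprocess.tmm_factors(counts_kept)
    base_design = linear_model.build_design_matrix(design)
    batch = preprocess.ruvr_factors(
        counts_kept, base_design, k=model.ruv_k, norm=norm_tx
    )
    x = linear_model.build_design_matrix(design, batch)
    contrasts = build_contrasts(design)

    voom_tx = linear_model.voom_weights(
        counts_kept, norm_tx, x, span=model.voom_span
    )
    fit_tx = linear_model.ebayes_moderate(
        linear_model.fit_wls(voom_tx.log2cpm, voom_tx.weights, x)
    )
    tx_result = linear_model.contrast_stats(fit_tx, contrasts)

    counts_gene = quant_io.aggregate_gene_level(counts_kept, map_kept)
    norm_gene = preprocess.tmm_factors(counts_gene)
    voom_gene = linear_model.voom_weights(
        counts_gene, norm_gene, x, span=model.voom_span
    )
    fit_gene = linear_model.ebayes_moderate(
        linear_model.fit_wls(voom_gene.log2cpm, voom_gene.weights, x)
    )
    gene_result = linear_model.contrast_stats(fit_gene, contrasts)

    de_gene = das_analysis.call_de(
        gene_result,
        contrasts,
        max_adj_p=thresholds.max_adj_p,
        min_abs_log2fc=thresholds.min_abs_log2fc,
        min_consecutive=thresholds.min_consecutive,
    )
    de_tx = das_analysis.call_de(
        tx_result,
        contrasts,
        max_adj_p=thresholds.max_adj_p,
        min_abs_log2fc=thresholds.min_abs_log2fc,
        min_consecutive=thresholds.min_consecutive,
    )

    ps = das_analysis.compute_ps(tpm_kept, map_kept, design, contrasts)
    divergence = das_analysis.das_divergence(
        tx_result, fit_tx, map_kept, contrasts
    )
    das = das_analysis.call_das(
        divergence,
        ps,
        map_kept,
        contrasts,
        max_adj_p=thresholds.max_adj_p,
        min_delta_ps=thresholds.min_delta_ps,
        min_consecutive=thresholds.min_consecutive,
    )
    classification = das_analysis.classify(
        de_gene, das, universe=filt.kept_genes
    )
    switches = isoform_switch.detect_switches(
        tpm_kept,
        map_kept,
        design,
        min_score=thresholds.min_switch_score,
        max_p=thresholds.max_switch_p,
    )
    return AnalysisResults(
        design=design,
        contrasts=contrasts,
        filter_result=filt,
        norm_tx=norm_tx,
        norm_gene=norm_gene,
        batch_factors=batch,
        tx_result=tx_result,
        gene_result=gene_result,
        de_gene=de_gene,
        de_tx=de_tx,
        ps=ps,
        divergence=divergence,
        das=das,
        classification=classification,
        switches=switches,
    )


def write_results(results: AnalysisResults, out_dir: str | Path) -> Path:
    """Write the per-gene/per-transcript tables and summaries as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _wide(res: linear_model.ContrastResult, stem: str) -> None:
        res.log2fc.to_csv(out / f"{stem}_log2fc.tsv", sep="\t")
        res.adj_pvalue.to_csv(out / f"{stem}_adj_pvalue.tsv", sep="\t")

    _wide(results.gene_result, "gene")
    _wide(results.tx_result, "transcript")
    results.ps.ps.to_csv(out / "percent_spliced.tsv", sep="\t")
    results.ps.delta_ps.to_csv(out / "delta_ps.tsv", sep="\t")
    results.divergence.adj_pvalue.to_csv(
        out / "divergence_adj_pvalue.tsv", sep="\t"
    )
    results.classification.table().to_csv(
        out / "gene_classification.tsv", sep="\t", index=False
    )
    results.summary().rename("count").to_csv(
        out / "summary.tsv", sep="\t", header=True
    )
    isoform_switch.events_table(results.switches).to_csv(
        out / "isoform_switches.tsv", sep="\t", index=False
    )
    return out
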