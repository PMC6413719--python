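"""PS/dPS statistics, DE/DAS decision rules and gene classification."""

import numpy as np
import pandas as pd
import pytest

from dieldas.das_analysis import (
    DASDecision,
    DEDecision,
    GeneClassification,
    call_das,
    call_de,
    classify,
    compute_ps,
    das_divergence,
    subset_by_panel,
)
from dieldas.linear_model import ContrastResult
from dieldas.study_design import (
    build_contrasts,
    build_default_design,
    timepoint_key,
)


@pytest.fixture(scope="module")
def design():
    return build_default_design()


@pytest.fixture(scope="module")
def contrasts(design):
    return build_contrasts(design)


def _t2g(tx_to_gene):
    return pd.DataFrame(
        {
            "transcript_id": list(tx_to_gene),
            "gene_id": [tx_to_gene[t] for t in tx_to_gene],
        }
    )


def _tpm_matrix(design, tx_values):
    """Constant-in-time TPM matrix from per-transcript values."""
    data = {
        s.sample_id: pd.Series(tx_values) for s in design.samples
    }
    out = pd.DataFrame(data)
    out.index.name = "transcript_id"
    return out


class TestComputePS:
    def test_share_of_gene_abundance(self, design, contrasts):
        tpm = _tpm_matrix(design, {"a1": 30.0, "a2": 10.0})
        ps = compute_ps(tpm, _t2g({"a1": "A", "a2": "A"}), design, contrasts)
        key = timepoint_key(("control20", 0.0))
        assert ps.ps.loc["a1", key] == pytest.approx(0.75)
        assert ps.ps.loc["a2", key] == pytest.approx(0.25)

    def test_single_transcript_gene_is_always_one(self, design, contrasts):
        tpm = _tpm_matrix(design, {"b1": 5.0})
        ps = compute_ps(tpm, _t2g({"b1": "B"}), design, contrasts)
        assert np.allclose(ps.ps.loc["b1"], 1.0)
        assert np.allclose(ps.delta_ps.loc["b1"], 0.0)

    def test_delta_ps_is_treatment_minus_control(self, design, contrasts):
        tpm = _tpm_matrix(design, {"a1": 50.0, "a2": 50.0})
        # cold samples shifted to 80/20
        for s in design.samples:
            if s.block != "control20":
                tpm.loc["a1", s.sample_id] = 80.0
                tpm.loc["a2", s.sample_id] = 20.0
        ps = compute_ps(tpm, _t2g({"a1": "A", "a2": "A"}), design, contrasts)
        assert np.allclose(ps.delta_ps.loc["a1"], 0.3)
        assert np.allclose(ps.delta_ps.loc["a2"], -0.3)

    def test_simplex_conservation_per_timepoint(self, design, contrasts):
        rng = np.random.default_rng(0)
        values = {f"t{i}": float(v) for i, v in
                  enumerate(rng.uniform(1, 100, 12))}
        mapping = {f"t{i}": f"G{i % 4}" for i in range(12)}
        tpm = _tpm_matrix(design, values) + rng.uniform(
            0, 5, size=(12, design.n_samples)
        )
        ps = compute_ps(tpm, _t2g(mapping), design, contrasts)
        sums = ps.ps.groupby(
            pd.Series(mapping).loc[ps.ps.index].to_numpy()
        ).sum()
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_zero_gene_mean_flagged_nan(self, design, contrasts):
        tpm = _tpm_matrix(design, {"z1": 0.0, "z2": 0.0})
        ps = compute_ps(tpm, _t2g({"z1": "Z", "z2": "Z"}), design, contrasts)
        assert ps.ps.loc["z1"].isna().all()


def _manual_result(contrasts, lfc_rows, adjp_rows, index):
    labels = [c.label for c in contrasts]
    lfc = pd.DataFrame(lfc_rows, index=index, columns=labels)
    adjp = pd.DataFrame(adjp_rows, index=index, columns=labels)
    ones = pd.DataFrame(1.0, index=index, columns=labels)
    return ContrastResult(
        log2fc=lfc,
        se=ones,
        t=lfc,
        pvalue=adjp,
        adj_pvalue=adjp,
        contrasts=list(contrasts),
    )


class TestCallDE:
    def _result(self, contrasts, sig_at, lfc=1.2):
        n = len(contrasts)
        lfc_row = [lfc if i in sig_at else 0.0 for i in range(n)]
        p_row = [0.005 if i in sig_at else 0.9 for i in range(n)]
        return _manual_result(contrasts, [lfc_row], [p_row], ["g1"])

    def test_two_consecutive_qualify(self, contrasts):
        res = self._result(contrasts, sig_at={2, 3})
        assert call_de(res).is_de["g1"]

    def test_gap_does_not_qualify(self, contrasts):
        res = self._result(contrasts, sig_at={2, 4})
        assert not call_de(res).is_de["g1"]

    def test_fold_change_gate(self, contrasts):
        res = self._result(contrasts, sig_at=set(range(18)), lfc=0.9)
        assert not call_de(res).is_de["g1"]

    def test_block_boundary_breaks_runs(self, contrasts):
        # last contrast of day 1 (index 8) + first of day 4 (index 9)
        res = self._result(contrasts, sig_at={8, 9})
        assert not call_de(res).is_de["g1"]


class TestDivergence:
    def _pipeline(self, archetype_counts, seed):
        from dieldas.pipeline import run_analysis
        from dieldas.synthetic_data import generate_dataset, simulate_genes

        genes = simulate_genes(archetype_counts, seed=seed)
        ds = generate_dataset(genes, seed=seed)
        return ds, run_analysis(ds.quant_tables, ds.tx2gene, ds.design)

    def test_parallel_shift_is_pure_de(self, mixed_dataset, mixed_results):
        # de_up genes move all isoforms together: divergence stays small
        truth = mixed_dataset.truth
        de_multi = [
            t
            for g in truth.genes
            if g.params.archetype == "de_up" and len(g.transcript_ids) > 1
            for t in g.transcript_ids
        ]
        tested = [
            t for t in de_multi
            if t in mixed_results.divergence.adj_pvalue.index
        ]
        if tested:
            sig = (
                mixed_results.divergence.adj_pvalue.loc[tested] < 0.01
            ).to_numpy()
            assert sig.mean() < 0.2

    def test_isoform_swap_gives_opposite_signs(
        self, mixed_dataset, mixed_results
    ):
        truth = mixed_dataset.truth
        das_genes = truth.genes_with("das_switch")
        last = mixed_results.divergence.divergence.columns[-1]
        for g in das_genes:
            gene = next(x for x in truth.genes if x.gene_id == g)
            t1, t2 = gene.transcript_ids[:2]
            div = mixed_results.divergence.divergence
            if t1 in div.index and t2 in div.index:
                assert div.loc[t1, last] * div.loc[t2, last] < 0

    def test_identical_trajectories_have_zero_divergence(self, contrasts):
        # two isoforms with exactly equal log2FC in every contrast
        from dieldas.linear_model import ModelFit

        labels = [c.label for c in contrasts]
        lfc = pd.DataFrame(
            [[1.0] * 18, [1.0] * 18], index=["a1", "a2"], columns=labels
        )
        se = pd.DataFrame(
            0.1, index=["a1", "a2"], columns=labels
        )
        res = ContrastResult(
            log2fc=lfc, se=se, t=lfc, pvalue=se, adj_pvalue=se,
            contrasts=list(contrasts),
        )
        fit = ModelFit(
            coefficients=lfc,
            sigma=pd.Series(0.1, index=["a1", "a2"]),
            df_residual=10.0,
            cov_unscaled=np.zeros((2, 18, 18)),
            design_columns=labels,
        )
        div = das_divergence(res, fit, _t2g({"a1": "A", "a2": "A"}))
        assert np.allclose(div.divergence.to_numpy(), 0.0, atol=1e-12)


class TestCallDAS:
    def _inputs(self, contrasts, adjp_at, dps_at, adjp=0.001, dps=0.15):
        labels = [c.label for c in contrasts]
        n = len(labels)
        adjp_row = [adjp if i in adjp_at else 0.9 for i in range(n)]
        dps_row = [dps if i in dps_at else 0.0 for i in range(n)]
        from dieldas.das_analysis import DivergenceResult, PSResult

        idx = pd.Index(["a1"], name="transcript_id")
        frame = lambda row: pd.DataFrame([row], index=idx, columns=labels)
        div = DivergenceResult(
            divergence=frame(dps_row),
            t=frame(adjp_row),
            pvalue=frame(adjp_row),
            adj_pvalue=frame(adjp_row),
            gene_f=pd.DataFrame(),
            gene_f_pvalue=pd.DataFrame(),
            contrasts=list(contrasts),
        )
        ps = PSResult(
            ps=pd.DataFrame(),
            delta_ps=frame(dps_row),
            gene_mean_tpm=pd.DataFrame(),
        )
        return div, ps

    def test_consecutive_significant_with_dps(self, contrasts):
        div, ps = self._inputs(contrasts, {0, 1}, {0, 1})
        out = call_das(div, ps, _t2g({"a1": "A"}))
        assert out.is_das_gene["A"]

    def test_small_dps_blocks_the_call(self, contrasts):
        div, ps = self._inputs(contrasts, {0, 1}, {0, 1}, dps=0.05)
        out = call_das(div, ps, _t2g({"a1": "A"}))
        assert not out.is_das_gene["A"]

    def test_single_contrast_insufficient(self, contrasts):
        div, ps = self._inputs(contrasts, {0}, {0})
        out = call_das(div, ps, _t2g({"a1": "A"}))
        assert not out.is_das_gene["A"]

    def test_gates_must_coincide(self, contrasts):
        # significance at contrasts 0,1 but dPS only at 2,3: no call
        div, ps = self._inputs(contrasts, {0, 1}, {2, 3})
        out = call_das(div, ps, _t2g({"a1": "A"}))
        assert not out.is_das_gene["A"]


class TestClassification:
    def _decisions(self, de_genes, das_genes, universe):
        de = DEDecision(
            is_de=pd.Series(
                {g: g in de_genes for g in universe}
            ),
            qualifies=pd.DataFrame(),
        )
        das = DASDecision(
            is_das_gene=pd.Series(
                {g: g in das_genes for g in universe}
            ),
            is_das_transcript=pd.Series(dtype=bool),
            qualifies=pd.DataFrame(),
        )
        return de, das

    def test_partition(self):
        de, das = self._decisions({"a", "b"}, {"b", "c"}, "abcd")
        cls = classify(de, das, universe=set("abcd"))
        assert cls.de_only == {"a"}
        assert cls.de_and_das == {"b"}
        assert cls.das_only == {"c"}
        assert cls.not_regulated == {"d"}
        assert cls.universe == set("abcd")

    def test_panel_subsetting(self):
        de, das = self._decisions({"a"}, {"c"}, "abc")
        cls = classify(de, das, universe=set("abc"))
        sub = subset_by_panel(cls, ["a", "c", "zz", "yy"])
        assert sub.de_only == {"a"}
        assert sub.das_only == {"c"}
        assert sub.not_expressed == {"zz", "yy"}

    def test_whole_universe_panel_is_identity(self):
        de, das = self._decisions({"a"}, {"b"}, "abc")
        cls = classify(de, das, universe=set("abc"))
        sub = subset_by_panel(cls, set("abc"))
        assert sub.universe == cls.universe
        assert not sub.not_expressed

    def test_empty_panel_warns(self):
        de, das = self._decisions({"a"}, set(), "ab")
        cls = classify(de, das, universe=set("ab"))
        with pytest.warns(UserWarning, match="empty"):
            sub = subset_by_panel(cls, [])
        assert not sub.universe
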