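"""Synthetic diel cold-shift RNA-seq datasets with ground truth.

Each simulated gene follows a rhythmic baseline (cosine on the 24-h clock)
modified after the cold switch according to one of a set of cold-response
archetypes observed in shift experiments: sustained up/down regulation,
transient responses confined to the first cold day, adaptive responses that
persist into acclimation, late responses appearing only in the acclimated day,
rhythm damping/gain, phase shifts, and pure isoform switches in which the
gene total is unchanged while isoform proportions swap.

Counts are drawn from a gamma-Poisson (negative-binomial) law around the
expectation, with multiplicative log-normal replicate-batch effects, and the
per-sample quantification tables report TPM recomputed from those counts so
counts and TPM are mutually consistent, as a quantification tool would emit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study_design import TimeSeriesDesign, build_default_design, timepoint_key

ARCHETYPES = (
    "null",
    "de_up",
    "de_down",
    "transient",
    "adaptive",
    "late",
    "rhythm_damped",
    "rhythm_gained",
    "phase_shift",
    "das_switch",
)

# archetype shape constants (documented in the methods note)
DAMPING_FACTOR = 0.25     # cold amplitude multiplier for rhythm_damped
GAIN_FACTOR = 3.0         # cold amplitude multiplier for rhythm_gained (capped)
MAX_AMPLITUDE = 0.9
PHASE_ADVANCE_H = 6.0     # cold phase advance for phase_shift

#: effective length = length - EFFLEN_OFFSET, floored at 1 (fragment-length
#: correction convention of quantification tools)
EFFLEN_OFFSET = 200.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeParams:
    """Cold-response parameters of one simulated gene."""

    archetype: str = "null"
    baseline_tpm: float = 30.0
    rhythm_amplitude: float = 0.0
    rhythm_phase_h: float = 0.0
    cold_log2fc: float = 0.0
    das_delta_ps: float = 0.0
    onset_h: float = 3.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise SimulationError(f"unknown archetype {self.archetype!r}")
        if self.baseline_tpm <= 0:
            raise SimulationError("baseline_tpm must be positive")
        if not 0 <= self.rhythm_amplitude < 1:
            raise SimulationError("rhythm_amplitude must be in [0, 1)")
        if not 0 <= self.das_delta_ps <= 1:
            raise SimulationError("das_delta_ps must be in [0, 1]")
        if self.das_delta_ps > 0 and self.archetype != "das_switch":
            raise SimulationError(
                "das_delta_ps > 0 is only meaningful for das_switch genes"
            )


@dataclass(frozen=True)
class SimGene:
    """A gene with one or more isoforms and its archetype parameters.

    ``base_isoform_fractions`` is the isoform-usage simplex at warm
    temperature; for ``das_switch`` genes the first two isoforms exchange
    ``das_delta_ps`` of usage after the cold switch.
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    transcript_lengths: tuple[float, ...]
    base_isoform_fractions: tuple[float, ...]
    params: ArchetypeParams

    def __post_init__(self) -> None:
        ntx = len(self.transcript_ids)
        if ntx < 1:
            raise SimulationError(f"gene {self.gene_id}: needs >= 1 transcript")
        if len(self.transcript_lengths) != ntx or len(
            self.base_isoform_fractions
        ) != ntx:
            raise SimulationError(
                f"gene {self.gene_id}: field lengths disagree"
            )
        if any(l < 200 for l in self.transcript_lengths):
            raise SimulationError(
                f"gene {self.gene_id}: transcript lengths must be >= 200 nt"
            )
        if abs(sum(self.base_isoform_fractions) - 1.0) > 1e-8:
            raise SimulationError(
                f"gene {self.gene_id}: isoform fractions must sum to 1"
            )
        if any(f < 0 for f in self.base_isoform_fractions):
            raise SimulationError(
                f"gene {self.gene_id}: isoform fractions must be >= 0"
            )
        if self.params.archetype == "das_switch" and ntx < 2:
            raise SimulationError(
                f"gene {self.gene_id}: das_switch needs >= 2 transcripts"
            )


@dataclass
class NoiseModel:
    """Count-noise parameters.

    ``nb_dispersion`` is the negative-binomial dispersion phi in
    Var = mu + phi * mu**2; 0 selects the exact noise-free limit.
    ``batch_sd`` is the SD of per-(gene, batch) log-normal multipliers.
    """

    nb_dispersion: float = 0.05
    batch_sd: float = 0.1
    libsize_range: tuple[float, float] = (8e5, 1.2e6)

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0")
        if self.batch_sd < 0:
            raise SimulationError("batch_sd must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise SimulationError("libsize_range must be positive and ordered")


@dataclass
class SimTruth:
    """Everything needed to reconstruct the expectation surface."""

    genes: list[SimGene]
    seed: int
    noise: NoiseModel
    libsizes: pd.Series                 # per sample
    batch_log2_effects: pd.DataFrame    # genes x batches, log2 multipliers

    def archetype_of(self) -> pd.Series:
        return pd.Series(
            {g.gene_id: g.params.archetype for g in self.genes},
            name="archetype",
        )

    def genes_with(self, archetype: str) -> list[str]:
        return [
            g.gene_id for g in self.genes if g.params.archetype == archetype
        ]


@dataclass
class SimDataset:
    quant_tables: dict[str, pd.DataFrame]   # sample_id -> quant table
    design: TimeSeriesDesign
    tx2gene: pd.DataFrame                   # columns transcript_id, gene_id
    truth: SimTruth


def onset_weight(
    t_since_switch_h: np.ndarray | float, onset_h: float
) -> np.ndarray | float:
    """Logistic 0->1 ramp after the switch, half-maximal at ``onset_h``.

    The slope scale is onset_h / 4, which puts the ramp essentially between 0
    and 2*onset_h; onset_h = 0 degenerates to a unit step at the switch.
    Before the switch (negative times) the weight is 0.
    """
    t = np.asarray(t_since_switch_h, dtype=float)
    if onset_h <= 0:
        w = np.where(t >= 0, 1.0, 0.0)
    else:
        tau = onset_h / 4.0
        w = 1.0 / (1.0 + np.exp(-(t - onset_h) / tau))
        w = np.where(t < 0, 0.0, w)
    if np.isscalar(t_since_switch_h):
        return float(w)
    return w


def _gene_level_expectation(
    params: ArchetypeParams,
    block_is_cold: np.ndarray,
    t_since_switch: np.ndarray,
    in_first_cold_day: np.ndarray,
    tod: np.ndarray,
) -> np.ndarray:
    """Expected total gene abundance (TPM units) per time-point."""
    amp = np.full_like(tod, params.rhythm_amplitude, dtype=float)
    phase = np.full_like(tod, params.rhythm_phase_h, dtype=float)
    mult = np.ones_like(tod, dtype=float)
    w = onset_weight(t_since_switch, params.onset_h)

    a = params.archetype
    if a in ("de_up", "de_down", "adaptive"):
        mult = np.where(
            block_is_cold, 2.0 ** (params.cold_log2fc * w), 1.0
        )
    elif a == "transient":
        # full effect during the first cold day, gone by acclimation
        mult = np.where(
            block_is_cold & in_first_cold_day,
            2.0 ** (params.cold_log2fc * w),
            1.0,
        )
    elif a == "late":
        mult = np.where(
            block_is_cold & ~in_first_cold_day,
            2.0 ** params.cold_log2fc,
            1.0,
        )
    elif a == "rhythm_damped":
        amp = np.where(block_is_cold, amp * DAMPING_FACTOR, amp)
    elif a == "rhythm_gained":
        amp = np.where(
            block_is_cold, np.minimum(MAX_AMPLITUDE, amp * GAIN_FACTOR), amp
        )
    elif a == "phase_shift":
        phase = np.where(block_is_cold, phase - PHASE_ADVANCE_H, phase)
    # null and das_switch: gene total unchanged

    rhythm = 1.0 + amp * np.cos(2.0 * np.pi * (tod - phase) / 24.0)
    return params.baseline_tpm * rhythm * mult


def expected_profile(
    gene: SimGene, design: TimeSeriesDesign
) -> pd.DataFrame:
    """Expected TPM per (transcript, time-point), before renormalisation.

    Rows are the gene's transcripts, columns the design's distinct
    (block, absolute time) cells labelled ``block@<abs>h``.
    """
    tps = design.timepoints
    blocks = np.array([tp[0] for tp in tps])
    abst = np.array([tp[1] for tp in tps], dtype=float)
    tod = abst % 24.0
    switch = design.transition_time_h()
    cold = blocks != design.control_block
    t_since = np.where(cold, abst - switch, -np.inf)
    cold_blocks = [b for b in design.blocks if b != design.control_block]
    first_cold = blocks == (cold_blocks[0] if cold_blocks else "")

    total = _gene_level_expectation(
        gene.params, cold, t_since, first_cold, tod
    )

    fracs = np.tile(
        np.asarray(gene.base_isoform_fractions, dtype=float)[:, None],
        (1, len(tps)),
    )
    if gene.params.archetype == "das_switch":
        w = onset_weight(t_since, gene.params.onset_h)
        w = np.where(cold, w, 0.0)
        delta = gene.params.das_delta_ps
        # usage flows from isoform 1 to isoform 2 with the onset ramp
        fracs[0, :] = fracs[0, :] - delta * w
        fracs[1, :] = fracs[1, :] + delta * w
        if (fracs < -1e-12).any():
            raise SimulationError(
                f"gene {gene.gene_id}: das_delta_ps {delta} exceeds the "
                "base usage of the donor isoform"
            )
        fracs = np.clip(fracs, 0.0, 1.0)

    cols = [f"{b}@{t:g}h" for b, t in tps]
    return pd.DataFrame(
        fracs * total[None, :], index=list(gene.transcript_ids), columns=cols
    )


def _tx_index(genes: Sequence[SimGene]) -> tuple[list[str], np.ndarray]:
    tx_ids: list[str] = []
    lengths: list[float] = []
    for g in genes:
        tx_ids.extend(g.transcript_ids)
        lengths.extend(g.transcript_lengths)
    if len(set(tx_ids)) != len(tx_ids):
        raise SimulationError("duplicate transcript ids across genes")
    return tx_ids, np.asarray(lengths, dtype=float)


def tx2gene_table(genes: Sequence[SimGene]) -> pd.DataFrame:
    rows = [
        (tx, g.gene_id) for g in genes for tx in g.transcript_ids
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id"])


def generate_dataset(
    genes: Sequence[SimGene],
    design: TimeSeriesDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SimDataset:
    """Draw a full per-sample quant-table dataset plus its ground truth.

    Per sample, expected transcript TPM (including the gene's batch
    multiplier) is converted to expected read fractions via effective
    lengths, scaled by a drawn library size, and counts are sampled
    gamma-Poisson around that mean.  TPM is then recomputed from the counts.
    Deterministic for a fixed seed.
    """
    if not genes:
        raise SimulationError("need at least one gene")
    design = design or build_default_design()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    tx_ids, lengths = _tx_index(genes)
    efflens = np.maximum(lengths - EFFLEN_OFFSET, 1.0)
    tp_keys = [timepoint_key(tp) for tp in design.timepoints]

    # expectation surface: transcripts x timepoints
    exp_tpm = pd.concat(
        [expected_profile(g, design) for g in genes], axis=0
    ).loc[tx_ids, tp_keys]
    exp_arr = exp_tpm.to_numpy()

    batches = sorted({s.replicate_batch for s in design.samples})
    gene_ids = [g.gene_id for g in genes]
    if noise.batch_sd > 0:
        batch_log2 = rng.normal(
            0.0, noise.batch_sd, size=(len(gene_ids), len(batches))
        )
    else:
        batch_log2 = np.zeros((len(gene_ids), len(batches)))
    batch_df = pd.DataFrame(batch_log2, index=gene_ids, columns=batches)

    gene_of_tx = np.array(
        [i for i, g in enumerate(genes) for _ in g.transcript_ids]
    )
    lo, hi = noise.libsize_range
    libsizes = pd.Series(
        rng.uniform(lo, hi, size=design.n_samples),
        index=design.sample_ids,
        name="libsize",
    )

    tp_index = {k: j for j, k in enumerate(tp_keys)}
    batch_index = {b: j for j, b in enumerate(batches)}
    tables: dict[str, pd.DataFrame] = {}
    for s in design.samples:
        mu_tpm = exp_arr[:, tp_index[timepoint_key(s.timepoint)]].copy()
        mu_tpm *= 2.0 ** batch_log2[gene_of_tx, batch_index[s.replicate_batch]]
        read_weight = mu_tpm * efflens
        total = read_weight.sum()
        if total <= 0:
            raise SimulationError(
                f"sample {s.sample_id}: all expected abundances are zero"
            )
        mu = read_weight / total * libsizes[s.sample_id]
        if noise.nb_dispersion == 0:
            counts = np.round(mu)
        else:
            shape = 1.0 / noise.nb_dispersion
            lam = rng.gamma(shape, mu * noise.nb_dispersion)
            counts = rng.poisson(lam).astype(float)
        tpm = counts / efflens
        tsum = tpm.sum()
        tpm = tpm / tsum * 1e6 if tsum > 0 else tpm
        tables[s.sample_id] = pd.DataFrame(
            {
                "Name": tx_ids,
                "Length": lengths,
                "EffectiveLength": efflens,
                "TPM": tpm,
                "NumReads": counts,
            }
        )

    truth = SimTruth(
        genes=list(genes),
        seed=seed,
        noise=noise,
        libsizes=libsizes,
        batch_log2_effects=batch_df,
    )
    return SimDataset(
        quant_tables=tables,
        design=design,
        tx2gene=tx2gene_table(genes),
        truth=truth,
    )


def simulate_genes(
    archetype_counts: Mapping[str, int],
    seed: int = 0,
    cold_log2fc: float = 1.5,
    das_delta_ps: float = 0.3,
    onset_h: float = 3.0,
    baseline_log_mean: float = math.log(30.0),
    baseline_log_sd: float = 0.8,
    max_rhythm_amplitude: float = 0.4,
) -> list[SimGene]:
    """Build a gene cohort with randomized baselines, phases and isoforms.

    Effect sizes default to the magnitudes the decision rules downstream are
    designed around: 2.8-fold expression changes (log2FC 1.5) and isoform
    usage swaps of 0.3 with a 3-h onset half-time after the switch.
    """
    rng = np.random.default_rng(seed)
    genes: list[SimGene] = []
    i = 0
    for archetype, n in archetype_counts.items():
        if archetype not in ARCHETYPES:
            raise SimulationError(f"unknown archetype {archetype!r}")
        for _ in range(n):
            i += 1
            gid = f"G{i:05d}_{archetype}"
            baseline = float(
                np.exp(rng.normal(baseline_log_mean, baseline_log_sd))
            )
            amp = float(rng.uniform(0.0, max_rhythm_amplitude))
            phase = float(rng.uniform(0.0, 24.0))
            lfc = 0.0
            if archetype in ("de_up", "transient", "adaptive", "late"):
                lfc = cold_log2fc
            elif archetype == "de_down":
                lfc = -cold_log2fc
            delta = das_delta_ps if archetype == "das_switch" else 0.0
            if archetype == "das_switch":
                ntx = 2
                # donor isoform starts above 0.5 so a delta_ps swap reverses
                # the isoform ranking (an isoform switch, not just a shift)
                fracs = (0.5 + delta / 2, 0.5 - delta / 2)
            else:
                ntx = int(rng.integers(1, 4))
                raw = rng.dirichlet(np.ones(ntx) * 2.0)
                fracs = tuple(float(x) for x in raw)
                fracs = tuple(x / sum(fracs) for x in fracs)
            lengths = tuple(
                float(rng.integers(500, 3000)) for _ in range(ntx)
            )
            genes.append(
                SimGene(
                    gene_id=gid,
                    transcript_ids=tuple(
                        f"{gid}.t{j + 1}" for j in range(ntx)
                    ),
                    transcript_lengths=lengths,
                    base_isoform_fractions=fracs,
                    params=ArchetypeParams(
                        archetype=archetype,
                        baseline_tpm=baseline,
                        rhythm_amplitude=amp,
                        rhythm_phase_h=phase,
                        cold_log2fc=lfc,
                        das_delta_ps=delta,
                        onset_h=onset_h,
                    ),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# on-disk round trip


def write_dataset(dataset: SimDataset, directory: str | Path) -> Path:
    """Write quant tables, design, tx2gene map and truth under ``directory``."""
    if not dataset.quant_tables:
        raise SimulationError("dataset has no samples to write")
    directory = Path(directory)
    quant_dir = directory / "quants"
    quant_dir.mkdir(parents=True, exist_ok=True)
    for sid, table in dataset.quant_tables.items():
        table.to_csv(quant_dir / f"{sid}.quant.sf", sep="\t", index=False)
    dataset.design.write_tsv(directory / "design.tsv")
    dataset.tx2gene.to_csv(directory / "tx2gene.tsv", sep="\t", index=False)
    _write_truth(dataset.truth, directory / "truth.json")
    return directory


def _write_truth(truth: SimTruth, path: Path) -> None:
    payload = {
        "seed": truth.seed,
        "noise": asdict(truth.noise),
        "libsizes": truth.libsizes.to_dict(),
        "batch_log2_effects": {
            gene: {str(b): float(v) for b, v in row.items()}
            for gene, row in truth.batch_log2_effects.iterrows()
        },
        "genes": [
            {
                "gene_id": g.gene_id,
                "transcript_ids": list(g.transcript_ids),
                "transcript_lengths": list(g.transcript_lengths),
                "base_isoform_fractions": list(g.base_isoform_fractions),
                "params": asdict(g.params),
            }
            for g in truth.genes
        ],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    genes = [
        SimGene(
            gene_id=g["gene_id"],
            transcript_ids=tuple(g["transcript_ids"]),
            transcript_lengths=tuple(g["transcript_lengths"]),
            base_isoform_fractions=tuple(g["base_isoform_fractions"]),
            params=ArchetypeParams(**g["params"]),
        )
        for g in payload["genes"]
    ]
    batch = pd.DataFrame(payload["batch_log2_effects"]).T
    batch.columns = [int(c) for c in batch.columns]
    return SimTruth(
        genes=genes,
        seed=payload["seed"],
        noise=NoiseModel(
            nb_dispersion=payload["noise"]["nb_dispersion"],
            batch_sd=payload["noise"]["batch_sd"],
            libsize_range=tuple(payload["noise"]["libsize_range"]),
        ),
        libsizes=pd.Series(payload["libsizes"], name="libsize"),
        batch_log2_effects=batch,
    )
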