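"""Reading quantification tables and deriving count/TPM matrices.

Consumes the tab-separated per-sample output dialect of lightweight
transcript quantifiers (columns Name, Length, EffectiveLength, TPM,
NumReads), plus a two-column transcript-to-gene map, and produces
transcripts x samples and genes x samples matrices.  Counts are derived
from TPM by rescaling to the sample's library size (the "scaled TPM"
convention), and kept as non-negative reals rather than integers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

QUANT_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")
TPM_SUM_TOL = 1e-3  # relative tolerance on the 1e6 TPM total


class QuantIOError(ValueError):
    pass


def validate_quant_table(table: pd.DataFrame, origin: str = "<table>") -> None:
    missing = [c for c in QUANT_COLUMNS if c not in table.columns]
    if missing:
        raise QuantIOError(f"{origin}: missing column(s) {missing}")
    dup = table["Name"][table["Name"].duplicated()]
    if len(dup):
        raise QuantIOError(
            f"{origin}: duplicate transcript id(s) {sorted(set(dup))[:5]}"
        )
    for col in ("Length", "EffectiveLength", "TPM", "NumReads"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() | (vals < 0)]
        if len(bad):
            row = bad[0]
            raise QuantIOError(
                f"{origin}: non-numeric or negative {col} at row {row} "
                f"(transcript {table.loc[row, 'Name']!r})"
            )
    total = float(table["TPM"].sum())
    if total > 0 and abs(total - 1e6) > TPM_SUM_TOL * 1e6:
        raise QuantIOError(
            f"{origin}: TPM column sums to {total:.1f}, expected ~1e6"
        )


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read and validate one per-sample quantification table.

    Unknown extra columns are dropped; the five canonical columns are
    required and checked for duplicates and negative values.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    validate_quant_table(table, origin=str(path))
    table = table.loc[:, list(QUANT_COLUMNS)].copy()
    for col in ("Length", "EffectiveLength", "TPM", "NumReads"):
        table[col] = table[col].astype(float)
    return table


def read_tx2gene(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise QuantIOError(f"{path}: tx2gene map needs two columns")
    table = table.iloc[:, :2]
    table.columns = ["transcript_id", "gene_id"]
    dup = table["transcript_id"][table["transcript_id"].duplicated()]
    if len(dup):
        raise QuantIOError(
            f"{path}: transcript(s) mapped more than once: "
            f"{sorted(set(dup))[:5]}"
        )
    return table


def read_quant_dir(
    directory: str | Path, sample_ids: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Read every ``*.quant.sf`` table under ``directory``.

    Sample ids are the file names minus the ``.quant.sf`` suffix.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.quant.sf"))
    if not paths:
        raise QuantIOError(f"no *.quant.sf files under {directory}")
    tables = {p.name[: -len(".quant.sf")]: read_quant_table(p) for p in paths}
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in tables]
        if missing:
            raise QuantIOError(f"quant tables missing for samples {missing}")
        tables = {s: tables[s] for s in sample_ids}
    return tables


def tpm_matrix(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Transcripts x samples TPM matrix; sample order follows the mapping."""
    _check_common_universe(tables)
    cols = {}
    for sid, t in tables.items():
        cols[sid] = t.set_index("Name")["TPM"]
    first = next(iter(tables.values()))["Name"]
    out = pd.DataFrame(cols).loc[first].astype(float)
    out.index.name = "transcript_id"
    return out


def _check_common_universe(tables: Mapping[str, pd.DataFrame]) -> None:
    ids = None
    first_sid = None
    for sid, t in tables.items():
        cur = set(t["Name"])
        if ids is None:
            ids, first_sid = cur, sid
        elif cur != ids:
            diff = sorted(cur.symmetric_difference(ids))
            raise QuantIOError(
                f"transcript sets differ between {first_sid!r} and {sid!r}: "
                f"symmetric difference {diff[:10]}"
                + ("..." if len(diff) > 10 else "")
            )


def counts_from_tpm(
    tables: Mapping[str, pd.DataFrame],
    libsizes: Mapping[str, float] | str = "from_est_reads",
) -> pd.DataFrame:
    """Transcript counts rescaled from TPM: count = TPM * libsize / 1e6.

    With the default ``"from_est_reads"``, each sample's library size is the
    sum of its estimated read counts, so count columns sum to the sample's
    total reads (the scaled-TPM convention).
    """
    _check_common_universe(tables)
    tpm = tpm_matrix(tables)
    sizes: dict[str, float] = {}
    for sid, t in tables.items():
        if libsizes == "from_est_reads":
            sizes[sid] = float(t["NumReads"].sum())
        else:
            if sid not in libsizes:
                raise QuantIOError(f"no library size given for {sid!r}")
            sizes[sid] = float(libsizes[sid])
        if sizes[sid] < 0:
            raise QuantIOError(f"negative library size for {sid!r}")
    for sid in tpm.columns:
        if tpm[sid].sum() == 0:
            warnings.warn(
                f"sample {sid!r} has an all-zero TPM column", stacklevel=2
            )
    counts = tpm * pd.Series(sizes)[tpm.columns] / 1e6
    counts.index.name = "transcript_id"
    return counts


def aggregate_gene_level(
    counts_tx: pd.DataFrame, tx2gene: pd.DataFrame
) -> pd.DataFrame:
    """Gene counts as the per-sample sum of member transcript counts."""
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    unmapped = counts_tx.index.difference(mapping.index)
    if len(unmapped):
        raise QuantIOError(
            f"transcript(s) missing from the tx2gene map: "
            f"{list(unmapped[:10])}"
        )
    gene_of = mapping.loc[counts_tx.index]
    out = counts_tx.groupby(gene_of.to_numpy()).sum()
    out.index.name = "gene_id"
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
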