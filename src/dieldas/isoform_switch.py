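"""Detection of rapid, significant isoform switches in TPM time-profiles.

For every pair of isoforms of a gene, the replicate-mean abundance profiles
are scanned for points where their order reverses.  Each strict sign change
of the mean difference between adjacent time-points is a candidate switch;
it is scored by how consistently one isoform dominates before the switch and
the other after (the mean of the two frequencies over individual samples),
and each flanking interval is tested for separation with a two-sample
Welch t-test on the per-time-point replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study_design import TimeSeriesDesign, timepoint_key


class SwitchError(ValueError):
    pass


@dataclass(frozen=True)
class SwitchEvent:
    gene_id: str
    isoform_before: str        # the isoform on top before the switch
    isoform_after: str         # the isoform on top after the switch
    switch_time_h: float       # interpolated crossing (absolute hours)
    before_times: tuple[float, ...]
    after_times: tuple[float, ...]
    score: float               # 0..1 dominance consistency
    before_pvalue: float
    after_pvalue: float
    mean_diff_before: float    # |mean separation| within the before interval
    mean_diff_after: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.isoform_before, self.isoform_after)


def _interval_stats(
    a_means: np.ndarray, b_means: np.ndarray
) -> tuple[float, float]:
    """Welch t-test p-value and absolute mean separation on an interval."""
    diff = float(abs(a_means.mean() - b_means.mean()))
    if len(a_means) < 2:
        return 1.0, diff
    if a_means.var() + b_means.var() < 1e-24:
        # degenerate noise-free interval: separation alone decides
        return (0.0 if diff > 0 else 1.0), diff
    res = stats.ttest_ind(a_means, b_means, equal_var=False)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return p, diff


def detect_switches(
    tpm_tx: pd.DataFrame,
    tx2gene: pd.DataFrame,
    design: TimeSeriesDesign,
    min_score: float = 0.5,
    max_p: float = 0.05,
    min_interval_points: int = 2,
) -> list[SwitchEvent]:
    """Scan all isoform pairs of every multi-isoform gene for switches.

    Candidates require a strict sign change of the replicate-mean difference
    between adjacent time-points (exact ties break a crossing); they are kept
    when the dominance score reaches ``min_score``, both flanking intervals
    contain at least ``min_interval_points`` time-points and both interval
    t-tests reach ``max_p``.  Events are sorted by switch time.
    """
    tps = sorted(design.timepoints, key=lambda tp: tp[1])
    times = np.array([tp[1] for tp in tps])
    if len(tps) < 2 * min_interval_points:
        raise SwitchError("design too short for the requested intervals")
    sample_sets = [
        [s.sample_id for s in design.samples_at(tp)] for tp in tps
    ]
    means = pd.DataFrame(
        {
            timepoint_key(tp): tpm_tx[sids].mean(axis=1)
            for tp, sids in zip(tps, sample_sets)
        }
    )
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    gene_of = mapping.loc[tpm_tx.index]

    events: list[SwitchEvent] = []
    for gene, members in tpm_tx.index.groupby(gene_of.to_numpy()).items():
        members = list(members)
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                events.extend(
                    _pair_events(
                        gene,
                        members[i],
                        members[j],
                        means,
                        tpm_tx,
                        times,
                        sample_sets,
                        min_score,
                        max_p,
                        min_interval_points,
                    )
                )
    events.sort(key=lambda e: (e.switch_time_h, e.gene_id))
    return events


def _pair_events(
    gene: str,
    tx_a: str,
    tx_b: str,
    means: pd.DataFrame,
    tpm_tx: pd.DataFrame,
    times: np.ndarray,
    sample_sets: list[list[str]],
    min_score: float,
    max_p: float,
    min_interval_points: int,
) -> list[SwitchEvent]:
    d = means.loc[tx_a].to_numpy() - means.loc[tx_b].to_numpy()
    crossings = [
        k for k in range(len(d) - 1) if d[k] * d[k + 1] < 0
    ]
    if not crossings:
        return []
    boundaries = [-1] + crossings + [len(d) - 1]
    out: list[SwitchEvent] = []
    for c_idx, k in enumerate(crossings):
        before_idx = list(range(boundaries[c_idx] + 1, k + 1))
        after_idx = list(range(k + 1, boundaries[c_idx + 2] + 1))
        if (
            len(before_idx) < min_interval_points
            or len(after_idx) < min_interval_points
        ):
            continue
        # linear interpolation of the zero crossing between times k, k+1
        t0, t1 = times[k], times[k + 1]
        frac = d[k] / (d[k] - d[k + 1])
        switch_time = float(t0 + frac * (t1 - t0))

        top_before, top_after = (tx_a, tx_b) if d[k] > 0 else (tx_b, tx_a)
        score = 0.5 * (
            _dominance(tpm_tx, top_before, top_after, sample_sets, before_idx)
            + _dominance(tpm_tx, top_after, top_before, sample_sets, after_idx)
        )
        a_before = means.loc[tx_a].to_numpy()[before_idx]
        b_before = means.loc[tx_b].to_numpy()[before_idx]
        a_after = means.loc[tx_a].to_numpy()[after_idx]
        b_after = means.loc[tx_b].to_numpy()[after_idx]
        p_before, diff_before = _interval_stats(a_before, b_before)
        p_after, diff_after = _interval_stats(a_after, b_after)
        if score >= min_score and p_before <= max_p and p_after <= max_p:
            out.append(
                SwitchEvent(
                    gene_id=gene,
                    isoform_before=top_before,
                    isoform_after=top_after,
                    switch_time_h=switch_time,
                    before_times=tuple(times[before_idx]),
                    after_times=tuple(times[after_idx]),
                    score=float(score),
                    before_pvalue=p_before,
                    after_pvalue=p_after,
                    mean_diff_before=diff_before,
                    mean_diff_after=diff_after,
                )
            )
    return out


def _dominance(
    tpm_tx: pd.DataFrame,
    top: str,
    other: str,
    sample_sets: list[list[str]],
    idx: list[int],
) -> float:
    """Fraction of individual samples in the interval where ``top`` > ``other``."""
    sids = [sid for k in idx for sid in sample_sets[k]]
    a = tpm_tx.loc[top, sids].to_numpy(dtype=float)
    b = tpm_tx.loc[other, sids].to_numpy(dtype=float)
    return float(np.mean(a > b))


def filter_rapid(
    events: Sequence[SwitchEvent],
    design: TimeSeriesDesign,
    window_h: float = 3.0,
) -> pd.DataFrame:
    """Keep switches within ``window_h`` hours after the cold transition.

    Returns a table of the kept events annotated with the time since the
    transition; empty input yields an empty table.
    """
    transition = design.transition_time_h()
    rows = []
    for e in events:
        dt = e.switch_time_h - transition
        if 0 <= dt <= window_h:
            rows.append(
                {
                    "gene_id": e.gene_id,
                    "isoform_before": e.isoform_before,
                    "isoform_after": e.isoform_after,
                    "switch_time_h": e.switch_time_h,
                    "hours_after_transition": dt,
                    "score": e.score,
                    "before_pvalue": e.before_pvalue,
                    "after_pvalue": e.after_pvalue,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "isoform_before",
            "isoform_after",
            "switch_time_h",
            "hours_after_transition",
            "score",
            "before_pvalue",
            "after_pvalue",
        ],
    )


def events_table(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "isoform_before": e.isoform_before,
                "isoform_after": e.isoform_after,
                "switch_time_h": e.switch_time_h,
                "score": e.score,
                "before_pvalue": e.before_pvalue,
                "after_pvalue": e.after_pvalue,
                "mean_diff_before": e.mean_diff_before,
                "mean_diff_after": e.mean_diff_after,
            }
            for e in events
        ],
        columns=[
            "gene_id",
            "isoform_before",
            "isoform_after",
            "switch_time_h",
            "score",
            "before_pvalue",
            "after_pvalue",
            "mean_diff_before",
            "mean_diff_after",
        ],
    )
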