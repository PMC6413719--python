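"""Bench-validation arithmetic: ddCt fold changes, splicing ratios from
capillary-electrophoresis peak intensities, and temperature-step t-tests.

These are the statistics used to confirm sequencing-derived calls at the
bench: quantitative RT-PCR relative expression via the delta-delta-Ct
method against a reference gene, isoform proportions from fluorescent
RT-PCR product peaks (relative fluorescence units), and per-condition
Student t-tests of each temperature step against the warm control with
the conventional star notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CtRecord:
    """Paired qPCR cycle thresholds for one condition."""

    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, v in (
            ("ct_target", self.ct_target),
            ("ct_reference", self.ct_reference),
        ):
            if not 0 < v < 45:
                raise ValidationError(
                    f"{self.condition}: {name} {v} outside (0, 45) cycles"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_relative_expression(treated: CtRecord, control: CtRecord) -> float:
    """Fold change 2**(-ddCt) of treated vs control, reference-normalized."""
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def splicing_ratios(peaks: Mapping[str, float]) -> dict[str, float]:
    """Per-product proportions of summed peak intensity (RFUs)."""
    if not peaks:
        raise ValidationError("no peaks given")
    vals = {k: float(v) for k, v in peaks.items()}
    if any(v < 0 for v in vals.values()):
        raise ValidationError("peak intensities must be >= 0")
    total = sum(vals.values())
    if total <= 0:
        raise ValidationError("all peaks are zero; ratios undefined")
    return {k: v / total for k, v in vals.items()}


def significance_stars(
    p: float, levels: Sequence[tuple[float, str]] = ((0.001, "***"), (0.01, "**"))
) -> str:
    """Star label for a p-value; thresholds checked from most stringent."""
    for cut, stars in sorted(levels):
        if p < cut:
            return stars
    return ""


def step_comparison(
    measurements: Mapping[str, Sequence[float]],
    control_label: str,
    equal_var: bool = True,
    levels: Sequence[tuple[float, str]] = ((0.001, "***"), (0.01, "**")),
) -> pd.DataFrame:
    """Two-sample t-test of every condition against the control.

    Returns a table (one row per non-control condition) with the mean
    difference, p-value and star label.  Student's equal-variance test by
    default; set ``equal_var=False`` for Welch.
    """
    if control_label not in measurements:
        raise ValidationError(f"control {control_label!r} not in measurements")
    control = np.asarray(measurements[control_label], dtype=float)
    if control.size < 2:
        raise ValidationError("control needs >= 2 replicates")
    rows = []
    for label, values in measurements.items():
        if label == control_label:
            continue
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValidationError(f"condition {label!r} needs >= 2 replicates")
        res = stats.ttest_ind(v, control, equal_var=equal_var)
        p = float(res.pvalue)
        rows.append(
            {
                "condition": label,
                "n": int(v.size),
                "mean": float(v.mean()),
                "mean_diff": float(v.mean() - control.mean()),
                "t": float(res.statistic),
                "pvalue": p,
                "stars": significance_stars(p, levels),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "n", "mean", "mean_diff", "t", "pvalue", "stars"],
    )
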