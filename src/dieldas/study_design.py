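"""Diel time-series design and time-of-day-matched contrast construction.

The experimental layout modelled here is a temperature-shift time course on a
24-h light/dark cycle: plants sampled every 3 h over the last warm day, then
over the first and fourth day after a shift to cold applied at dusk.  Because
every cold time-point has a warm time-point at the identical time of day,
contrasts between matched time-points cancel diel (time-of-day) variation and
isolate the temperature response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CONTROL_BLOCK = "control20"
COLD_DAY1 = "cold_day1"
COLD_DAY4 = "cold_day4"

#: hours between consecutive harvests in the default design
DEFAULT_SPACING_H = 3.0


class DesignError(ValueError):
    """Raised when a design or contrast request is inconsistent."""


@dataclass(frozen=True)
class SampleInfo:
    """One harvested sample.

    ``time_of_day_h`` is on a 24-h clock with dusk = 0 (the temperature switch
    is applied at dusk, so the clock is anchored at the intervention).
    ``absolute_time_h`` counts hours since the start of the series.
    """

    sample_id: str
    block: str
    time_of_day_h: float
    absolute_time_h: float
    replicate_batch: int

    def __post_init__(self) -> None:
        if not 0 <= self.time_of_day_h < 24:
            raise DesignError(
                f"sample {self.sample_id}: time_of_day_h {self.time_of_day_h} "
                "outside [0, 24)"
            )
        if self.replicate_batch < 1:
            raise DesignError(
                f"sample {self.sample_id}: replicate_batch must be >= 1"
            )
        if not math.isclose(
            self.time_of_day_h, self.absolute_time_h % 24.0, abs_tol=1e-9
        ):
            raise DesignError(
                f"sample {self.sample_id}: time_of_day_h "
                f"{self.time_of_day_h} != absolute_time_h mod 24 "
                f"({self.absolute_time_h % 24.0})"
            )

    @property
    def timepoint(self) -> tuple[str, float]:
        """Key identifying this sample's (block, absolute time) cell."""
        return (self.block, self.absolute_time_h)


@dataclass
class TimeSeriesDesign:
    """An ordered collection of samples on the diel time grid."""

    samples: list[SampleInfo]
    control_block: str = CONTROL_BLOCK

    def __post_init__(self) -> None:
        seen: set[tuple[str, float, int]] = set()
        for s in self.samples:
            key = (s.block, s.absolute_time_h, s.replicate_batch)
            if key in seen:
                raise DesignError(
                    f"duplicate (block, absolute_time_h, replicate_batch) {key}"
                )
            seen.add(key)
        if self.control_block not in self.blocks:
            raise DesignError(
                f"control block {self.control_block!r} absent from design"
            )

    @property
    def blocks(self) -> list[str]:
        """Block labels in first-appearance order."""
        out: list[str] = []
        for s in self.samples:
            if s.block not in out:
                out.append(s.block)
        return out

    @property
    def timepoints(self) -> list[tuple[str, float]]:
        """Distinct (block, absolute_time_h) cells, ordered by appearance."""
        out: list[tuple[str, float]] = []
        for s in self.samples:
            if s.timepoint not in out:
                out.append(s.timepoint)
        return out

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_replicates(self) -> int:
        return len({s.replicate_batch for s in self.samples})

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_at(self, timepoint: tuple[str, float]) -> list[SampleInfo]:
        return [s for s in self.samples if s.timepoint == timepoint]

    def transition_time_h(self) -> float:
        """Absolute time of the switch to cold.

        Taken as the first sampled time of the earliest non-control block; the
        switch is applied at dusk, which is also the first cold harvest.
        """
        cold = [
            s.absolute_time_h
            for s in self.samples
            if s.block != self.control_block
        ]
        if not cold:
            raise DesignError("design has no non-control samples")
        return min(cold)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "block": [s.block for s in self.samples],
                "time_of_day_h": [s.time_of_day_h for s in self.samples],
                "absolute_time_h": [s.absolute_time_h for s in self.samples],
                "replicate_batch": [s.replicate_batch for s in self.samples],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, control_block: str = CONTROL_BLOCK
    ) -> "TimeSeriesDesign":
        required = {
            "sample_id",
            "block",
            "time_of_day_h",
            "absolute_time_h",
            "replicate_batch",
        }
        missing = required - set(table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        samples = [
            SampleInfo(
                sample_id=str(r.sample_id),
                block=str(r.block),
                time_of_day_h=float(r.time_of_day_h),
                absolute_time_h=float(r.absolute_time_h),
                replicate_batch=int(r.replicate_batch),
            )
            for r in table.itertuples()
        ]
        return cls(samples=samples, control_block=control_block)

    @classmethod
    def read_tsv(
        cls, path: str | Path, control_block: str = CONTROL_BLOCK
    ) -> "TimeSeriesDesign":
        return cls.from_table(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ContrastGroup:
    """A cold time-point paired with its time-of-day-matched control."""

    label: str
    block: str
    treatment_timepoint: tuple[str, float]
    reference_timepoint: tuple[str, float]
    time_of_day_h: float
    ordinal: int

    @property
    def is_first_in_block(self) -> bool:
        return self.ordinal == 1


def timepoint_key(timepoint: tuple[str, float]) -> str:
    """Canonical string key for a (block, absolute time) cell."""
    return f"{timepoint[0]}@{timepoint[1]:g}h"


def _grid(start_h: float, n: int, spacing_h: float) -> list[float]:
    return [start_h + i * spacing_h for i in range(n)]


def build_default_design(n_replicates: int = 3) -> TimeSeriesDesign:
    """Canonical cold-shift design: 26 time-points x 3 replicates = 78 samples.

    Control block: the last warm day, 8 harvests at 3-h spacing starting at
    dusk (absolute hours 0..21).  The switch to cold occurs at the following
    dusk (absolute hour 24).  Each cold day is harvested from its dusk through
    the following dusk inclusive (9 harvests): the first cold day at absolute
    hours 24..48 and the fourth cold day at 96..120.
    """
    layout: list[tuple[str, list[float]]] = [
        (CONTROL_BLOCK, _grid(0.0, 8, DEFAULT_SPACING_H)),
        (COLD_DAY1, _grid(24.0, 9, DEFAULT_SPACING_H)),
        (COLD_DAY4, _grid(96.0, 9, DEFAULT_SPACING_H)),
    ]
    samples: list[SampleInfo] = []
    for block, times in layout:
        for i, t in enumerate(times, start=1):
            for rep in range(1, n_replicates + 1):
                samples.append(
                    SampleInfo(
                        sample_id=f"{block}.T{i}.rep{rep}",
                        block=block,
                        time_of_day_h=t % 24.0,
                        absolute_time_h=t,
                        replicate_batch=rep,
                    )
                )
    return TimeSeriesDesign(samples=samples)


def build_contrasts(design: TimeSeriesDesign) -> list[ContrastGroup]:
    """One contrast per non-control time-point vs its matched control.

    Matching is by time of day on the 24-h clock (wrap allowed), so a block
    sampled through the following dusk pairs both of its dusk time-points with
    the single control dusk.  Output is sorted by block (appearance order)
    then absolute time; ordinals restart at 1 in each block.
    """
    control_by_tod: dict[float, tuple[str, float]] = {}
    control_index: dict[float, int] = {}
    ctrl_points = sorted(
        tp for tp in design.timepoints if tp[0] == design.control_block
    )
    for i, tp in enumerate(ctrl_points, start=1):
        tod = round(tp[1] % 24.0, 9)
        if tod in control_by_tod:
            raise DesignError(
                f"control block has duplicate time of day {tod} h"
            )
        control_by_tod[tod] = tp
        control_index[tod] = i

    contrasts: list[ContrastGroup] = []
    for block in design.blocks:
        if block == design.control_block:
            continue
        points = sorted(
            tp for tp in design.timepoints if tp[0] == block
        )
        for ordinal, tp in enumerate(points, start=1):
            tod = round(tp[1] % 24.0, 9)
            if tod not in control_by_tod:
                raise DesignError(
                    f"no control time-point matches {block} at time of day "
                    f"{tod} h (absolute {tp[1]} h)"
                )
            ref = control_by_tod[tod]
            contrasts.append(
                ContrastGroup(
                    label=(
                        f"{block}.T{ordinal}_vs_"
                        f"{design.control_block}.T{control_index[tod]}"
                    ),
                    block=block,
                    treatment_timepoint=tp,
                    reference_timepoint=ref,
                    time_of_day_h=tod,
                    ordinal=ordinal,
                )
            )
    return contrasts


def consecutive_pairs(
    contrasts: Sequence[ContrastGroup],
) -> list[tuple[int, int]]:
    """Indices of adjacent contrast pairs within a block.

    Adjacency across the block boundary is never counted: the last contrast of
    one cold day and the first of the next sampled day are days apart in real
    time.
    """
    pairs: list[tuple[int, int]] = []
    for i in range(len(contrasts) - 1):
        a, b = contrasts[i], contrasts[i + 1]
        if a.block == b.block and b.ordinal == a.ordinal + 1:
            pairs.append((i, i + 1))
    return pairs
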