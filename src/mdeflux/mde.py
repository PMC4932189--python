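"""MDE series: maximal observed dispersal events per million-year slice.

For each integer time point t (an age in Ma), the raw MDE value is the
number of events whose 95% HPD interval, rounded to the nearest full
million years, covers t.  Summing interval coverage rather than point
estimates makes the statistic robust to dating uncertainty: overlapping
intervals are taken as evidence of concerted (geo-)dispersal.

Conventions (fixed here so every downstream number is reproducible):

* time points are integer Ma labels ``t = 0 .. t_max`` and an event whose
  rounded interval is ``(y, o)`` covers every integer ``y <= t <= o``
  inclusive, so a point interval covers exactly one slice;
* rounding uses half-away-from-zero (2.5 Ma -> 3 Ma), which is monotone
  and therefore order-preserving on interval bounds;
* events entirely older than ``t_max`` after rounding are dropped with a
  warning, intervals straddling ``t_max`` are clipped;
* series are stored oldest-first (``t_max`` down to the youngest retained
  slice), the orientation in which change points are read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .events import DIRECTIONS, TAXON_GROUPS, DispersalEvent, EventTable

__all__ = [
    "TimeGrid",
    "MDESeries",
    "round_interval",
    "compute_mde",
    "smooth_series",
    "stratified_mde",
    "avian_bias_cutoff",
    "truncate_series",
    "avian_nonavian_split",
    "NON_AVIAN_GROUPS",
]

#: Taxon groups pooled as the "non-avian" reference in the recency-bias
#: comparison (all groups except birds).
NON_AVIAN_GROUPS: frozenset[str] = TAXON_GROUPS - {"bird"}


@dataclass(frozen=True)
class TimeGrid:
    """Integer 1-Myr time grid from the present back to ``t_max`` Ma."""

    t_max: int = 70

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")

    @property
    def ages(self) -> np.ndarray:
        """Grid ages in Ma, oldest first: ``t_max, t_max-1, ..., 0``."""
        return np.arange(self.t_max, -1, -1)

    def __len__(self) -> int:
        return self.t_max + 1


@dataclass
class MDESeries:
    """One MDE trajectory on a (possibly truncated) integer time grid.

    ``ages`` run oldest-first; ``values`` align with them.  ``stage`` tells
    whether the values are raw per-slice counts or sliding-window means;
    ``truncation_age`` records the youngest age retained after the
    recency-bias cut (``None`` if never truncated).
    """

    grid: TimeGrid
    ages: np.ndarray
    values: np.ndarray
    label: str = "pooled"
    stage: Literal["raw", "smoothed"] = "raw"
    truncation_age: int | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ValueError("ages and values must have identical length")
        if len(self.ages) == 0:
            raise ValueError("series must cover at least one time point")

    def value_at(self, t: int) -> float:
        """Value at age ``t`` Ma (raises if ``t`` not on the grid)."""
        idx = np.nonzero(self.ages == t)[0]
        if idx.size != 1:
            raise KeyError(f"age {t} Ma not on this series' grid")
        return float(self.values[idx[0]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ma": self.ages,
                "value": self.values,
                "label": self.label,
                "stage": self.stage,
            }
        )


def round_interval(event: DispersalEvent) -> tuple[int, int]:
    """Round an event's HPD bounds to the nearest full million years.

    Ties (x.5) round half away from zero.  Returns ``(y, o)`` with
    ``y <= o``; no grid clipping happens here.
    """
    y = int(math.floor(event.hpd_young_ma + 0.5))
    o = int(math.floor(event.hpd_old_ma + 0.5))
    return y, o


def compute_mde(table: EventTable, grid: TimeGrid | None = None,
                label: str = "pooled") -> MDESeries:
    """Raw MDE: per-slice count of events whose rounded interval covers it.

    Each event contributes once to every slice in its (clipped) interval;
    events are treated as independent even within a source phylogeny.
    Events rounding entirely older than the grid are excluded with a
    warning, since the analysis span ends at ``grid.t_max``.
    """
    grid = grid or TimeGrid()
    counts = np.zeros(len(grid), dtype=float)
    ages = grid.ages  # t_max .. 0, so index of age t is t_max - t
    for ev in table:
        y, o = round_interval(ev)
        if y > grid.t_max:
            warnings.warn(
                f"event {ev.event_id!r} rounds to ({y}, {o}) Ma, entirely "
                f"older than the {grid.t_max} Ma analysis span; excluded",
                stacklevel=2,
            )
            continue
        o = min(o, grid.t_max)
        # ages are descending: age o sits at index t_max - o
        counts[grid.t_max - o : grid.t_max - y + 1] += 1.0
    return MDESeries(grid=grid, ages=ages, values=counts, label=label, stage="raw")


def smooth_series(series: MDESeries, window_myr: int = 5) -> MDESeries:
    """Sliding-window mean with an odd, centred window of ``window_myr`` Myr.

    At the two ends the window truncates to the available grid points, so
    the output has the same length as the input.  ``window_myr=1`` is the
    identity.
    """
    if window_myr < 1 or window_myr % 2 == 0:
        raise ValueError(
            f"window must be a positive odd number of Myr, got {window_myr}"
        )
    smoothed = (
        pd.Series(series.values)
        .rolling(window=window_myr, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(series, values=smoothed, stage="smoothed")


def stratified_mde(
    table: EventTable,
    grid: TimeGrid | None = None,
    by: Literal["direction", "taxon"] = "direction",
) -> dict[str, MDESeries]:
    """One raw MDE series per stratum of ``direction`` or ``taxon`` group.

    Every enumeration member gets a series (all-zero if unrepresented), and
    the pointwise sum over strata equals the pooled series, because each
    event belongs to exactly one stratum.
    """
    grid = grid or TimeGrid()
    if by == "direction":
        labels = sorted(DIRECTIONS)
        key = lambda ev: ev.direction  # noqa: E731
    elif by == "taxon":
        labels = sorted(TAXON_GROUPS)
        key = lambda ev: ev.taxon_group  # noqa: E731
    else:
        raise ValueError(f"by must be 'direction' or 'taxon', got {by!r}")
    buckets: dict[str, list[DispersalEvent]] = {lab: [] for lab in labels}
    for ev in table:
        buckets[key(ev)].append(ev)
    return {
        lab: compute_mde(EventTable(evs, metadata=dict(table.metadata)),
                         grid, label=lab)
        for lab, evs in buckets.items()
    }


def avian_bias_cutoff(avian: MDESeries, non_avian: MDESeries) -> int:
    """Age (Ma) below which the record is dominated by avian oversampling.

    Bird phylogenies in the compilation sample down to subspecies, so the
    avian MDE rises sharply towards the present while every other group's
    declines — a sampling artefact, not biology.  The correction removes
    all slices younger than the point where the smoothed avian and
    non-avian trajectories intersect.

    Returns the youngest age ``t*`` at which ``sign(avian - non_avian)``
    differs from the next-younger slice (the crossing closest to the
    present); ``0`` if the two series never cross (no truncation needed).
    Exact-tie plateaus resolve to their youngest point.
    """
    if not np.array_equal(avian.ages, non_avian.ages):
        raise ValueError("avian and non-avian series must share a grid")
    diff = avian.values - non_avian.values
    if not np.any(diff > 0):
        return 0  # avian never exceeds non-avian: nothing to truncate
    sign = np.sign(diff)
    # ages descending: the youngest slices are at the end of the arrays
    for i in range(len(sign) - 1, 0, -1):
        if sign[i] != sign[i - 1]:
            return int(avian.ages[i - 1])
    return 0


def truncate_series(series: MDESeries, cutoff: int) -> MDESeries:
    """Drop all slices younger than ``cutoff`` Ma, recording the cut.

    ``cutoff=0`` is the identity (apart from stamping ``truncation_age``);
    ``cutoff=t_max`` leaves the single oldest slice.
    """
    if cutoff < 0 or cutoff > series.grid.t_max:
        raise ValueError(
            f"cutoff {cutoff} Ma outside the grid [0, {series.grid.t_max}]"
        )
    keep = series.ages >= cutoff
    return replace(
        series,
        ages=series.ages[keep],
        values=series.values[keep],
        truncation_age=cutoff,
    )


def avian_nonavian_split(
    table: EventTable,
    grid: TimeGrid | None = None,
    window_myr: int = 5,
) -> tuple[MDESeries, MDESeries]:
    """Smoothed avian vs pooled non-avian MDE series for the bias cut."""
    from .events import filter_events

    grid = grid or TimeGrid()
    avian = compute_mde(filter_events(table, taxa={"bird"}), grid, label="avian")
    non_avian = compute_mde(
        filter_events(table, taxa=NON_AVIAN_GROUPS), grid, label="non_avian"
    )
    return smooth_series(avian, window_myr), smooth_series(non_avian, window_myr)
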