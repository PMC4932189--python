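"""Dispersal-event tables: the raw material of the meta-analysis.

Every analysis in this package starts from a table of inferred dispersal
(range-shift) events between the Indian subcontinent and mainland Asia.
Each event is a node in a time-calibrated phylogeny at which ancestral-area
reconstruction inferred movement in one direction, together with the 95%
highest-posterior-density (HPD) interval of the divergence time at that
node, in Ma (million years before present).

The on-disk format is a UTF-8, tab-separated file with a header row and
exactly these columns::

    event_id  dataset_id  taxon_group  direction  hpd_old_ma  hpd_young_ma

Events from the same source phylogeny (``dataset_id``) are deliberately
kept as independent observations and are never deduplicated or
down-weighted; pooling over phylogenies is the point of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "DIRECTIONS",
    "TAXON_GROUPS",
    "COLUMNS",
    "DispersalEvent",
    "EventTable",
    "EventValidationError",
    "read_events",
    "write_events",
    "filter_events",
]

#: Admissible dispersal directions between the two landmasses.
DIRECTIONS: frozenset[str] = frozenset({"india_to_asia", "asia_to_india"})

#: Admissible organismal groups. ``bird`` is singled out downstream for the
#: recency-bias correction; everything else is "non-avian".
TAXON_GROUPS: frozenset[str] = frozenset(
    {
        "amphibian",
        "non_avian_reptile",
        "bird",
        "arthropod",
        "plant",
        "teleost_fish",
        "mammal",
        "other",
    }
)

#: Exact header of the TSV dialect, in order.
COLUMNS: tuple[str, ...] = (
    "event_id",
    "dataset_id",
    "taxon_group",
    "direction",
    "hpd_old_ma",
    "hpd_young_ma",
)


class EventValidationError(ValueError):
    """A row or field of an event table violates the schema."""


@dataclass(frozen=True)
class DispersalEvent:
    """One inferred range shift with its dated-node uncertainty.

    Parameters
    ----------
    event_id
        Opaque identifier, unique within a table.
    dataset_id
        Source phylogeny the event was extracted from.
    taxon_group
        One of :data:`TAXON_GROUPS`.
    direction
        One of :data:`DIRECTIONS`.
    hpd_old_ma, hpd_young_ma
        Older and younger bounds (Ma) of the 95% HPD interval of the
        divergence time at the node where the shift was inferred.
    """

    event_id: str
    dataset_id: str
    taxon_group: str
    direction: str
    hpd_old_ma: float
    hpd_young_ma: float

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise EventValidationError(
                f"event {self.event_id!r}: unknown taxon_group {self.taxon_group!r} "
                f"(expected one of {sorted(TAXON_GROUPS)})"
            )
        if self.direction not in DIRECTIONS:
            raise EventValidationError(
                f"event {self.event_id!r}: unknown direction {self.direction!r} "
                f"(expected one of {sorted(DIRECTIONS)})"
            )
        old = float(self.hpd_old_ma)
        young = float(self.hpd_young_ma)
        if not (old == old and young == young):  # NaN guard
            raise EventValidationError(
                f"event {self.event_id!r}: unparseable or missing HPD bound"
            )
        if young < 0:
            raise EventValidationError(
                f"event {self.event_id!r}: hpd_young_ma={young} is negative"
            )
        if old < young:
            raise EventValidationError(
                f"event {self.event_id!r}: hpd_old_ma={old} < hpd_young_ma={young}"
            )


class EventTable:
    """Ordered, validated collection of :class:`DispersalEvent`.

    Row order is preserved through IO and filtering; ``metadata`` carries
    free-form provenance (never interpreted by the computations).
    """

    def __init__(
        self,
        events: Iterable[DispersalEvent] = (),
        metadata: Mapping[str, str] | None = None,
    ) -> None:
        self.events: list[DispersalEvent] = list(events)
        self.metadata: dict[str, str] = dict(metadata or {})
        seen: set[str] = set()
        for ev in self.events:
            if ev.event_id in seen:
                raise EventValidationError(f"duplicate event_id {ev.event_id!r}")
            seen.add(ev.event_id)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[DispersalEvent]:
        return iter(self.events)

    def __getitem__(self, i: int) -> DispersalEvent:
        return self.events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.events == other.events

    def to_dataframe(self) -> pd.DataFrame:
        """Return the table as a :class:`pandas.DataFrame` in schema order."""
        return pd.DataFrame(
            [
                (e.event_id, e.dataset_id, e.taxon_group, e.direction,
                 e.hpd_old_ma, e.hpd_young_ma)
                for e in self.events
            ],
            columns=list(COLUMNS),
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metadata: Mapping[str, str] | None = None
    ) -> "EventTable":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise EventValidationError(f"missing required column(s): {missing}")
        events = []
        for pos, row in enumerate(df.itertuples(index=False)):
            try:
                old = float(getattr(row, "hpd_old_ma"))
                young = float(getattr(row, "hpd_young_ma"))
            except (TypeError, ValueError) as exc:
                raise EventValidationError(
                    f"row {pos}: unparseable age in hpd_old_ma/hpd_young_ma"
                ) from exc
            try:
                events.append(
                    DispersalEvent(
                        event_id=str(getattr(row, "event_id")),
                        dataset_id=str(getattr(row, "dataset_id")),
                        taxon_group=str(getattr(row, "taxon_group")),
                        direction=str(getattr(row, "direction")),
                        hpd_old_ma=old,
                        hpd_young_ma=young,
                    )
                )
            except EventValidationError as exc:
                raise EventValidationError(f"row {pos}: {exc}") from exc
        return cls(events, metadata)


def read_events(path: str | Path, dialect: str = "tsv") -> EventTable:
    """Read and validate a dispersal-event table.

    Parameters
    ----------
    path
        Path to a TSV file with the six required columns.
    dialect
        Only ``"tsv"`` is supported; the argument exists so callers fail
        loudly rather than silently mis-parsing other separators.

    Raises
    ------
    EventValidationError
        Missing column, unparseable age, inverted interval, or unknown
        direction/taxon label; the message names the offending row and field.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'tsv' is defined")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = EventTable.from_dataframe(df, metadata={"source": str(path)})
    return table


def write_events(table: EventTable, path: str | Path) -> None:
    """Write ``table`` as TSV so that :func:`read_events` round-trips it.

    Ages are written with :func:`repr` precision, so the round-trip is exact
    field-for-field.
    """
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False)


def filter_events(
    table: EventTable,
    direction: str | None = None,
    taxa: Iterable[str] | None = None,
) -> EventTable:
    """Subset a table by dispersal direction and/or taxon-group membership.

    Order is preserved; passing no filters returns an equal table. Unknown
    labels raise rather than returning a silently empty result.
    """
    if direction is not None and direction not in DIRECTIONS:
        raise EventValidationError(
            f"unknown direction {direction!r} (expected one of {sorted(DIRECTIONS)})"
        )
    taxa_set: frozenset[str] | None = None
    if taxa is not None:
        taxa_set = frozenset(taxa)
        unknown = taxa_set - TAXON_GROUPS
        if unknown:
            raise EventValidationError(
                f"unknown taxon group(s) {sorted(unknown)} "
                f"(expected members of {sorted(TAXON_GROUPS)})"
            )
    kept = [
        e
        for e in table
        if (direction is None or e.direction == direction)
        and (taxa_set is None or e.taxon_group in taxa_set)
    ]
    return EventTable(kept, metadata=dict(table.metadata))
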