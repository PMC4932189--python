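from __future__ import annotations

import numpy as np
import pytest

from mdeflux import DispersalEvent, EventTable

DIRECTIONS = ("india_to_asia", "asia_to_india")
TAXA = (
    "amphibian",
    "non_avian_reptile",
    "bird",
    "arthropod",
    "plant",
    "teleost_fish",
    "mammal",
    "other",
)


def random_table(rng: np.random.Generator, n_events: int, t_max: float = 70.0) -> EventTable:
    """Random but always-valid event table for property tests."""
    events = []
    for i in range(n_events):
        young = rng.uniform(0, t_max)
        old = young + rng.exponential(5.0)
        events.append(
            DispersalEvent(
                event_id=f"e{i}",
                dataset_id=f"d{rng.integers(0, 10)}",
                taxon_group=TAXA[rng.integers(0, len(TAXA))],
                direction=DIRECTIONS[rng.integers(0, 2)],
                hpd_old_ma=float(old),
                hpd_young_ma=float(young),
            )
        )
    return EventTable(events)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160704)


@pytest.fixture
def small_table() -> EventTable:
    return EventTable(
        [
            DispersalEvent("a", "ds1", "bird", "india_to_asia", 2.4, 0.6),
            DispersalEvent("b", "ds1", "plant", "asia_to_india", 5.0, 5.0),
            DispersalEvent("c", "ds2", "amphibian", "asia_to_india", 40.2, 33.7),
        ]
    )
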