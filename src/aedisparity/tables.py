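"""2x2 host-factor contingency tables and the table-level filters.

Two orientations are supported. A *by-drug* table fixes an adverse event i
and asks, for each drug j, whether reports of (i, j) split between the two
host-factor groups the way all reports of event i do:

                 group 1            group 2
    drug j       a1 = n1_ij         a2 = n2_ij
    no drug j    b1 = n1_i. - n1_ij b2 = n2_i. - n2_ij

A *by-AE* table fixes a drug j and varies the event, with margins taken
over all events reported for that drug. The statistics in
:mod:`aedisparity.stats` are orientation-agnostic; only the margin
construction differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import CountCube

__all__ = [
    "HostTable",
    "TableFamily",
    "build_family",
    "filter_min_cell",
    "filter_min_units",
    "filter_exposed_exceeds_margin",
]


@dataclass(frozen=True)
class HostTable:
    """One 2x2 host-factor table.

    ``a1``/``a2`` are the exposed counts in group 1 / group 2 and
    ``b1``/``b2`` the unexposed counts; "exposed" means with-drug in the
    by-drug orientation and with-event in the by-AE orientation.
    """

    orientation: str  # "by_drug" | "by_ae"
    unit_id: str
    context_id: str
    a1: int
    a2: int
    b1: int
    b2: int

    def __post_init__(self) -> None:
        if self.orientation not in ("by_drug", "by_ae"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if min(self.a1, self.a2, self.b1, self.b2) < 0:
            raise ValueError("negative cell count")

    @property
    def n_exposed(self) -> int:
        return self.a1 + self.a2

    @property
    def m1(self) -> int:
        """Group-1 margin (n1_i. or n1_.j)."""
        return self.a1 + self.b1

    @property
    def m2(self) -> int:
        return self.a2 + self.b2

    @property
    def n(self) -> int:
        return self.m1 + self.m2

    @property
    def p_null(self) -> float:
        """Null group-1 proportion p = M1 / N."""
        return self.m1 / self.n

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a1, self.a2, self.b1, self.b2)

    def swapped(self) -> "HostTable":
        """Same table with the two group labels exchanged."""
        return HostTable(self.orientation, self.unit_id, self.context_id,
                         self.a2, self.a1, self.b2, self.b1)


@dataclass
class TableFamily:
    """An ordered collection of tables sharing one context and orientation.

    For a by-drug family the context is an adverse event and the units are
    the drugs reported with it; the family is the set over which the
    maximal statistic is taken and multiplicity is controlled.
    """

    tables: list[HostTable]
    removal_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("TableFamily requires at least one table")
        ctx = {(t.orientation, t.context_id) for t in self.tables}
        if len(ctx) != 1:
            raise ValueError(f"tables mix contexts/orientations: {sorted(ctx)}")
        ids = [t.unit_id for t in self.tables]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit_id in family")

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)

    @property
    def J(self) -> int:
        return len(self.tables)

    @property
    def orientation(self) -> str:
        return self.tables[0].orientation

    @property
    def context_id(self) -> str:
        return self.tables[0].context_id

    @property
    def unit_ids(self) -> list[str]:
        return [t.unit_id for t in self.tables]

    def arrays(self) -> dict[str, np.ndarray]:
        """Cell and margin arrays aligned with ``unit_ids`` (vector path)."""
        a1 = np.array([t.a1 for t in self.tables], dtype=float)
        a2 = np.array([t.a2 for t in self.tables], dtype=float)
        b1 = np.array([t.b1 for t in self.tables], dtype=float)
        b2 = np.array([t.b2 for t in self.tables], dtype=float)
        return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
                "n": a1 + a2, "m1": a1 + b1, "m2": a2 + b2}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"orientation": t.orientation, "context_id": t.context_id,
                 "unit_id": t.unit_id, "a1": t.a1, "a2": t.a2, "b1": t.b1, "b2": t.b2}
                for t in self.tables
            ]
        )


def build_family(cube: CountCube, orientation: str, context_id: str) -> TableFamily:
    """Construct the 2x2 family for one context from a count cube.

    by_drug: context is an event i; for every drug j with any reports of
    i, a1 = n1_ij and b1 = n1_i. - n1_ij (margins summed over drugs).
    by_ae: context is a drug j; margins are summed over events for j.
    Units with zero exposed count are not emitted (they carry no disparity
    information and would fail the min-cell filter regardless).
    """
    g1, g2 = cube.group_labels
    if orientation == "by_drug":
        if context_id not in cube.events():
            raise KeyError(f"event {context_id!r} not present in cube")
        m1 = cube.event_margin(context_id, g1)
        m2 = cube.event_margin(context_id, g2)
        units = sorted({d for (e, d, _) in cube.entries if e == context_id})
        cells = [(u, cube.count(context_id, u, g1), cube.count(context_id, u, g2))
                 for u in units]
    elif orientation == "by_ae":
        if context_id not in cube.drugs():
            raise KeyError(f"drug {context_id!r} not present in cube")
        m1 = cube.drug_margin(context_id, g1)
        m2 = cube.drug_margin(context_id, g2)
        units = sorted({e for (e, d, _) in cube.entries if d == context_id})
        cells = [(u, cube.count(u, context_id, g1), cube.count(u, context_id, g2))
                 for u in units]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    tables = [
        HostTable(orientation, unit, context_id, c1, c2, m1 - c1, m2 - c2)
        for unit, c1, c2 in cells
        if c1 + c2 > 0
    ]
    if not tables:
        raise KeyError(f"no exposed counts for context {context_id!r}")
    return TableFamily(tables)


def filter_min_cell(family: TableFamily, min_cell: int = 5) -> TableFamily:
    """Drop tables with any 2x2 cell below ``min_cell`` (default 5).

    Mirrors the preprocessing rule that excludes drug-AE combinations with
    low expected counts, where the normal and ratio approximations are
    unreliable. Removals are logged per unit_id; may return an empty-table
    family error if nothing survives.
    """
    if min_cell < 0:
        raise ValueError("min_cell must be >= 0")
    kept = [t for t in family if min(t.cells()) >= min_cell]
    removed = {t.unit_id: f"cell<{min_cell}" for t in family if min(t.cells()) < min_cell}
    if not kept:
        raise ValueError(f"min-cell filter ({min_cell}) removed every table in "
                         f"family {family.context_id!r}")
    out = TableFamily(kept)
    out.removal_log = {**family.removal_log, **removed}
    return out


def filter_min_units(
    families: Iterable[TableFamily], min_units: int = 5
) -> list[TableFamily]:
    """Keep only families with strictly more than ``min_units`` tables.

    The default (keep J > 5) restricts attention to events with more than
    five associated drugs, so the multiplicity procedures have a
    non-trivial family to act on.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    return [f for f in families if f.J > min_units]


def filter_exposed_exceeds_margin(family: TableFamily) -> TableFamily | None:
    """Exclude the whole family if any unit has n_exposed > min(M1, M2).

    Used when preparing simulation bases: such a unit could draw a
    group-s count exceeding its margin under the binomial null, breaking
    the subgroup-ratio computations. Returns None when excluded.
    """
    for t in family:
        if t.n_exposed > min(t.m1, t.m2):
            return None
    return family
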