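"""Report-level ingestion and preprocessing for spontaneous AE data.

A spontaneous reporting database (FAERS, VigiBase, VAERS) delivers one row
per (report, drug, event) combination together with patient attributes.
This module parses such delimited files into :class:`ReportRecord` objects,
optionally collapses groups of MedDRA Preferred Terms into a single named
composite event (e.g. "liver toxicity"), and tabulates the records into a
:class:`CountCube` of (event, drug, host-factor group) counts ready for
2x2 table construction.

Preprocessing follows three rules: only primary-suspect drug mentions are
counted, records with a missing host-factor value are dropped, and exact
duplicate (report_id, drug, event_term) triples are collapsed to one.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReportRecord",
    "CompositeEventMap",
    "CountCube",
    "PreprocessLog",
    "read_reports",
    "read_faers_ascii",
    "read_composite_map",
    "apply_composite_events",
    "preprocess",
    "normalize_term",
]

#: Drug role codes as used in FAERS (DRUG.ROLE_COD) plus spelled-out forms.
ROLE_ALIASES = {
    "ps": "primary_suspect",
    "primary_suspect": "primary_suspect",
    "primary suspect": "primary_suspect",
    "ss": "secondary_suspect",
    "secondary_suspect": "secondary_suspect",
    "secondary suspect": "secondary_suspect",
    "c": "concomitant",
    "concomitant": "concomitant",
    "i": "interacting",
    "interacting": "interacting",
}

_WS = re.compile(r"\s+")


def normalize_term(text: str) -> str:
    """Trim, collapse internal whitespace and case-fold a drug/PT name."""
    return _WS.sub(" ", str(text).strip()).casefold()


@dataclass(frozen=True)
class ReportRecord:
    """One (report, drug, event) row of a spontaneous reporting database.

    ``group`` is one of the two declared host-factor labels, or ``None``
    when the value was missing or unparseable; no third label survives
    parsing.
    """

    report_id: str
    drug: str
    role: str  # primary_suspect | secondary_suspect | concomitant | interacting | other
    event_term: str
    group: str | None


@dataclass(frozen=True)
class CompositeEventMap:
    """Maps a set of MedDRA Preferred Terms to one named composite event.

    Terms are matched case-insensitively after whitespace normalization.
    The canonical use is combining the many PTs that manifest liver
    toxicity into a single "liver toxicity" event.
    """

    event_name: str
    member_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_terms:
            raise ValueError("CompositeEventMap requires at least one member term")
        object.__setattr__(self, "event_name", normalize_term(self.event_name))
        object.__setattr__(
            self, "member_terms", frozenset(normalize_term(t) for t in self.member_terms)
        )

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.member_terms


@dataclass
class CountCube:
    """Report counts indexed by (event, drug, group).

    ``group_labels`` is the ordered pair (group 1, group 2); all keys use
    one of these two labels. Counts are non-negative by construction.
    """

    entries: dict[tuple[str, str, str], int]
    group_labels: tuple[str, str]

    def count(self, event: str, drug: str, group: str) -> int:
        return self.entries.get((event, drug, group), 0)

    def total(self) -> int:
        return sum(self.entries.values())

    def events(self) -> list[str]:
        return sorted({e for (e, _, _) in self.entries})

    def drugs(self) -> list[str]:
        return sorted({d for (_, d, _) in self.entries})

    def event_margin(self, event: str, group: str) -> int:
        """n^(s)_i. : reports of ``event`` in ``group`` summed over drugs."""
        return sum(v for (e, _, g), v in self.entries.items() if e == event and g == group)

    def drug_margin(self, drug: str, group: str) -> int:
        """n^(s)_.j : reports of ``drug`` in ``group`` summed over events."""
        return sum(v for (_, d, g), v in self.entries.items() if d == drug and g == group)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (event, drug, group, count) table."""
        rows = [
            {"event": e, "drug": d, "group": g, "count": c}
            for (e, d, g), c in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["event", "drug", "group", "count"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_labels: tuple[str, str]) -> "CountCube":
        entries = {
            (str(r.event), str(r.drug), str(r.group)): int(r.count)
            for r in frame.itertuples(index=False)
        }
        return cls(entries=entries, group_labels=group_labels)


@dataclass
class PreprocessLog:
    """Per-rule removal counts; sums to input minus output."""

    n_input: int = 0
    removed_role: int = 0
    removed_missing_group: int = 0
    n_output: int = 0
    notes: list[str] = field(default_factory=list)


DEFAULT_COLUMNS = {
    "report_id": "report_id",
    "drug": "drug",
    "role": "role",
    "event_term": "event_term",
    "group": "group",
}


def _parse_role(raw: object) -> str:
    return ROLE_ALIASES.get(str(raw).strip().casefold(), "other")


def _parse_group(
    raw: object,
    group_labels: tuple[str, str],
    age_threshold: float | None,
) -> str | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    if age_threshold is not None:
        # numeric age dichotomized: boundary goes to the "at least" group
        try:
            age = float(raw)
        except (TypeError, ValueError):
            return None
        return group_labels[1] if age >= age_threshold else group_labels[0]
    value = normalize_term(raw)
    norm_labels = {normalize_term(lab): lab for lab in group_labels}
    return norm_labels.get(value)


def read_reports(
    source,
    columns: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    group_labels: tuple[str, str] = ("male", "female"),
    age_threshold: float | None = None,
    **read_csv_kwargs,
) -> list[ReportRecord]:
    """Parse a delimited report-level file into ``ReportRecord`` objects.

    Parameters
    ----------
    source
        Path, file object or text stream accepted by :func:`pandas.read_csv`.
    columns
        Mapping of the logical fields (report_id, drug, role, event_term,
        group) to the actual column names; defaults to identity.
    delimiter
        Field delimiter, tab by default.
    group_labels
        The two declared host-factor levels, ordered (group 1, group 2).
        Values matching neither label become missing.
    age_threshold
        When given, the group column is read as a numeric age and cut at
        this threshold (default policy elsewhere: 65, with the boundary in
        the "at least" group, which is ``group_labels[1]``).

    Exact duplicate (report_id, drug, event_term) triples are collapsed to
    a single record (first occurrence wins for the remaining fields).
    """
    columns = {**DEFAULT_COLUMNS, **(columns or {})}
    frame = pd.read_csv(source, sep=delimiter, dtype=str, **read_csv_kwargs)
    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise KeyError(f"required column(s) not found: {', '.join(missing)}")
    if frame.empty:
        warnings.warn("input stream contained no report rows", stacklevel=2)
        return []

    records: list[ReportRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for row in frame.itertuples(index=False):
        get = lambda logical: getattr(row, columns[logical])  # noqa: E731
        drug = normalize_term(get("drug"))
        term = normalize_term(get("event_term"))
        rid = str(get("report_id")).strip()
        key = (rid, drug, term)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            ReportRecord(
                report_id=rid,
                drug=drug,
                role=_parse_role(get("role")),
                event_term=term,
                group=_parse_group(get("group"), group_labels, age_threshold),
            )
        )
    return records


def read_faers_ascii(source, **kwargs) -> list[ReportRecord]:
    """Thin reader for the raw FAERS quarterly ASCII layout ($-delimited).

    Accepts the same logical column mapping as :func:`read_reports`; only
    the delimiter differs. The canonical input remains the normalized
    delimited file.
    """
    kwargs.setdefault("delimiter", "$")
    return read_reports(source, **kwargs)


def read_composite_map(source) -> CompositeEventMap:
    """Read a two-column TSV (event_name, member_term) into a map.

    All rows must share one event name; one member term per line.
    """
    frame = pd.read_csv(source, sep="\t", dtype=str, header=None, comment="#")
    if frame.shape[1] < 2:
        raise ValueError("composite-event file needs two columns: event_name, member_term")
    names = {normalize_term(v) for v in frame.iloc[:, 0]}
    if len(names) != 1:
        raise ValueError(f"composite-event file names several events: {sorted(names)}")
    return CompositeEventMap(event_name=names.pop(), member_terms=frozenset(frame.iloc[:, 1]))


def apply_composite_events(
    records: Iterable[ReportRecord], cmap: CompositeEventMap
) -> list[ReportRecord]:
    """Replace member Preferred Terms by the composite event name.

    A report contributing several member terms for the same drug counts
    once for the composite event; non-member terms pass through unchanged.
    Idempotent: the composite name itself maps to itself.
    """
    out: list[ReportRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        term = cmap.event_name if (rec.event_term in cmap or rec.event_term == cmap.event_name) else rec.event_term
        key = (rec.report_id, rec.drug, term)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec if term == rec.event_term else ReportRecord(
            rec.report_id, rec.drug, rec.role, term, rec.group))
    return out


def preprocess(
    records: Sequence[ReportRecord],
    group_labels: tuple[str, str] = ("male", "female"),
    roles: frozenset[str] = frozenset({"primary_suspect"}),
) -> tuple[CountCube, PreprocessLog]:
    """Apply the counting rules and tabulate a :class:`CountCube`.

    Rules, in order: keep only records whose drug role is in ``roles``
    (primary suspect only, by default); drop records with a missing
    host-factor group. Returns the cube and a log of how many records each
    rule removed.
    """
    log = PreprocessLog(n_input=len(records))
    entries: dict[tuple[str, str, str], int] = {}
    for rec in records:
        if rec.role not in roles:
            log.removed_role += 1
            continue
        if rec.group is None:
            log.removed_missing_group += 1
            continue
        if rec.group not in group_labels:
            raise ValueError(
                f"record group {rec.group!r} is not one of the declared labels {group_labels}"
            )
        key = (rec.event_term, rec.drug, rec.group)
        entries[key] = entries.get(key, 0) + 1
        log.n_output += 1
    if log.n_output == 0:
        raise ValueError(
            "no records survive preprocessing "
            f"(role filter removed {log.removed_role}, missing group removed "
            f"{log.removed_missing_group}); review the role/group policy"
        )
    return CountCube(entries=entries, group_labels=group_labels), log
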