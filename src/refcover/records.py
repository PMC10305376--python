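"""Bibliographic records and multi-database corpora.

A search in a literature database exports a list of bibliographic records
(RIS, MEDLINE flat text, or CSV). This module parses those exports into
:class:`Record` objects stamped with their source database and pools them
into a :class:`PooledCorpus` — the duplicate-inclusive set of "records for
screening" that downstream deduplication, screening and retrieval
diagnostics operate on.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Record",
    "PooledCorpus",
    "CorpusFormatError",
    "normalize_doi",
    "read_records",
    "write_records_csv",
    "pooled_yield_table",
]

FORMATS = ("ris", "medline", "csv")

CSV_COLUMNS = [
    "record_id",
    "source_db",
    "title",
    "authors",
    "year",
    "journal",
    "doi",
    "abstract",
]

_DOI_PREFIX = re.compile(r"^(?:https?://(?:dx\.)?doi\.org/|doi:\s*)", re.IGNORECASE)
_YEAR_PREFIX = re.compile(r"^(\d{4})")


class CorpusFormatError(ValueError):
    """A bibliographic export could not be parsed in the declared format."""


def normalize_doi(raw: str | None) -> str | None:
    """Lower-case a DOI and strip any resolver URL / ``doi:`` prefix."""
    if raw is None:
        return None
    doi = _DOI_PREFIX.sub("", raw.strip()).strip().lower()
    return doi or None


def _parse_year(raw: str | None) -> int | None:
    # RIS PY fields often carry "2020/01/01"; take a leading 4-digit prefix.
    if not raw:
        return None
    m = _YEAR_PREFIX.match(raw.strip())
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class Record:
    """One bibliographic record as exported from one database.

    At least one of ``doi`` and ``title`` must be present; ``source_db``
    is the label of the database whose export the record came from.
    """

    record_id: str
    source_db: str
    title: str = ""
    authors: tuple[str, ...] = ()
    year: int | None = None
    journal: str | None = None
    doi: str | None = None
    abstract: str | None = None

    def __post_init__(self) -> None:
        if not self.source_db:
            raise ValueError(f"record {self.record_id!r}: source_db must be non-empty")
        if not self.title and self.doi is None:
            raise ValueError(
                f"record {self.record_id!r}: at least one of title/doi required"
            )
        object.__setattr__(self, "authors", tuple(self.authors))

    @property
    def first_author(self) -> str | None:
        return self.authors[0] if self.authors else None


@dataclass(frozen=True)
class PooledCorpus:
    """The concatenation of all per-database yields, before deduplication."""

    records: tuple[Record, ...]
    databases: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "databases", tuple(self.databases))
        known = set(self.databases)
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in corpus")
            seen.add(rec.record_id)
            if rec.source_db not in known:
                raise ValueError(
                    f"record {rec.record_id!r} has unknown source_db {rec.source_db!r}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[Record], databases: Sequence[str] | None = None
    ) -> "PooledCorpus":
        """Pool records; database order is first-seen unless given explicitly."""
        records = tuple(records)
        if databases is None:
            order: list[str] = []
            for rec in records:
                if rec.source_db not in order:
                    order.append(rec.source_db)
            databases = order
        return cls(records=records, databases=tuple(databases))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def db_yield(self, database: str) -> int:
        """Number of (duplicate-inclusive) records the database contributed."""
        if database not in self.databases:
            raise KeyError(f"unknown database {database!r}")
        return sum(1 for rec in self.records if rec.source_db == database)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": r.record_id,
                "source_db": r.source_db,
                "title": r.title,
                "authors": "; ".join(r.authors),
                "year": r.year,
                "journal": r.journal,
                "doi": r.doi,
                "abstract": r.abstract,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


# ---------------------------------------------------------------------------
# Parsers

_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")

_RIS_FIELDS = {
    "TI": "title",
    "T1": "title",
    "AU": "authors",
    "A1": "authors",
    "PY": "year",
    "Y1": "year",
    "DO": "doi",
    "JO": "journal",
    "T2": "journal",
    "AB": "abstract",
    "ID": "record_id",
}


def _parse_ris(text: str, source_db: str) -> list[Record]:
    records: list[Record] = []
    entry: dict[str, object] = {"authors": []}
    last_field: str | None = None
    started = False
    counter = 0

    def flush(line_no: int) -> None:
        nonlocal entry, counter, started
        counter += 1
        try:
            records.append(
                Record(
                    record_id=str(entry.get("record_id") or f"{source_db}-{counter:05d}"),
                    source_db=source_db,
                    title=str(entry.get("title") or ""),
                    authors=tuple(entry["authors"]),  # type: ignore[index]
                    year=_parse_year(entry.get("year")),  # type: ignore[arg-type]
                    journal=entry.get("journal"),  # type: ignore[arg-type]
                    doi=normalize_doi(entry.get("doi")),  # type: ignore[arg-type]
                    abstract=entry.get("abstract"),  # type: ignore[arg-type]
                )
            )
        except ValueError as exc:
            raise CorpusFormatError(f"RIS entry ending at line {line_no}: {exc}") from exc
        entry = {"authors": []}
        started = False

    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _RIS_TAG.match(line)
        if m is None:
            # Continuation of the previous field's value.
            if last_field and last_field != "authors" and started:
                entry[last_field] = f"{entry.get(last_field, '')} {line.strip()}".strip()
                continue
            raise CorpusFormatError(f"RIS parse error at line {line_no}: {line!r}")
        tag, value = m.group(1), m.group(2).strip()
        if tag == "TY":
            started = True
            last_field = None
            continue
        if tag == "ER":
            flush(line_no)
            last_field = None
            continue
        field_name = _RIS_FIELDS.get(tag)
        started = True
        if field_name is None:
            last_field = None
            continue
        if field_name == "authors":
            entry["authors"].append(value)  # type: ignore[union-attr]
        elif field_name not in entry or not entry[field_name]:
            entry[field_name] = value
        last_field = field_name

    if started:
        raise CorpusFormatError("RIS file ends inside an entry (missing ER tag)")
    return records


_MEDLINE_TAG = re.compile(r"^([A-Z0-9]{1,4}) *- (.*)$")


def _parse_medline(text: str, source_db: str) -> list[Record]:
    """Parse PubMed/MEDLINE flat text (PMID-/TI-/AU-/LID-/AID- tagged)."""
    entries: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] | None = None
    last_tag: str | None = None
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            current = None
            last_tag = None
            continue
        if line.startswith("      ") and last_tag and current is not None:
            current[last_tag][-1] += " " + line.strip()
            continue
        m = _MEDLINE_TAG.match(line)
        if m is None:
            raise CorpusFormatError(f"MEDLINE parse error at line {line_no}: {line!r}")
        tag, value = m.group(1), m.group(2).strip()
        if current is None or (tag == "PMID" and "PMID" in current):
            current = {}
            entries.append(current)
        current.setdefault(tag, []).append(value)
        last_tag = tag

    records: list[Record] = []
    for i, entry in enumerate(entries, start=1):
        doi = None
        for tag in ("LID", "AID"):
            for value in entry.get(tag, []):
                if value.endswith("[doi]"):
                    doi = value[: -len("[doi]")].strip()
                    break
            if doi:
                break
        pmid = entry.get("PMID", [None])[0]
        try:
            records.append(
                Record(
                    record_id=str(pmid or f"{source_db}-{i:05d}"),
                    source_db=source_db,
                    title=entry.get("TI", [""])[0],
                    authors=tuple(entry.get("AU", [])),
                    year=_parse_year(entry.get("DP", [None])[0]),
                    journal=entry.get("JT", entry.get("TA", [None]))[0],
                    doi=normalize_doi(doi),
                    abstract=entry.get("AB", [None])[0],
                )
            )
        except ValueError as exc:
            raise CorpusFormatError(f"MEDLINE entry {i}: {exc}") from exc
    return records


def _parse_csv(text: str, source_db: str | None) -> list[Record]:
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None or "record_id" not in reader.fieldnames:
        raise CorpusFormatError("CSV is missing the record_id header column")
    records: list[Record] = []
    for i, row in enumerate(reader, start=2):
        try:
            records.append(
                Record(
                    record_id=row["record_id"],
                    source_db=source_db or row.get("source_db") or "",
                    title=row.get("title") or "",
                    authors=tuple(
                        a for a in (row.get("authors") or "").split("; ") if a
                    ),
                    year=_parse_year(row.get("year")),
                    journal=row.get("journal") or None,
                    doi=normalize_doi(row.get("doi") or None),
                    abstract=row.get("abstract") or None,
                )
            )
        except ValueError as exc:
            raise CorpusFormatError(f"CSV line {i}: {exc}") from exc
    return records


def read_records(
    path: str | Path, format: str, source_db: str | None = None
) -> list[Record]:
    """Read one database's export file into a list of records.

    Parameters
    ----------
    path : path to the export file.
    format : one of ``"ris"``, ``"medline"``, ``"csv"``.
    source_db : database label stamped on every record. Required for RIS
        and MEDLINE; for CSV it overrides the file's ``source_db`` column
        when given.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format in ("ris", "medline") and not source_db:
        raise ValueError("source_db is required for RIS/MEDLINE input")
    text = Path(path).read_text(encoding="utf-8")
    if format == "ris":
        return _parse_ris(text, source_db)  # type: ignore[arg-type]
    if format == "medline":
        return _parse_medline(text, source_db)  # type: ignore[arg-type]
    return _parse_csv(text, source_db)


def write_records_csv(records: Iterable[Record], path: str | Path) -> None:
    """Write records in the package's fixed CSV dialect (UTF-8, ``; ``-joined authors)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.source_db,
                    r.title,
                    "; ".join(r.authors),
                    "" if r.year is None else r.year,
                    r.journal or "",
                    r.doi or "",
                    r.abstract or "",
                ]
            )


def read_corpus_csv(path: str | Path) -> PooledCorpus:
    """Read a pooled corpus previously written with :func:`write_records_csv`."""
    return PooledCorpus.from_records(read_records(path, "csv"))


def pooled_yield_table(corpus: PooledCorpus) -> pd.DataFrame:
    """Per-database record counts plus their sum (the screening workload).

    The total is always the recomputed sum of the per-database counts —
    i.e. the length of the pooled record list.
    """
    counts = {db: 0 for db in corpus.databases}
    for rec in corpus.records:
        counts[rec.source_db] += 1
    rows = [{"database": db, "records": n} for db, n in counts.items()]
    rows.append({"database": "Total records", "records": sum(counts.values())})
    return pd.DataFrame(rows, columns=["database", "records"])
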