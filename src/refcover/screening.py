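"""Eligibility screening and the record-flow ledger.

After deduplication every unique publication (cluster) receives exactly one
binary eligibility decision — here, whether it is a randomized clinical
trial on the topic of interest. Eligibility is a property of the
publication, not of any one database's copy, so labels attach to clusters
(optionally referenced by their canonical record id, which is stable for
human labelers).

The :class:`FlowLedger` is the PRISMA-style accounting identity
``pooled = duplicates + ineligible + eligible``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .dedup import DedupCluster
from .records import PooledCorpus

__all__ = [
    "ScreeningLabel",
    "ScreeningError",
    "FlowLedger",
    "LabeledCorpus",
    "apply_labels",
    "flow_ledger",
    "read_labels_csv",
    "write_labels_csv",
]

ELIGIBLE = "eligible"
INELIGIBLE = "ineligible"


class ScreeningError(ValueError):
    """Invalid label set: missing, duplicate or unresolvable cluster labels."""

    def __init__(self, message: str, cluster_ids: Sequence[str] = ()) -> None:
        self.cluster_ids = tuple(cluster_ids)
        if cluster_ids:
            message = f"{message}: {', '.join(sorted(cluster_ids))}"
        super().__init__(message)


@dataclass(frozen=True)
class ScreeningLabel:
    """The eligibility decision for one deduplicated publication."""

    cluster_id: str
    decision: str
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.decision not in (ELIGIBLE, INELIGIBLE):
            raise ValueError(
                f"decision must be {ELIGIBLE!r} or {INELIGIBLE!r}, "
                f"got {self.decision!r}"
            )
        if self.decision == INELIGIBLE and not self.reason:
            raise ValueError(
                f"label for {self.cluster_id!r}: an ineligible decision requires a reason"
            )


@dataclass(frozen=True)
class FlowLedger:
    """Record-flow counts: pooled = duplicates + ineligible + eligible."""

    pooled: int
    duplicates: int
    ineligible: int
    eligible: int

    def __post_init__(self) -> None:
        if self.pooled != self.duplicates + self.ineligible + self.eligible:
            raise ValueError(
                "flow ledger violates pooled = duplicates + ineligible + eligible: "
                f"{self.pooled} != {self.duplicates} + {self.ineligible} + {self.eligible}"
            )


@dataclass(frozen=True)
class LabeledCorpus:
    """A pooled corpus with its dedup clustering and eligibility labels.

    This is the object every retrieval diagnostic is computed from. It
    exposes the per-database coverage map (database *d* covers cluster *c*
    iff any member of *c* was exported by *d*) and duplicate-inclusive
    per-database yields.
    """

    corpus: PooledCorpus
    clusters: tuple[DedupCluster, ...]
    labels: Mapping[str, ScreeningLabel]

    @property
    def databases(self) -> tuple[str, ...]:
        return self.corpus.databases

    @property
    def pooled_size(self) -> int:
        return len(self.corpus)

    @cached_property
    def eligible_ids(self) -> frozenset[str]:
        return frozenset(
            cid for cid, lab in self.labels.items() if lab.decision == ELIGIBLE
        )

    @property
    def n_eligible(self) -> int:
        return len(self.eligible_ids)

    @cached_property
    def _record_db(self) -> dict[str, str]:
        return {rec.record_id: rec.source_db for rec in self.corpus.records}

    @cached_property
    def coverage(self) -> dict[str, frozenset[str]]:
        """database label -> set of cluster_ids with at least one member from it."""
        cov: dict[str, set[str]] = {db: set() for db in self.databases}
        rec_db = self._record_db
        for cluster in self.clusters:
            for member in cluster.member_ids:
                cov[rec_db[member]].add(cluster.cluster_id)
        return {db: frozenset(ids) for db, ids in cov.items()}

    @cached_property
    def yields(self) -> dict[str, int]:
        """database label -> duplicate-inclusive record count."""
        counts = {db: 0 for db in self.databases}
        for rec in self.corpus.records:
            counts[rec.source_db] += 1
        return counts

    def eligible_covered_by(self, database: str) -> frozenset[str]:
        if database not in self.coverage:
            raise KeyError(f"unknown database {database!r}")
        return self.coverage[database] & self.eligible_ids


def apply_labels(
    corpus: PooledCorpus,
    clusters: Sequence[DedupCluster],
    labels: Iterable[ScreeningLabel],
) -> LabeledCorpus:
    """Attach one eligibility label to every cluster.

    Labels may reference either ``cluster_id`` or the cluster's
    ``canonical_id``; every cluster must end up with exactly one label.

    Raises
    ------
    ScreeningError
        listing the offending cluster ids when a cluster is unlabeled,
        doubly labeled, or a label references no known cluster.
    """
    clusters = tuple(clusters)
    by_cluster_id = {c.cluster_id: c for c in clusters}
    by_canonical = {c.canonical_id: c for c in clusters}

    resolved: dict[str, ScreeningLabel] = {}
    duplicated: set[str] = set()
    unknown: set[str] = set()
    for label in labels:
        cluster = by_cluster_id.get(label.cluster_id) or by_canonical.get(
            label.cluster_id
        )
        if cluster is None:
            unknown.add(label.cluster_id)
            continue
        if cluster.cluster_id in resolved:
            duplicated.add(cluster.cluster_id)
            continue
        resolved[cluster.cluster_id] = ScreeningLabel(
            cluster_id=cluster.cluster_id,
            decision=label.decision,
            reason=label.reason,
        )
    if unknown:
        raise ScreeningError("labels reference unknown clusters", sorted(unknown))
    if duplicated:
        raise ScreeningError("clusters labeled more than once", sorted(duplicated))
    missing = set(by_cluster_id) - set(resolved)
    if missing:
        raise ScreeningError("clusters missing a label", sorted(missing))
    return LabeledCorpus(corpus=corpus, clusters=clusters, labels=resolved)


def flow_ledger(labeled: LabeledCorpus) -> FlowLedger:
    """Compute the record-flow ledger from a labeled corpus."""
    pooled = labeled.pooled_size
    unique = len(labeled.clusters)
    eligible = labeled.n_eligible
    return FlowLedger(
        pooled=pooled,
        duplicates=pooled - unique,
        ineligible=unique - eligible,
        eligible=eligible,
    )


def read_labels_csv(path: str | Path) -> list[ScreeningLabel]:
    """Read a labels file with columns cluster_id, decision, reason."""
    labels = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            labels.append(
                ScreeningLabel(
                    cluster_id=row["cluster_id"],
                    decision=row["decision"],
                    reason=row.get("reason") or None,
                )
            )
    return labels


def write_labels_csv(labels: Iterable[ScreeningLabel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cluster_id", "decision", "reason"])
        for lab in labels:
            writer.writerow([lab.cluster_id, lab.decision, lab.reason or ""])
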