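"""Duplicate detection across database exports.

The same publication retrieved from several databases (or twice from one)
must be collapsed to a single unique record before screening. Two records
are linked when any of three rules fires:

(a) equal non-absent DOIs;
(b) equal dedup keys — (normalized title, year, first-author family name);
(c) normalized-title similarity at or above a fuzzy threshold with equal
    year, unless the two records carry *different* non-absent DOIs (a DOI
    conflict vetoes a fuzzy link).

Clusters are the transitive closure of these pairwise links; the canonical
member of a cluster is its lexicographically smallest ``record_id``.
Title similarity is 1 − Levenshtein distance / max length.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .records import PooledCorpus, Record

__all__ = [
    "DedupCluster",
    "DedupReport",
    "normalize_title",
    "title_similarity",
    "first_author_family",
    "cluster_duplicates",
    "dedup_report",
    "write_clusters_csv",
    "read_clusters_csv",
]

DEFAULT_FUZZY_THRESHOLD = 0.90

_NON_ALNUM = re.compile(r"[^a-z0-9 ]+")
_WS = re.compile(r"\s+")


def normalize_title(title: str) -> str:
    """Normalize a title for matching.

    Lower-case, fold diacritics to ASCII, drop every character that is not
    a letter, digit or space, collapse whitespace runs, and strip. The
    function is idempotent.
    """
    text = unicodedata.normalize("NFKD", title)
    text = text.encode("ascii", "ignore").decode("ascii").lower()
    text = _WS.sub(" ", text)
    text = _NON_ALNUM.sub("", text)
    return _WS.sub(" ", text).strip()


def title_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity of two (already normalized) titles."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def first_author_family(author: str | None) -> str | None:
    """Family name of a first-author string.

    ``"Smith, J."`` → ``smith`` (pre-comma part); ``"J. Smith"`` → ``smith``
    (last whitespace token).
    """
    if not author:
        return None
    if "," in author:
        family = author.split(",", 1)[0]
    else:
        family = author.strip().split()[-1]
    return normalize_title(family) or None


@dataclass(frozen=True)
class DedupCluster:
    """A group of records judged to be the same publication."""

    cluster_id: str
    member_ids: tuple[str, ...]
    canonical_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        if self.canonical_id not in self.member_ids:
            raise ValueError("canonical_id must be a member of the cluster")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class DedupReport:
    pooled: int
    unique: int
    duplicates: int


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def records_linked(a: Record, b: Record, fuzzy_threshold: float) -> bool:
    """Pairwise link test between two records (rules a, b, c)."""
    if a.doi is not None and a.doi == b.doi:
        return True
    ta, tb = normalize_title(a.title), normalize_title(b.title)
    if ta and ta == tb and a.year == b.year:
        if first_author_family(a.first_author) == first_author_family(b.first_author):
            return True
    # Rule (c): fuzzy title link, vetoed by a DOI conflict.
    if a.doi is not None and b.doi is not None and a.doi != b.doi:
        return False
    if ta and tb and a.year == b.year:
        if title_similarity(ta, tb) >= fuzzy_threshold:
            return True
    return False


def cluster_duplicates(
    corpus: PooledCorpus, fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD
) -> list[DedupCluster]:
    """Partition the pooled corpus into duplicate clusters.

    Clusters are the transitive closure of the pairwise links described in
    the module docstring. Records lacking both a usable title and a DOI
    remain singletons. Returned clusters are sorted by canonical_id and
    assigned sequential cluster ids.
    """
    if not 0.0 <= fuzzy_threshold <= 1.0:
        raise ValueError("fuzzy_threshold must lie in [0, 1]")
    records = corpus.records
    n = len(records)
    uf = _UnionFind(n)

    # Rule (a): exact DOI index.
    by_doi: dict[str, int] = {}
    for i, rec in enumerate(records):
        if rec.doi is not None:
            if rec.doi in by_doi:
                uf.union(by_doi[rec.doi], i)
            else:
                by_doi[rec.doi] = i

    norm_titles = [normalize_title(rec.title) for rec in records]

    # Rule (b): exact key index.
    by_key: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        if not norm_titles[i]:
            continue
        key = (norm_titles[i], rec.year, first_author_family(rec.first_author))
        if key in by_key:
            uf.union(by_key[key], i)
        else:
            by_key[key] = i

    # Rule (c): fuzzy title similarity within equal-year blocks.
    by_year: dict[object, list[int]] = {}
    for i, rec in enumerate(records):
        if norm_titles[i]:
            by_year.setdefault(rec.year, []).append(i)
    for block in by_year.values():
        for pos, i in enumerate(block):
            for j in block[pos + 1 :]:
                if uf.find(i) == uf.find(j):
                    continue
                a, b = records[i], records[j]
                if a.doi is not None and b.doi is not None and a.doi != b.doi:
                    continue
                if title_similarity(norm_titles[i], norm_titles[j]) >= fuzzy_threshold:
                    uf.union(i, j)

    groups: dict[int, list[str]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(uf.find(i), []).append(rec.record_id)
    clusters = []
    for members in groups.values():
        members.sort()
        clusters.append((members[0], tuple(members)))
    clusters.sort()
    return [
        DedupCluster(
            cluster_id=f"c{idx:05d}", member_ids=members, canonical_id=canonical
        )
        for idx, (canonical, members) in enumerate(clusters, start=1)
    ]


def dedup_report(clusters: Sequence[DedupCluster]) -> DedupReport:
    """Summarize a clustering: pooled = unique + duplicates."""
    pooled = sum(len(c) for c in clusters)
    unique = len(clusters)
    return DedupReport(pooled=pooled, unique=unique, duplicates=pooled - unique)


def write_clusters_csv(clusters: Iterable[DedupCluster], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cluster_id", "canonical_id", "member_ids"])
        for c in clusters:
            writer.writerow([c.cluster_id, c.canonical_id, "|".join(c.member_ids)])


def read_clusters_csv(path: str | Path) -> list[DedupCluster]:
    clusters = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            clusters.append(
                DedupCluster(
                    cluster_id=row["cluster_id"],
                    canonical_id=row["canonical_id"],
                    member_ids=tuple(row["member_ids"].split("|")),
                )
            )
    return clusters
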