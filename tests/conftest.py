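"""Shared fixtures: tiny hand-built corpora and independent oracle helpers."""

from __future__ import annotations

import itertools

import pytest

from refcover.dedup import records_linked
from refcover.records import PooledCorpus, Record
from refcover.screening import ScreeningLabel, apply_labels
from refcover.dedup import cluster_duplicates


def make_record(record_id, source_db, title="a study", year=2020, doi=None,
                authors=("Smith, J.",), **kw):
    return Record(
        record_id=record_id, source_db=source_db, title=title, year=year,
        doi=doi, authors=authors, **kw,
    )


@pytest.fixture
def small_labeled():
    """Three databases, four unique publications (two eligible), with overlap.

    pub1 (eligible): in A and B (same DOI); pub2 (eligible): in B only;
    pub3 (ineligible): in A, B and C; pub4 (ineligible): in C only.
    """
    recs = [
        make_record("a1", "A", "alpha trial", doi="10.1/p1"),
        make_record("b1", "B", "alpha trial", doi="10.1/p1"),
        make_record("b2", "B", "beta trial", doi="10.1/p2"),
        make_record("a2", "A", "gamma cohort", doi="10.1/p3"),
        make_record("b3", "B", "gamma cohort", doi="10.1/p3"),
        make_record("c1", "C", "gamma cohort", doi="10.1/p3"),
        make_record("c2", "C", "delta review", doi="10.1/p4"),
    ]
    corpus = PooledCorpus.from_records(recs, databases=("A", "B", "C"))
    clusters = cluster_duplicates(corpus)
    labels = [
        ScreeningLabel("a1", "eligible"),
        ScreeningLabel("b2", "eligible"),
        ScreeningLabel("a2", "ineligible", "not randomized"),
        ScreeningLabel("c2", "ineligible", "review"),
    ]
    return apply_labels(corpus, clusters, labels)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive re-implementations)


def brute_force_clusters(corpus: PooledCorpus, threshold: float) -> set[frozenset[str]]:
    """All-pairs union-find over the pairwise link test."""
    recs = list(corpus.records)
    parent = {r.record_id: r.record_id for r in recs}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(recs, 2):
        if records_linked(a, b, threshold):
            ra, rb = find(a.record_id), find(b.record_id)
            if ra != rb:
                parent[rb] = ra
    groups: dict[str, set[str]] = {}
    for r in recs:
        groups.setdefault(find(r.record_id), set()).add(r.record_id)
    return {frozenset(g) for g in groups.values()}


def naive_union_counts(labeled, databases):
    """Recount a union 2x2 from raw records, independent of the engine."""
    member = {}
    for cl in labeled.clusters:
        for m in cl.member_ids:
            member[m] = cl.cluster_id
    dbs = set(databases)
    covered = {
        member[r.record_id] for r in labeled.corpus.records if r.source_db in dbs
    }
    tp = len(covered & labeled.eligible_ids)
    load = sum(1 for r in labeled.corpus.records if r.source_db in dbs)
    return {
        "tp": tp,
        "fp": load - tp,
        "fn": labeled.n_eligible - tp,
        "tn": max(len(labeled.corpus) - load, 0),
        "load": load,
    }


def binom_ci_by_inversion(k: int, n: int, level: float = 0.95):
    """Exact binomial CI by bisection on the binomial tail probabilities.

    Independent of any beta-quantile identity: the lower bound solves
    P(X >= k | p) = alpha/2 and the upper solves P(X <= k | p) = alpha/2.
    """
    from scipy.stats import binom

    alpha = 1.0 - level

    def bisect(f, target, lo=0.0, hi=1.0, tol=1e-12):
        for _ in range(100):
            mid = (lo + hi) / 2.0
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2.0

    lower = 0.0 if k == 0 else bisect(lambda p: binom.sf(k - 1, n, p), alpha / 2.0)
    upper = 1.0 if k == n else bisect(lambda p: -binom.cdf(k, n, p), -alpha / 2.0)
    return lower, upper
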