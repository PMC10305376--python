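"""Database-combination analysis: unions, pairwise efficacy, minimal covers.

A set of databases searched together behaves as one retrieval source that
returns a record when any member indexes it. Union sensitivity can only
grow with the set, while the screening load — the raw, duplicate-inclusive
number of records a reviewer must screen — grows with every member's
yield. The practical question is the smallest combination whose union
sensitivity reaches a target (typically 100%) at the lowest screening
load.

Union convention: the 2x2 cells generalize the single-database convention
with summed duplicate-inclusive yields, i.e. FP = sum of member yields −
union TP and TN = pooled − sum of member yields (floored at 0). An
optional deduplicated-universe mode counts FP over unique union records
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combos
from typing import Iterable, Sequence

import pandas as pd

from .diagnostics import (
    ContingencyTable,
    DiagnosticEstimate,
    accuracy,
    format_estimate,
    sensitivity,
    specificity,
)
from .screening import LabeledCorpus

__all__ = [
    "CombinationResult",
    "union_contingency",
    "screening_load",
    "pairwise_matrix",
    "render_pairwise",
    "minimal_cover",
]

EXHAUSTIVE_DB_LIMIT = 15


@dataclass(frozen=True)
class CombinationResult:
    """Diagnostics of one database combination under the union convention."""

    databases: tuple[str, ...]
    contingency: ContingencyTable
    se: DiagnosticEstimate
    sp: DiagnosticEstimate | None
    ac: DiagnosticEstimate
    screening_load: int
    heuristic: bool = False


def _check_databases(labeled: LabeledCorpus, databases: Iterable[str]) -> tuple[str, ...]:
    dbs = tuple(dict.fromkeys(databases))  # order-preserving dedup
    if not dbs:
        raise ValueError("database set must be non-empty")
    unknown = [db for db in dbs if db not in labeled.databases]
    if unknown:
        raise KeyError(f"unknown databases: {unknown}")
    return dbs


def union_coverage(labeled: LabeledCorpus, databases: Iterable[str]) -> frozenset[str]:
    """Cluster ids covered by at least one member database."""
    dbs = _check_databases(labeled, databases)
    covered: set[str] = set()
    for db in dbs:
        covered |= labeled.coverage[db]
    return frozenset(covered)


def screening_load(labeled: LabeledCorpus, databases: Iterable[str]) -> int:
    """Raw records to screen: the sum of member yields, duplicates included."""
    dbs = tuple(dict.fromkeys(databases))
    unknown = [db for db in dbs if db not in labeled.databases]
    if unknown:
        raise KeyError(f"unknown databases: {unknown}")
    return sum(labeled.yields[db] for db in dbs)


def union_contingency(
    labeled: LabeledCorpus,
    databases: Iterable[str],
    dedup_universe: bool = False,
) -> ContingencyTable:
    """The 2x2 table of a database union.

    With ``dedup_universe=False`` (default) FP/TN are computed on the
    pooled screening-load universe (summed duplicate-inclusive yields);
    with ``dedup_universe=True`` FP counts unique irrelevant clusters in
    the union and TN the unique irrelevant clusters outside it.
    """
    dbs = _check_databases(labeled, databases)
    covered_eligible = union_coverage(labeled, dbs) & labeled.eligible_ids
    tp = len(covered_eligible)
    fn = labeled.n_eligible - tp
    if dedup_universe:
        covered = union_coverage(labeled, dbs)
        fp = len(covered) - tp
        n_unique = len(labeled.clusters)
        tn = (n_unique - labeled.n_eligible) - fp
    else:
        load = screening_load(labeled, dbs)
        fp = load - tp
        tn = max(labeled.pooled_size - load, 0)
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_combination(
    labeled: LabeledCorpus,
    databases: Iterable[str],
    level: float = 0.95,
    dedup_universe: bool = False,
    heuristic: bool = False,
) -> CombinationResult:
    dbs = _check_databases(labeled, databases)
    ct = union_contingency(labeled, dbs, dedup_universe=dedup_universe)
    sp = specificity(ct, level) if ct.tn + ct.fp > 0 else None
    return CombinationResult(
        databases=tuple(sorted(dbs)),
        contingency=ct,
        se=sensitivity(ct, level),
        sp=sp,
        ac=accuracy(ct, level),
        screening_load=screening_load(labeled, dbs),
        heuristic=heuristic,
    )


def pairwise_matrix(
    labeled: LabeledCorpus,
    level: float = 0.95,
    dedup_universe: bool = False,
) -> pd.DataFrame:
    """Se/Sp/Ac of every unordered database pair (long format, one row per pair)."""
    dbs = labeled.databases
    if len(dbs) < 2:
        raise ValueError("pairwise matrix requires at least two databases")
    rows = []
    for a, b in _combos(dbs, 2):
        res = evaluate_combination(labeled, (a, b), level, dedup_universe)
        rows.append(
            {
                "db_a": a,
                "db_b": b,
                "tp": res.contingency.tp,
                "sensitivity": res.se.point,
                "specificity": res.sp.point if res.sp else float("nan"),
                "accuracy": res.ac.point,
                "screening_load": res.screening_load,
                "cell": _cell_text(res),
            }
        )
    return pd.DataFrame(rows)


def _cell_text(res: CombinationResult) -> str:
    sp_txt = format_estimate(res.sp).split(" ")[0] if res.sp else "-"
    return (
        f"Se {format_estimate(res.se).split(' ')[0]}"
        f"/Sp {sp_txt}"
        f"/Ac {format_estimate(res.ac).split(' ')[0]}"
    )


def render_pairwise(matrix: pd.DataFrame, databases: Sequence[str]) -> pd.DataFrame:
    """Reshape the long pair table into an upper-triangular display grid."""
    grid = pd.DataFrame("", index=list(databases), columns=list(databases))
    for row in matrix.itertuples():
        grid.loc[row.db_a, row.db_b] = row.cell
    return grid


def minimal_cover(
    labeled: LabeledCorpus,
    target_se: float = 1.0,
    max_size: int = 3,
    level: float = 0.95,
    dedup_universe: bool = False,
) -> list[CombinationResult]:
    """Smallest database combinations reaching a target union sensitivity.

    Enumerates all subsets up to ``max_size`` exhaustively when the corpus
    has at most 15 databases; beyond that a greedy marginal-coverage
    heuristic is used and the results are flagged ``heuristic=True``.
    Qualifying combinations are returned best-first, ordered by subset
    size, then screening load, then label tuple. An empty list (with a
    warning) means the target is unreachable even with every database.
    """
    if not 0.0 < target_se <= 1.0:
        raise ValueError("target_se must lie in (0, 1]")
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    dbs = labeled.databases
    if labeled.n_eligible == 0:
        raise ValueError("no eligible publications: target sensitivity is undefined")

    all_se = len(union_coverage(labeled, dbs) & labeled.eligible_ids) / labeled.n_eligible
    if all_se < target_se:
        warnings.warn(
            f"target sensitivity {target_se:.2f} unreachable: union of all "
            f"{len(dbs)} databases reaches {all_se:.2f}",
            stacklevel=2,
        )
        return []

    if len(dbs) <= EXHAUSTIVE_DB_LIMIT:
        hits = []
        for size in range(1, min(max_size, len(dbs)) + 1):
            for subset in _combos(sorted(dbs), size):
                res = evaluate_combination(
                    labeled, subset, level, dedup_universe, heuristic=False
                )
                if res.se.point >= target_se:
                    hits.append(res)
        hits.sort(key=lambda r: (len(r.databases), r.screening_load, r.databases))
        return hits

    # Greedy marginal-coverage heuristic for very wide corpora.
    chosen: list[str] = []
    covered: set[str] = set()
    eligible = labeled.eligible_ids
    while len(chosen) < max_size:
        best_db, best_gain = None, -1
        for db in sorted(set(dbs) - set(chosen)):
            gain = len((labeled.coverage[db] & eligible) - covered)
            if gain > best_gain or (
                gain == best_gain and best_db is not None
                and labeled.yields[db] < labeled.yields[best_db]
            ):
                best_db, best_gain = db, gain
        assert best_db is not None
        chosen.append(best_db)
        covered |= labeled.coverage[best_db] & eligible
        if len(covered) / labeled.n_eligible >= target_se:
            return [
                evaluate_combination(
                    labeled, chosen, level, dedup_universe, heuristic=True
                )
            ]
    return []
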