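"""Retrieval diagnostics: 2x2 contingency tables and exact binomial intervals.

Each database is scored as a diagnostic test against the reference set of
eligible publications found across *all* databases:

* TP — eligible unique publications present in the database's yield;
* FP — the remaining (irrelevant, duplicate-inclusive) records in the
  yield, i.e. yield − TP;
* FN — eligible publications the database missed;
* TN — pooled corpus size − yield (irrelevant records not in the yield).

Note the deliberate asymmetry of this convention: TP and FN count unique
publications while FP and TN count raw pooled records, so the 2x2 total is
``pooled + eligible − TP`` and differs across databases. It is preserved
as-is because it is how retrieval-coverage studies tabulate their data.

Sensitivity = TP/(TP+FN) (identical to "coverage"), specificity =
TN/(TN+FP), and accuracy = sensitivity x prevalence + specificity x
(1 − prevalence) with prevalence = (TP+FN)/total, which collapses
algebraically to (TP+TN)/total. All interval estimates are Clopper–Pearson
exact binomial intervals (guaranteed >= nominal coverage); the accuracy
interval treats TP+TN of total as a single binomial count, a stated
convention of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .screening import LabeledCorpus

__all__ = [
    "ContingencyTable",
    "DiagnosticEstimate",
    "UndefinedEstimateError",
    "clopper_pearson",
    "sensitivity",
    "specificity",
    "accuracy",
    "build_contingency",
    "contingency_from_counts",
    "diagnostics_table",
    "percent",
    "format_estimate",
]

DEFAULT_LEVEL = 0.95


class UndefinedEstimateError(ZeroDivisionError):
    """The requested proportion has an empty denominator."""


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts for one database (or database union)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_eligible(self) -> int:
        return self.tp + self.fn

    @property
    def db_yield(self) -> int:
        return self.tp + self.fp

    @property
    def prevalence(self) -> float:
        if self.total == 0:
            raise UndefinedEstimateError("empty contingency table")
        return self.n_eligible / self.total


@dataclass(frozen=True)
class DiagnosticEstimate:
    """A proportion k/n with its exact binomial confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    level: float = DEFAULT_LEVEL

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0:
            raise ValueError(
                f"interval must satisfy 0 <= low <= point <= high <= 1, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )

    def __str__(self) -> str:
        return format_estimate(self)


def percent(p: float) -> int:
    """Half-up rounding of a proportion to an integer percent."""
    return int(math.floor(100.0 * p + 0.5))


def format_estimate(est: DiagnosticEstimate) -> str:
    """Render as the conventional ``"88% (79-94%)"`` integer-percent string."""
    return f"{percent(est.point)}% ({percent(est.ci_low)}-{percent(est.ci_high)}%)"


def clopper_pearson(
    k: int, n: int, level: float = DEFAULT_LEVEL
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k successes of n.

    The lower bound is the (1−level)/2 quantile of Beta(k, n−k+1) (0 when
    k = 0) and the upper bound the 1−(1−level)/2 quantile of
    Beta(k+1, n−k) (1 when k = n).
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def _estimate(k: int, n: int, level: float) -> DiagnosticEstimate:
    lower, upper = clopper_pearson(k, n, level)
    return DiagnosticEstimate(
        point=k / n, ci_low=lower, ci_high=upper, k=k, n=n, level=level
    )


def sensitivity(ct: ContingencyTable, level: float = DEFAULT_LEVEL) -> DiagnosticEstimate:
    """TP/(TP+FN): the fraction of eligible publications the database covers."""
    if ct.tp + ct.fn == 0:
        raise UndefinedEstimateError("sensitivity undefined: no eligible publications")
    return _estimate(ct.tp, ct.tp + ct.fn, level)


def specificity(ct: ContingencyTable, level: float = DEFAULT_LEVEL) -> DiagnosticEstimate:
    """TN/(TN+FP): the fraction of irrelevant records the database excludes."""
    if ct.tn + ct.fp == 0:
        raise UndefinedEstimateError("specificity undefined: no irrelevant records")
    return _estimate(ct.tn, ct.tn + ct.fp, level)


def accuracy(ct: ContingencyTable, level: float = DEFAULT_LEVEL) -> DiagnosticEstimate:
    """Se x prevalence + Sp x (1 − prevalence), algebraically (TP+TN)/total."""
    if ct.total == 0:
        raise UndefinedEstimateError("accuracy undefined: empty table")
    return _estimate(ct.tp + ct.tn, ct.total, level)


def build_contingency(labeled: LabeledCorpus, database: str) -> ContingencyTable:
    """The database's 2x2 table under the retrieval-coverage convention."""
    if database not in labeled.databases:
        raise KeyError(f"unknown database {database!r}")
    tp = len(labeled.eligible_covered_by(database))
    db_yield = labeled.yields[database]
    return ContingencyTable(
        tp=tp,
        fp=db_yield - tp,
        fn=labeled.n_eligible - tp,
        tn=labeled.pooled_size - db_yield,
    )


def contingency_from_counts(
    tp: int, db_yield: int, n_eligible: int, pooled: int
) -> ContingencyTable:
    """Build a 2x2 table from published marginal counts.

    Useful when only the per-database coverage count (TP), the per-database
    yield, the eligible total and the pooled total are reported — the four
    cells follow from the convention in the module docstring.
    """
    return ContingencyTable(
        tp=tp, fp=db_yield - tp, fn=n_eligible - tp, tn=pooled - db_yield
    )


def _row(
    database: str, ct: ContingencyTable, level: float
) -> dict[str, object]:
    row: dict[str, object] = {
        "database": database,
        "tp": ct.tp,
        "fp": ct.fp,
        "fn": ct.fn,
        "tn": ct.tn,
        "coverage": ct.tp,
    }
    for name, fn in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("accuracy", accuracy),
    ):
        try:
            est = fn(ct, level)
        except UndefinedEstimateError:
            row[name] = float("nan")
            row[f"{name}_low"] = float("nan")
            row[f"{name}_high"] = float("nan")
            row[f"{name}_pct"] = ""
        else:
            row[name] = est.point
            row[f"{name}_low"] = est.ci_low
            row[f"{name}_high"] = est.ci_high
            row[f"{name}_pct"] = format_estimate(est)
    return row


def diagnostics_table(
    labeled: LabeledCorpus | None = None,
    level: float = DEFAULT_LEVEL,
    *,
    tables: Mapping[str, ContingencyTable] | None = None,
) -> pd.DataFrame:
    """Per-database coverage, sensitivity, specificity and accuracy with CIs.

    One row per database, in corpus order. Full-precision proportions are
    kept in the ``sensitivity``/``specificity``/``accuracy`` (and ``_low``,
    ``_high``) columns; ``*_pct`` columns carry the rendered
    integer-percent strings. Either a labeled corpus or a precomputed
    mapping of contingency tables may be supplied.
    """
    if (labeled is None) == (tables is None):
        raise ValueError("supply exactly one of labeled corpus or tables")
    if tables is None:
        assert labeled is not None
        tables = {db: build_contingency(labeled, db) for db in labeled.databases}
    rows = [_row(db, ct, level) for db, ct in tables.items()]
    return pd.DataFrame(rows)
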