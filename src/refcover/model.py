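"""Model/Results interface over the coverage-diagnostics pipeline.

:class:`DatabaseCoverage` is the entry point for a whole analysis: it is
built either from per-record data (a pooled corpus plus screening labels,
deduplicating internally if needed) or from published marginal counts, and
its :meth:`~DatabaseCoverage.fit` returns a :class:`CoverageResults`
carrying the per-database diagnostic estimates with their exact binomial
intervals, the record-flow ledger, and — when per-record data are
available — pairwise-combination diagnostics and minimal-cover search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import combinations as _comb
from .dedup import DedupCluster, cluster_duplicates, DEFAULT_FUZZY_THRESHOLD
from .diagnostics import (
    ContingencyTable,
    build_contingency,
    contingency_from_counts,
    diagnostics_table,
    percent,
)
from .records import PooledCorpus, pooled_yield_table
from .screening import (
    FlowLedger,
    LabeledCorpus,
    ScreeningLabel,
    apply_labels,
    flow_ledger,
)

__all__ = ["DatabaseCoverage", "CoverageResults"]


class DatabaseCoverage:
    """Retrieval-coverage model of a multi-database literature search.

    Parameters
    ----------
    labeled : a labeled corpus (records + dedup clusters + eligibility
        labels). Use one of the constructors for other input shapes.
    """

    def __init__(self, labeled: LabeledCorpus) -> None:
        self.labeled: LabeledCorpus | None = labeled
        self._tables: dict[str, ContingencyTable] | None = None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_corpus(
        cls,
        corpus: PooledCorpus,
        labels: Iterable[ScreeningLabel],
        clusters: Sequence[DedupCluster] | None = None,
        fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD,
    ) -> "DatabaseCoverage":
        """Build from a pooled corpus, deduplicating if clusters not given."""
        if clusters is None:
            clusters = cluster_duplicates(corpus, fuzzy_threshold)
        return cls(apply_labels(corpus, clusters, labels))

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        n_eligible: int,
        pooled: int,
    ) -> "DatabaseCoverage":
        """Build from published marginal counts.

        ``counts`` needs columns ``database`` (label), ``tp`` (eligible
        publications covered) and ``yield`` (total records retrieved).
        Only single-database diagnostics are available on this path:
        combination analyses need per-record overlap data.
        """
        model = cls.__new__(cls)
        model.labeled = None
        model._tables = {
            str(row["database"]): contingency_from_counts(
                tp=int(row["tp"]),
                db_yield=int(row["yield"]),
                n_eligible=n_eligible,
                pooled=pooled,
            )
            for _, row in counts.iterrows()
        }
        return model

    # -- estimation ---------------------------------------------------

    def contingency(self, database: str) -> ContingencyTable:
        if self._tables is not None:
            return self._tables[database]
        assert self.labeled is not None
        return build_contingency(self.labeled, database)

    @property
    def databases(self) -> tuple[str, ...]:
        if self._tables is not None:
            return tuple(self._tables)
        assert self.labeled is not None
        return self.labeled.databases

    def fit(self, level: float = 0.95) -> "CoverageResults":
        """Estimate per-database diagnostics at the given confidence level."""
        tables = {db: self.contingency(db) for db in self.databases}
        diag = diagnostics_table(tables=tables, level=level)
        flow = flow_ledger(self.labeled) if self.labeled is not None else None
        yields = (
            pooled_yield_table(self.labeled.corpus)
            if self.labeled is not None
            else None
        )
        return CoverageResults(
            model=self, diagnostics=diag, flow=flow, yield_table=yields, level=level
        )


@dataclass
class CoverageResults:
    """Fitted per-database retrieval diagnostics."""

    model: DatabaseCoverage
    diagnostics: pd.DataFrame
    flow: FlowLedger | None
    yield_table: pd.DataFrame | None
    level: float

    def estimate(self, database: str, measure: str) -> float:
        """Point estimate (proportion) for one database and measure."""
        row = self.diagnostics.set_index("database").loc[database]
        return float(row[measure])

    def conf_int(self, database: str, measure: str) -> tuple[float, float]:
        row = self.diagnostics.set_index("database").loc[database]
        return float(row[f"{measure}_low"]), float(row[f"{measure}_high"])

    # -- combination analyses (need per-record data) -------------------

    def _labeled(self) -> LabeledCorpus:
        if self.model.labeled is None:
            raise ValueError(
                "combination analyses require per-record data; this model was "
                "built from marginal counts"
            )
        return self.model.labeled

    def pairwise(self, dedup_universe: bool = False) -> pd.DataFrame:
        return _comb.pairwise_matrix(
            self._labeled(), level=self.level, dedup_universe=dedup_universe
        )

    def minimal_cover(
        self,
        target_se: float = 1.0,
        max_size: int = 3,
        dedup_universe: bool = False,
    ) -> list[_comb.CombinationResult]:
        return _comb.minimal_cover(
            self._labeled(),
            target_se=target_se,
            max_size=max_size,
            level=self.level,
            dedup_universe=dedup_universe,
        )

    def screening_load(self, databases: Iterable[str]) -> int:
        return _comb.screening_load(self._labeled(), databases)

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table in the style of a fitted-model report."""
        lines = [
            "Database retrieval-coverage diagnostics",
            "=" * 78,
        ]
        if self.flow is not None:
            lines.append(
                f"Records: {self.flow.pooled} pooled = "
                f"{self.flow.duplicates} duplicates + "
                f"{self.flow.ineligible} ineligible + "
                f"{self.flow.eligible} eligible"
            )
            lines.append("-" * 78)
        lines.append(
            f"{'database':<32}{'TP':>5}{'FP':>5}{'FN':>5}{'TN':>6}"
            f"{'Se':>10}{'Sp':>10}{'Ac':>10}"
        )
        for _, row in self.diagnostics.iterrows():
            def pct(v: object) -> str:
                try:
                    return f"{percent(float(v))}%"  # type: ignore[arg-type]
                except (TypeError, ValueError):
                    return "-"
            lines.append(
                f"{row['database']:<32}{row['tp']:>5}{row['fp']:>5}"
                f"{row['fn']:>5}{row['tn']:>6}"
                f"{pct(row['sensitivity']):>10}{pct(row['specificity']):>10}"
                f"{pct(row['accuracy']):>10}"
            )
        lines.append("=" * 78)
        lines.append(
            f"{int(round(self.level * 100))}% intervals are exact "
            "(Clopper-Pearson); accuracy interval treats TP+TN as one "
            "binomial count."
        )
        return "\n".join(lines)
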