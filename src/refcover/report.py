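"""End-to-end pipeline runs and table-shaped report bundles.

A run is described by a single config file (YAML or JSON) naming the
per-database input files, the dedup threshold, confidence level and union
convention. ``run_pipeline`` ingests, deduplicates, screens, computes
per-database diagnostics, the pairwise-combination matrix and the
minimal-cover search, and writes every report as CSV plus a Markdown
rendering, together with a stage-by-stage run log (record counts in and
out of every stage) so each value can be re-derived from the persisted
intermediates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .combinations import render_pairwise
from .dedup import DEFAULT_FUZZY_THRESHOLD, cluster_duplicates, write_clusters_csv
from .model import CoverageResults, DatabaseCoverage
from .records import PooledCorpus, pooled_yield_table, read_records, write_records_csv
from .screening import flow_ledger, read_labels_csv, write_labels_csv

__all__ = ["InputFile", "RunConfig", "ReportBundle", "run_pipeline"]


@dataclass(frozen=True)
class InputFile:
    path: str
    format: str
    database: str


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, loadable from YAML/JSON."""

    inputs: tuple[InputFile, ...]
    labels: str
    outdir: str
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD
    level: float = 0.95
    dedup_universe: bool = False
    target_se: float = 1.0
    max_size: int = 3
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        inputs = tuple(InputFile(**item) for item in data.pop("inputs"))
        return cls(inputs=inputs, **data)

    def validate(self) -> None:
        missing = [i.path for i in self.inputs if not Path(i.path).exists()]
        if self.labels and not Path(self.labels).exists():
            missing.append(self.labels)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class ReportBundle:
    yield_table: pd.DataFrame
    flow: dict
    diagnostics: pd.DataFrame
    pairwise: pd.DataFrame
    minimal_cover: pd.DataFrame
    results: CoverageResults
    outdir: Path


def _md_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _write(df: pd.DataFrame, outdir: Path, stem: str) -> None:
    df.to_csv(outdir / f"{stem}.csv", index=False)
    (outdir / f"{stem}.md").write_text(_md_table(df), encoding="utf-8")


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run ingest → dedup → screen → diagnostics → combinations, persisting all stages."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {json.dumps(dataclasses.asdict(config), sort_keys=True)}"]

    def stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    records = []
    for item in config.inputs:
        recs = stage("ingest")(read_records, item.path, item.format, item.database)
        log.append(f"ingest: {item.database}: {len(recs)} records from {item.path}")
        records.extend(recs)
    corpus = PooledCorpus.from_records(
        records, databases=tuple(dict.fromkeys(i.database for i in config.inputs))
    )
    write_records_csv(corpus.records, outdir / "corpus.csv")

    clusters = stage("dedup")(cluster_duplicates, corpus, config.fuzzy_threshold)
    write_clusters_csv(clusters, outdir / "clusters.csv")
    log.append(f"dedup: {len(corpus)} records -> {len(clusters)} unique clusters")

    labels = stage("screen")(read_labels_csv, config.labels) if config.labels else []
    write_labels_csv(labels, outdir / "labels.csv")
    model = stage("screen")(
        DatabaseCoverage.from_corpus, corpus, labels, clusters=clusters
    )
    results = stage("diagnostics")(model.fit, config.level)
    assert results.flow is not None and results.yield_table is not None
    log.append(
        "screen: "
        f"pooled {results.flow.pooled} = duplicates {results.flow.duplicates} "
        f"+ ineligible {results.flow.ineligible} + eligible {results.flow.eligible}"
    )

    _write(results.yield_table, outdir, "yield_table")
    (outdir / "flow_ledger.json").write_text(
        json.dumps(dataclasses.asdict(results.flow), indent=2) + "\n", encoding="utf-8"
    )
    _write(results.diagnostics, outdir, "diagnostics")

    if len(corpus.databases) >= 2:
        pairwise = stage("combinations")(results.pairwise, config.dedup_universe)
    else:
        pairwise = pd.DataFrame()
    _write(pairwise, outdir, "pairwise")
    if not pairwise.empty:
        grid = render_pairwise(pairwise, corpus.databases)
        grid.insert(0, "database", grid.index)
        _write(grid.reset_index(drop=True), outdir, "pairwise_grid")

    if results.flow.eligible > 0:
        cover = stage("combinations")(
            results.minimal_cover, config.target_se, config.max_size,
            config.dedup_universe,
        )
    else:
        cover = []
    cover_df = pd.DataFrame(
        [
            {
                "databases": " + ".join(r.databases),
                "size": len(r.databases),
                "sensitivity": r.se.point,
                "screening_load": r.screening_load,
                "heuristic": r.heuristic,
            }
            for r in cover
        ],
        columns=["databases", "size", "sensitivity", "screening_load", "heuristic"],
    )
    _write(cover_df, outdir, "minimal_cover")
    log.append(
        f"combinations: {len(pairwise)} pairs; "
        f"{len(cover_df)} combinations reach target Se {config.target_se}"
    )
    log.append(
        f"conventions: fuzzy_threshold={config.fuzzy_threshold} "
        f"level={config.level} dedup_universe={config.dedup_universe}"
    )
    (outdir / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")

    return ReportBundle(
        yield_table=results.yield_table,
        flow=dataclasses.asdict(results.flow),
        diagnostics=results.diagnostics,
        pairwise=pairwise,
        minimal_cover=cover_df,
        results=results,
        outdir=outdir,
    )
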