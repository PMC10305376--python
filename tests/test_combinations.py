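"""Database unions, pairwise efficacy, and minimal-cover search."""

import itertools

import pytest

from refcover.combinations import (
    evaluate_combination,
    minimal_cover,
    pairwise_matrix,
    render_pairwise,
    screening_load,
    union_contingency,
)
from refcover.dedup import cluster_duplicates
from refcover.diagnostics import build_contingency
from refcover.model import DatabaseCoverage
from refcover import synthetic
from conftest import naive_union_counts


def _random_labeled(n_db, seed, n_eligible=20, irr=12, coverage=(0.8, 0.5, 0.3)):
    spec = synthetic.SyntheticSpec(
        n_eligible=n_eligible,
        databases=tuple(
            synthetic.DatabaseProfile(f"DB{i}", coverage[i % len(coverage)], irr)
            for i in range(n_db)
        ),
        seed=seed,
    )
    corpus, _, labels = synthetic.generate(spec)
    return DatabaseCoverage.from_corpus(corpus, labels).labeled


def test_union_with_itself_is_single_database(small_labeled):
    for db in small_labeled.databases:
        assert union_contingency(small_labeled, [db, db]) == build_contingency(
            small_labeled, db
        )


def test_union_with_zero_yield_database_is_identity():
    labeled = _random_labeled(3, seed=4)
    # DB3 exists in name only: rebuild with an empty extra database.
    corpus = labeled.corpus
    from refcover.records import PooledCorpus

    wide = PooledCorpus(records=corpus.records, databases=corpus.databases + ("EMPTY",))
    labeled2 = DatabaseCoverage.from_corpus(
        wide, list(labeled.labels.values()), clusters=labeled.clusters
    ).labeled
    for db in corpus.databases:
        assert union_contingency(labeled2, [db, "EMPTY"]) == build_contingency(
            labeled2, db
        )


def test_union_rejects_empty_set(small_labeled):
    with pytest.raises(ValueError):
        union_contingency(small_labeled, [])
    with pytest.raises(KeyError):
        union_contingency(small_labeled, ["A", "nope"])


def test_screening_load_sums_duplicate_inclusive_yields(small_labeled):
    assert screening_load(small_labeled, ["A", "B"]) == 5
    assert screening_load(small_labeled, []) == 0
    assert screening_load(small_labeled, small_labeled.databases) == len(
        small_labeled.corpus
    )


def test_study_preset_full_union_pair():
    corpus, _, labels = synthetic.generate_study(seed=3)
    labeled = DatabaseCoverage.from_corpus(corpus, labels).labeled
    ct = union_contingency(labeled, ["Cochrane Central", "PubMed"])
    assert ct.tp == labeled.n_eligible == 76
    assert screening_load(labeled, ["Cochrane Central", "PubMed"]) == 141 + 138


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pairwise_matrix_matches_naive_recount(seed):
    labeled = _random_labeled(5, seed=seed)
    matrix = pairwise_matrix(labeled)
    assert len(matrix) == 10  # 5 choose 2
    for row in matrix.itertuples():
        want = naive_union_counts(labeled, (row.db_a, row.db_b))
        assert row.tp == want["tp"]
        assert row.screening_load == want["load"]
        assert row.sensitivity == pytest.approx(want["tp"] / labeled.n_eligible)
        denom = want["tn"] + want["fp"]
        if denom:
            assert row.specificity == pytest.approx(want["tn"] / denom)


def test_pair_symmetry(small_labeled):
    ab = evaluate_combination(small_labeled, ("A", "B"))
    ba = evaluate_combination(small_labeled, ("B", "A"))
    assert ab == ba


def test_twelve_databases_give_66_pairs():
    corpus, _, labels = synthetic.generate_study(seed=0)
    labeled = DatabaseCoverage.from_corpus(corpus, labels).labeled
    assert len(pairwise_matrix(labeled)) == 66


def test_render_pairwise_upper_triangular(small_labeled):
    grid = render_pairwise(pairwise_matrix(small_labeled), small_labeled.databases)
    assert grid.loc["A", "B"].startswith("Se ")
    assert grid.loc["B", "A"] == ""
    assert grid.loc["A", "A"] == ""


def test_union_sensitivity_monotone_in_set_growth():
    labeled = _random_labeled(6, seed=9)
    dbs = list(labeled.databases)
    prev = 0.0
    for size in range(1, len(dbs) + 1):
        ct = union_contingency(labeled, dbs[:size])
        se = ct.tp / (ct.tp + ct.fn)
        assert se >= prev
        prev = se


def test_specificity_drops_when_adding_uninformative_yield():
    """Adding a database with yield but no new eligible coverage lowers Sp."""
    labeled = _random_labeled(3, seed=2, coverage=(0.8, 0.5, 0.0))
    base = union_contingency(labeled, ["DB0", "DB1"])
    assert not labeled.eligible_covered_by("DB2")
    assert labeled.yields["DB2"] > 0
    wider = union_contingency(labeled, ["DB0", "DB1", "DB2"])
    assert wider.tn / (wider.tn + wider.fp) < base.tn / (base.tn + base.fp)


class TestMinimalCover:
    def test_single_covering_database_is_optimal(self):
        spec = synthetic.SyntheticSpec(
            n_eligible=10,
            databases=(
                synthetic.DatabaseProfile("FULL", 1.0, 5),
                synthetic.DatabaseProfile("HALF", 0.5, 1),
            ),
            seed=0,
        )
        corpus, _, labels = synthetic.generate(spec)
        labeled = DatabaseCoverage.from_corpus(corpus, labels).labeled
        best = minimal_cover(labeled, target_se=1.0, max_size=2)[0]
        assert best.databases == ("FULL",)

    def test_study_preset_best_pair(self):
        corpus, _, labels = synthetic.generate_study(seed=1)
        labeled = DatabaseCoverage.from_corpus(corpus, labels).labeled
        results = minimal_cover(labeled, target_se=1.0, max_size=2)
        assert results, "full coverage must be reachable with two databases"
        best = results[0]
        assert best.databases == ("Cochrane Central", "PubMed")
        assert best.se.point == 1.0
        assert best.screening_load == 279
        assert not best.heuristic

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exhaustive_equals_subset_enumeration(self, seed):
        labeled = _random_labeled(6, seed=seed, n_eligible=15, irr=6)
        target = 0.9
        got = minimal_cover(labeled, target_se=target, max_size=3)
        # Brute-force oracle over all subsets of size <= 3.
        hits = []
        for size in (1, 2, 3):
            for subset in itertools.combinations(sorted(labeled.databases), size):
                counts = naive_union_counts(labeled, subset)
                se = counts["tp"] / labeled.n_eligible
                if se >= target:
                    hits.append((size, counts["load"], subset, se))
        hits.sort()
        assert [r.databases for r in got] == [h[2] for h in hits]
        assert [r.se.point for r in got] == pytest.approx([h[3] for h in hits])

    def test_no_combination_within_max_size_returns_empty(self):
        # Many weak databases: no singleton reaches full coverage, so a
        # max_size=1 search comes back empty even though the union of all
        # databases does (every eligible cluster has at least one record).
        labeled = _random_labeled(6, seed=5, n_eligible=25, coverage=(0.4, 0.3))
        singles = max(
            naive_union_counts(labeled, (db,))["tp"] for db in labeled.databases
        )
        assert singles < labeled.n_eligible
        assert minimal_cover(labeled, target_se=1.0, max_size=1) == []
        assert minimal_cover(labeled, target_se=1.0, max_size=6)

    def test_greedy_heuristic_beyond_exhaustive_limit(self):
        spec = synthetic.SyntheticSpec(
            n_eligible=12,
            databases=tuple(
                synthetic.DatabaseProfile(f"D{i:02d}", 0.45, 3) for i in range(16)
            ),
            seed=8,
        )
        corpus, _, labels = synthetic.generate(spec)
        labeled = DatabaseCoverage.from_corpus(corpus, labels).labeled
        exhaustive_best = None
        for size in (1, 2, 3):
            for subset in itertools.combinations(sorted(labeled.databases), size):
                se = naive_union_counts(labeled, subset)["tp"] / labeled.n_eligible
                if se >= 0.9:
                    exhaustive_best = (size, subset, se)
                    break
            if exhaustive_best:
                break
        greedy = minimal_cover(labeled, target_se=0.9, max_size=3)
        if greedy:
            assert greedy[0].heuristic
            assert greedy[0].se.point >= 0.9
            if exhaustive_best:
                # Greedy can never beat the exhaustive optimum's size.
                assert len(greedy[0].databases) >= exhaustive_best[0]
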