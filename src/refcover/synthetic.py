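"""Synthetic multi-database corpora with planted ground truth.

Real database-coverage studies cannot share their raw exports, so every
pipeline stage here is exercised on generated corpora instead: a set of
unique publications (eligible trials plus irrelevant records) is planted
across databases, each copy is emitted as a bibliographic record with
optional title perturbations and missing DOIs, and the generator returns
the planted facts (indexing matrix, eligibility flags) as ground truth.

Two constrained presets reconstruct the marginal structure of the
motivating coverage study of randomized trials for central serous
chorioretinopathy across 12 literature databases:

* :func:`study_preset` plants the published per-database eligible-coverage
  counts (32, 12, 66, 44, 0, 0, 67, 4, 28, 57, 0, 51 of 76) and
  per-database yields (80, 26, 141, 97, 0, 0, 184, 4, 102, 138, 2, 126),
  with the Cochrane Central / PubMed overlap drawn so their union covers
  all 76 eligible trials. The published yields sum to 900, so the preset
  corpus pools 900 records; the study's own printed total (848) is
  inconsistent with its yield column and is not forced.
* :func:`flow_preset` plants the published screening flow exactly:
  848 pooled records = 547 duplicates + 225 ineligible + 76 eligible.

Both presets are *reconstructions*: they satisfy the published marginals
but invent the unprinted overlap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dedup import normalize_title, title_similarity
from .records import PooledCorpus, Record
from .screening import ELIGIBLE, INELIGIBLE, ScreeningLabel

__all__ = [
    "DatabaseProfile",
    "SyntheticSpec",
    "Publication",
    "GroundTruth",
    "IndexingConstraints",
    "generate",
    "study_preset",
    "generate_study",
    "flow_preset",
    "STUDY_DATABASES",
]

# Label, eligible-coverage count (of 76), total yield — the published
# per-database marginals the study presets reconstruct.
STUDY_DATABASES: tuple[tuple[str, int, int], ...] = (
    ("BIOSIS Previews", 32, 80),
    ("CINAHL", 12, 26),
    ("Cochrane Central", 66, 141),
    ("Current Contents Connect", 44, 97),
    ("Data Citation Index", 0, 0),
    ("Derwent Innovations Index", 0, 0),
    ("EMBASE", 67, 184),
    ("KCI-Korean Journal Database", 4, 4),
    ("MEDLINE", 28, 102),
    ("PubMed", 57, 138),
    ("SciELO Citation Index", 0, 2),
    ("Web of Science Core Collection", 51, 126),
)

N_ELIGIBLE_STUDY = 76
FULL_UNION_PAIR = ("Cochrane Central", "PubMed")

# Distinct publications never share a year with normalized-title similarity
# at or above this bound, so default-threshold dedup recovers the planted
# clustering exactly for every seed.
_TITLE_SEPARATION = 0.88

_WORD_POOL = (
    "retinal choroidal serous macular subretinal fluid photodynamic therapy "
    "verteporfin micropulse laser eplerenone spironolactone mineralocorticoid "
    "antagonist bevacizumab ranibizumab aflibercept intravitreal subthreshold "
    "half dose fluence treatment outcomes visual acuity resolution chronic "
    "acute central chorioretinopathy pigment epithelium detachment thickness "
    "randomized controlled trial placebo sham comparison efficacy safety "
    "observation mifepristone rifampicin melatonin propranolol metoprolol "
    "ketoconazole finasteride aspirin anticoagulant photocoagulation grid "
    "focal navigated yellow green diode transpupillary thermotherapy oral "
    "topical nonsteroidal dorzolamide timolol steroid cessation stress "
    "cortisol helicobacter eradication pylori obstructive sleep apnea "
    "continuous positive airway pressure lifestyle modification followup "
    "month week year baseline endpoint angiography tomography coherence "
    "optical fundus autofluorescence indocyanine leakage hyperpermeability "
    "pachychoroid vessel recurrence persistent resolved bilateral unilateral "
    "prospective multicenter single blind double masked crossover parallel "
    "pilot feasibility dosage regimen adjunct combined monotherapy response "
    "nonresponder morphology function sensitivity microperimetry contrast"
).split()

_FAMILY_NAMES = (
    "Andersen Bergström Chen Dimitrov Eriksen Fischer García Hansen Ivanov "
    "Johansson Kim Larsen Martínez Nakamura Olsen Park Qureshi Rossi Sato "
    "Tanaka Ueda Virtanen Wang Yamada Zhang Nielsen Okafor Petrov Silva Tran"
).split()

_JOURNALS = (
    "Retina",
    "Acta Ophthalmologica",
    "American Journal of Ophthalmology",
    "Ophthalmology Retina",
    "Graefes Archive",
    "Eye",
    "British Journal of Ophthalmology",
    "Investigative Ophthalmology and Visual Science",
)


@dataclass(frozen=True)
class DatabaseProfile:
    """One database's generating parameters.

    ``coverage_p`` is the probability that an eligible publication is
    indexed; ``irrelevant_yield`` the count of irrelevant records the
    database contributes.
    """

    label: str
    coverage_p: float
    irrelevant_yield: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_p <= 1.0:
            raise ValueError(f"coverage_p must lie in [0, 1], got {self.coverage_p}")
        if self.irrelevant_yield < 0:
            raise ValueError("irrelevant_yield must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic corpus draw."""

    n_eligible: int
    databases: tuple[DatabaseProfile, ...]
    duplicate_noise: float = 0.1
    doi_missing_rate: float = 0.1
    irrelevant_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "databases", tuple(self.databases))
        if self.n_eligible < 0:
            raise ValueError("n_eligible must be non-negative")
        for name in ("duplicate_noise", "doi_missing_rate", "irrelevant_overlap"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class Publication:
    """A planted unique publication and the databases carrying a copy."""

    pub_id: str
    title: str
    year: int
    authors: tuple[str, ...]
    journal: str
    doi: str
    eligible: bool
    databases: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    """All planted facts: per-publication indexing sets and eligibility."""

    publications: tuple[Publication, ...]

    @property
    def indexing(self) -> dict[str, frozenset[str]]:
        return {p.pub_id: frozenset(p.databases) for p in self.publications}

    @property
    def eligibility(self) -> dict[str, bool]:
        return {p.pub_id: p.eligible for p in self.publications}

    def coverage_count(self, database: str) -> int:
        """Planted eligible publications carried by the database."""
        return sum(
            1 for p in self.publications if p.eligible and database in p.databases
        )

    @property
    def n_unique_emitted(self) -> int:
        return sum(1 for p in self.publications if p.databases)

    @property
    def pooled_size(self) -> int:
        return sum(len(p.databases) for p in self.publications)


@dataclass(frozen=True)
class IndexingConstraints:
    """Forced indexing plans overriding the spec's probabilistic sampling.

    ``eligible_sets`` maps a database label to the indices (into the
    eligible-publication list) it must carry; ``irrelevant_plan`` maps a
    label to the indices (into the irrelevant-publication list) of its
    irrelevant copies.
    """

    eligible_sets: Mapping[str, frozenset[int]]
    irrelevant_plan: Mapping[str, tuple[int, ...]]
    n_irrelevant: int


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in label.lower())


def _draw_title(rng: np.random.Generator, year_titles: dict[int, list[str]], year: int) -> str:
    """Sample a title well separated from every same-year title."""
    existing = year_titles.setdefault(year, [])
    for _ in range(500):
        n_words = int(rng.integers(5, 9))
        words = rng.choice(len(_WORD_POOL), size=n_words, replace=False)
        title = " ".join(_WORD_POOL[i] for i in words)
        norm = normalize_title(title)
        if all(title_similarity(norm, t) < _TITLE_SEPARATION for t in existing):
            existing.append(norm)
            return title
    raise RuntimeError("could not draw a sufficiently distinct title")


def _make_publications(
    rng: np.random.Generator,
    n_eligible: int,
    n_irrelevant: int,
    eligible_dbs: Sequence[tuple[str, ...]],
    irrelevant_dbs: Sequence[tuple[str, ...]],
) -> list[Publication]:
    year_titles: dict[int, list[str]] = {}
    pubs: list[Publication] = []
    total = n_eligible + n_irrelevant
    for i in range(total):
        eligible = i < n_eligible
        pub_id = f"p{i:04d}"
        year = int(rng.integers(1995, 2024))
        title = _draw_title(rng, year_titles, year)
        n_auth = int(rng.integers(1, 5))
        authors = tuple(
            f"{_FAMILY_NAMES[int(rng.integers(len(_FAMILY_NAMES)))]}, "
            f"{chr(65 + int(rng.integers(26)))}."
            for _ in range(n_auth)
        )
        dbs = eligible_dbs[i] if eligible else irrelevant_dbs[i - n_eligible]
        pubs.append(
            Publication(
                pub_id=pub_id,
                title=title,
                year=year,
                authors=authors,
                journal=str(_JOURNALS[int(rng.integers(len(_JOURNALS)))]),
                doi=f"10.5555/synth.{pub_id}",
                eligible=eligible,
                databases=tuple(dbs),
            )
        )
    return pubs


def _perturb_title(rng: np.random.Generator, title: str) -> str:
    """One of: random-word case flip, punctuation insertion, doubled space."""
    kind = int(rng.integers(3))
    if kind == 0:
        words = title.split()
        i = int(rng.integers(len(words)))
        words[i] = words[i].upper()
        return " ".join(words)
    if kind == 1:
        pos = int(rng.integers(1, len(title)))
        mark = "-:;,!"[int(rng.integers(5))]
        return title[:pos] + mark + title[pos:]
    spaces = [i for i, ch in enumerate(title) if ch == " "]
    if not spaces:
        return title + " "
    pos = spaces[int(rng.integers(len(spaces)))]
    return title[:pos] + "  " + title[pos:]


def _emit(
    pubs: Sequence[Publication],
    databases: Sequence[str],
    duplicate_noise: float,
    doi_missing_rate: float,
    rng: np.random.Generator,
) -> tuple[PooledCorpus, GroundTruth, list[ScreeningLabel]]:
    records: list[Record] = []
    labels: list[ScreeningLabel] = []
    for pub in pubs:
        copy_ids = [f"{_slug(db)}:{pub.pub_id}" for db in pub.databases]
        for db, rec_id in zip(pub.databases, copy_ids):
            title = pub.title
            if rng.random() < duplicate_noise:
                title = _perturb_title(rng, title)
            doi = None if rng.random() < doi_missing_rate else pub.doi
            records.append(
                Record(
                    record_id=rec_id,
                    source_db=db,
                    title=title,
                    authors=pub.authors,
                    year=pub.year,
                    journal=pub.journal,
                    doi=doi,
                )
            )
        if copy_ids:
            # Labels reference the canonical (lexicographically smallest)
            # copy id; apply_labels resolves these against dedup clusters.
            labels.append(
                ScreeningLabel(
                    cluster_id=min(copy_ids),
                    decision=ELIGIBLE if pub.eligible else INELIGIBLE,
                    reason=None if pub.eligible else "not a randomized clinical trial",
                )
            )
    # Corpus order: records grouped by database, in declared database order.
    order = {db: i for i, db in enumerate(databases)}
    records.sort(key=lambda r: (order[r.source_db], r.record_id))
    corpus = PooledCorpus(records=tuple(records), databases=tuple(databases))
    return corpus, GroundTruth(publications=tuple(pubs)), labels


def generate(
    spec: SyntheticSpec, constraints: IndexingConstraints | None = None
) -> tuple[PooledCorpus, GroundTruth, list[ScreeningLabel]]:
    """Draw a corpus, its ground truth and its screening labels.

    Without constraints, each eligible publication is indexed by each
    database independently with the database's ``coverage_p``, and each
    database contributes ``irrelevant_yield`` irrelevant records
    (unique to it by default; with ``irrelevant_overlap`` > 0 a copy is
    drawn from a shared irrelevant pool with that probability). With
    constraints, the planted indexing follows the forced plan exactly.
    Identical (spec, constraints) inputs yield byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    db_labels = [p.label for p in spec.databases]

    if constraints is not None:
        eligible_dbs = [
            tuple(
                db
                for db in db_labels
                if i in constraints.eligible_sets.get(db, frozenset())
            )
            for i in range(spec.n_eligible)
        ]
        n_irrelevant = constraints.n_irrelevant
        irrelevant_sets: list[list[str]] = [[] for _ in range(n_irrelevant)]
        for db in db_labels:
            for j in constraints.irrelevant_plan.get(db, ()):
                irrelevant_sets[j].append(db)
        irrelevant_dbs = [tuple(s) for s in irrelevant_sets]
    else:
        eligible_dbs = [
            tuple(
                p.label for p in spec.databases if rng.random() < p.coverage_p
            )
            for _ in range(spec.n_eligible)
        ]
        irrelevant_sets = []
        shared_pool: list[int] = []
        for profile in spec.databases:
            for _ in range(profile.irrelevant_yield):
                reusable = [
                    j for j in shared_pool
                    if profile.label not in irrelevant_sets[j]
                ]
                if reusable and rng.random() < spec.irrelevant_overlap:
                    j = reusable[int(rng.integers(len(reusable)))]
                    irrelevant_sets[j].append(profile.label)
                else:
                    irrelevant_sets.append([profile.label])
                    shared_pool.append(len(irrelevant_sets) - 1)
        irrelevant_dbs = [tuple(s) for s in irrelevant_sets]
        n_irrelevant = len(irrelevant_dbs)

    pubs = _make_publications(
        rng, spec.n_eligible, n_irrelevant, eligible_dbs, irrelevant_dbs
    )
    return _emit(pubs, db_labels, spec.duplicate_noise, spec.doi_missing_rate, rng)


# ---------------------------------------------------------------------------
# Study-scale presets (reconstructions of published marginals)


def study_preset(seed: int = 0) -> tuple[SyntheticSpec, IndexingConstraints]:
    """Constrained generator reproducing the published per-database marginals.

    Plants exactly the published eligible-coverage counts and total yields
    per database, with the Cochrane Central / PubMed eligible sets drawn
    (seeded) so that their union covers all 76 eligible publications, and
    225 unique irrelevant publications supplying the remaining yield. The
    unprinted overlap structure is invented subject to those constraints.
    """
    rng = np.random.default_rng(seed)
    n = N_ELIGIBLE_STUDY
    counts = {label: cov for label, cov, _ in STUDY_DATABASES}
    central, pubmed = FULL_UNION_PAIR
    # Union must cover all n: overlap = |CENTRAL| + |PubMed| - n.
    perm = rng.permutation(n)
    eligible_sets: dict[str, frozenset[int]] = {
        pubmed: frozenset(int(i) for i in perm[: counts[pubmed]]),
        central: frozenset(int(i) for i in perm[n - counts[central]:]),
    }
    for label, cov, _ in STUDY_DATABASES:
        if label in (central, pubmed):
            continue
        eligible_sets[label] = frozenset(
            int(i) for i in rng.choice(n, size=cov, replace=False)
        )

    irrelevant_counts = {
        label: total - cov for label, cov, total in STUDY_DATABASES
    }
    n_irrelevant = 225
    plan: dict[str, list[int]] = {label: [] for label in irrelevant_counts}
    capacity = dict(irrelevant_counts)
    # Every irrelevant publication appears at least once (there is spare
    # capacity: sum of irrelevant yields is 539 > 225).
    labels_cycle = [label for label, c in capacity.items() if c > 0]
    for j in range(n_irrelevant):
        choices = [lab for lab in labels_cycle if capacity[lab] > 0]
        lab = choices[int(rng.integers(len(choices)))]
        plan[lab].append(j)
        capacity[lab] -= 1
    for label in labels_cycle:
        while capacity[label] > 0:
            available = [
                j for j in range(n_irrelevant) if j not in set(plan[label])
            ]
            picks = rng.choice(len(available), size=capacity[label], replace=False)
            plan[label].extend(available[int(p)] for p in picks)
            capacity[label] = 0

    spec = SyntheticSpec(
        n_eligible=n,
        databases=tuple(
            DatabaseProfile(label, cov / n, irrelevant_counts[label])
            for label, cov, _ in STUDY_DATABASES
        ),
        duplicate_noise=0.1,
        doi_missing_rate=0.1,
        seed=seed,
    )
    constraints = IndexingConstraints(
        eligible_sets=eligible_sets,
        irrelevant_plan={lab: tuple(sorted(v)) for lab, v in plan.items()},
        n_irrelevant=n_irrelevant,
    )
    return spec, constraints


def generate_study(
    seed: int = 0,
) -> tuple[PooledCorpus, GroundTruth, list[ScreeningLabel]]:
    """Convenience wrapper: materialize the study-marginals preset."""
    spec, constraints = study_preset(seed)
    return generate(spec, constraints)


def flow_preset(
    seed: int = 0,
    pooled: int = 848,
    duplicates: int = 547,
    ineligible: int = 225,
    eligible: int = 76,
) -> tuple[PooledCorpus, GroundTruth, list[ScreeningLabel]]:
    """A corpus planting the published screening flow exactly.

    ``pooled`` records collapse to ``pooled − duplicates`` unique
    publications, of which ``eligible`` are randomized trials; database
    yields are whatever the seeded copy assignment produces. Requires
    pooled = duplicates + ineligible + eligible.
    """
    n_unique = ineligible + eligible
    if pooled != duplicates + n_unique:
        raise ValueError("require pooled = duplicates + ineligible + eligible")
    rng = np.random.default_rng(seed)
    db_labels = [label for label, _, _ in STUDY_DATABASES]
    n_db = len(db_labels)

    # One home copy per publication, then extra duplicate copies spread over
    # (publication, database) pairs not already used.
    sets: list[set[int]] = [
        {int(rng.integers(n_db))} for _ in range(n_unique)
    ]
    pair_pool = [
        (i, d) for i in range(n_unique) for d in range(n_db) if d not in sets[i]
    ]
    picks = rng.choice(len(pair_pool), size=duplicates, replace=False)
    for p in picks:
        i, d = pair_pool[int(p)]
        sets[i].add(d)

    eligible_idx = set(int(i) for i in rng.choice(n_unique, size=eligible, replace=False))
    eligible_dbs = [
        tuple(db_labels[d] for d in sorted(sets[i]))
        for i in range(n_unique)
        if i in eligible_idx
    ]
    irrelevant_dbs = [
        tuple(db_labels[d] for d in sorted(sets[i]))
        for i in range(n_unique)
        if i not in eligible_idx
    ]
    pubs = _make_publications(rng, eligible, ineligible, eligible_dbs, irrelevant_dbs)
    return _emit(pubs, db_labels, 0.1, 0.1, rng)
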