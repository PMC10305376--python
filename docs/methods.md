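# Methods

## Scope and data model

`refcover` analyses a completed multi-database literature search. Its unit
of observation is the bibliographic **record** (one export line from one
database); records collapse to unique **publications** via deduplication;
publications carry a binary eligibility decision from human **screening**;
and each database (or database set) is then scored as a retrieval test
against the eligible reference set. The package manages decisions, it does
not make them: there is no automated trial classification.

## Deduplication

Duplicate detection is a declared convention, not a reconstruction of any
reference manager's behaviour. Two records are linked when

(a) they share a non-absent DOI;
(b) they share the dedup key (normalized title, year, first-author family
    name); or
(c) their normalized titles have edit-distance similarity ≥ the fuzzy
    threshold **and** they share a year — unless both carry DOIs that
    differ, in which case the fuzzy link is vetoed (a DOI conflict is
    treated as stronger evidence than a similar title).

Clusters are transitive closures of these links (union-find); the
canonical member is the lexicographically smallest record id, which makes
cluster identity stable and labelable by humans. Title normalization
lower-cases, folds diacritics to ASCII, removes all characters outside
letters/digits/space and collapses whitespace; it is idempotent.
Similarity is 1 − Levenshtein/max-length (computed with edlib), compared
only within equal-year blocks, which bounds the pairwise work and encodes
the judgement that same-title publications in different years are usually
distinct reports. Records with neither a usable title nor a DOI stay
singletons: there is no evidence to merge them.

**Default fuzzy threshold 0.90.** High enough that distinct trials with
similar template titles ("X versus Y for Z") do not merge, low enough to
absorb OCR/punctuation variants; lowering the threshold can only coarsen
the clustering (tested as a monotonicity property).

## Screening and the flow ledger

Labels attach to clusters (eligibility is a property of the publication,
not of one database's copy) and may reference the canonical record id.
Validation is strict: every cluster needs exactly one label, and the
offending cluster ids are listed otherwise. The flow ledger enforces
`pooled = duplicates + ineligible + eligible` as a constructor invariant,
so a bookkeeping error anywhere upstream fails loudly.

## Contingency convention and estimates

TP and FN count unique eligible publications; FP and TN count raw pooled
records (FP = yield − TP, TN = pooled − yield). The 2×2 total therefore
differs across databases (pooled + eligible − TP). This asymmetry is the
convention retrieval-coverage studies print, and it is preserved rather
than "fixed"; all downstream estimates are defined on it.

Confidence intervals are Clopper–Pearson exact binomial bounds from beta
quantiles (scipy), chosen because they behave correctly for the degenerate
rows these studies always contain: a zero-coverage database gets
0% (0–5%) at n = 76, where a Wald interval would collapse to width zero.
The k = 0 upper bound has the closed form 1 − (α/2)^(1/n), used as an
independent check; the general bounds are validated in the tests against
inversion of the binomial tail probabilities, a route independent of the
beta-quantile identity. The accuracy interval treats TP+TN of the table
total as one binomial count; this is a package convention (flagged in
reports), since accuracy is a derived mixture rather than a simple
proportion. Display rounding is half-up to integer percent; internal
values are kept at full precision.

## Combinations

A database set is scored under the **pooled screening-load universe**:
FP/TN generalize the single-database convention with summed
duplicate-inclusive yields. This keeps union diagnostics consistent with
the single-database tables and reflects the workload a reviewer actually
faces; an alternative `dedup_universe` mode counts FP over unique union
records instead. Published pairwise tables of this kind cannot generally
be reproduced without the per-record overlap data, so the engine is
validated against brute-force recounts on synthetic corpora rather than
against printed cells.

`minimal_cover` enumerates all subsets up to `max_size` (default 3 —
pairs are the practically interesting case, triples a cheap
generalization) whenever there are ≤ 15 databases, guaranteeing the
optimum; wider corpora fall back to a greedy marginal-coverage heuristic
whose results are flagged as such. Ties break deterministically by
(subset size, screening load, label tuple). Because every eligible
cluster contains at least one record, the union of *all* databases always
reaches sensitivity 1.0; the unreachable-target branch exists for
defensive completeness.

## Synthetic corpora

The generator plants unique publications (eligible and irrelevant) across
databases and emits each copy as a record, so every planted fact is known
ground truth. Eligible publication *i* is indexed by database *d* with
probability `coverage_p(d)` independently; each database adds its count
of irrelevant records (unique to it by default; an overlap parameter
shares them). Duplicate copies receive title perturbations — case flips,
punctuation insertion, doubled spaces — at rate `duplicate_noise`
(default 0.1), and lose their DOI at `doi_missing_rate` (default 0.1).
These perturbations are exactly the ones title normalization must absorb;
genuinely noisy variants (OCR substitutions, British/American spelling)
are exercised with hand-made fixtures in the unit tests. Titles are drawn
from a domain word pool with a separation guarantee: no two distinct
publications share a year with normalized-title similarity ≥ 0.88, so
default-threshold deduplication recovers the planted clustering exactly
for every seed — by construction, not by luck. Same spec and seed give
byte-identical output.

Two constrained presets reconstruct the marginal structure of a published
12-database coverage study of randomized trials for central serous
chorioretinopathy:

- **study preset** — plants the published per-database eligible-coverage
  counts (32, 12, 66, 44, 0, 0, 67, 4, 28, 57, 0, 51 of 76 eligible) and
  total yields (80, 26, 141, 97, 0, 0, 184, 4, 102, 138, 2, 126), with
  the Cochrane Central and PubMed eligible sets drawn from a seeded
  permutation with overlap exactly 47 so their union covers all 76 (the
  study pins the union at 100% but not the overlap), and 225 unique
  irrelevant publications supplying the remaining yield, each guaranteed
  at least one copy. The published yields sum to 900 while the study's
  own pooled total is printed as 848; a corpus matching the yield column
  necessarily pools 900 records, so the preset's TN column is 900 − yield
  where the published tables print 848 − yield. The package always
  reports recomputed sums; the counts-input path (`refcover.study`)
  carries both printed figures for exact reproduction of the published
  tables.
- **flow preset** — plants the published screening flow exactly:
  848 pooled = 547 duplicates + 225 ineligible + 76 eligible, with the
  547 extra copies spread over publication × database pairs.

All preset outputs are reconstructions: they satisfy the printed marginals
but invent the unprinted overlap structure. Passing tests on them show the
pipeline arithmetic is right under those marginals; they cannot show
anything about real exports' messiness (field variants, encoding damage,
within-database duplicates of different years), which the format parsers
and dedup unit tests cover only partially.

## Problem sizes and tolerances

Monte-Carlo checks use 500 replicates for single-database coverage
recovery (binomial mean within 3 standard errors), 300 replicates for the
two-database pipeline recovery (3.5 SE, allowing for the multiplicity of
two simultaneous checks), 2,000 draws for the interval-coverage property
(≥ 93% observed coverage at nominal 95%), and 20 seeds for planted-
duplicate recovery (≥ 99% of planted pairs re-clustered; in practice
recovery is exact by the separation guarantee). Brute-force oracle
comparisons (all-pairs union-find; subset enumeration) run on corpora of
≤ 200 records and ≤ 6–12 databases, where the oracle is unambiguous and
fast.

## Known limitations

- Eligibility and deduplication of real exports depend on fields this
  model treats as clean; MEDLINE/RIS dialects in the wild vary more than
  the parsers' test fixtures.
- The accuracy CI convention (binomial on TP+TN) is pragmatic, not
  derived; accuracy itself is dominated by the large TN cell and is a
  poor ranking criterion for low-sensitivity databases.
- One published accuracy cell (CINAHL) recomputes to 91% against a
  printed 92%; the recomputed value is reported and the discrepancy
  documented rather than matched.
- Coverage snapshots date quickly: nothing here models indexing lag or
  language-specific coverage.
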