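# refcover

Database-coverage diagnostics for systematic-review literature searches.

## The problem

A systematic review is only as good as its literature search, and no single
bibliographic database indexes every eligible study. Searching many
databases raises coverage but multiplies the screening workload, because
each extra database contributes mostly duplicates and irrelevant records.
`refcover` quantifies this trade-off for a completed multi-database search:
given the per-database record exports and the eligibility decisions, it
scores each database — and each database *combination* — as a diagnostic
test against the reference set of eligible studies found anywhere, and
searches for the smallest combination that still reaches a target coverage.

It is aimed at information specialists and review methodologists doing
retrieval-coverage ("relative recall") studies, of the kind that ask: *which
two of these twelve databases would have been enough?*

## The model

Pool the exports of all databases (``N`` raw records), collapse duplicates
into unique publications, and screen the unique records, yielding ``E``
eligible studies. Each database *d*, with duplicate-inclusive yield
``n_d``, gets a 2×2 contingency table:

| | relevant | irrelevant |
|---|---|---|
| retrieved by *d* | TP_d (eligible studies in *d*) | FP_d = n_d − TP_d |
| not retrieved | FN_d = E − TP_d | TN_d = N − n_d |

Note the convention (standard in coverage studies): TP/FN count unique
publications, FP/TN count raw pooled records. From the table,

- **sensitivity** (= coverage) Se = TP/(TP+FN),
- **specificity** Sp = TN/(TN+FP),
- **accuracy** Ac = Se·prev + Sp·(1−prev) with prev = (TP+FN)/total,
  algebraically (TP+TN)/total.

Every proportion gets an exact **Clopper–Pearson** 95% interval from beta
quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k).

A set *S* of databases is treated as one source that retrieves a record if
any member indexes it; its screening load is Σ_{d∈S} n_d (duplicates
included — that is what a reviewer actually screens). `minimal_cover`
enumerates all subsets up to a size cap and returns the combinations
reaching a target sensitivity, ordered by size, then load.

## Worked example

Score the 12 databases of a coverage study of randomized trials for
central serous chorioretinopathy from their published marginal counts:

```python
from refcover import DatabaseCoverage, study

model = DatabaseCoverage.from_counts(
    study.study_counts(), study.N_ELIGIBLE, study.POOLED_TOTAL
)
print(model.fit().summary())
```

```
Database retrieval-coverage diagnostics
==============================================================================
database                           TP   FP   FN    TN        Se        Sp        Ac
BIOSIS Previews                    32   48   44   768       42%       94%       90%
CINAHL                             12   14   64   822       16%       98%       91%
Cochrane Central                   66   75   10   707       87%       90%       90%
Current Contents Connect           44   53   32   751       58%       93%       90%
Data Citation Index                 0    0   76   848        0%      100%       92%
Derwent Innovations Index           0    0   76   848        0%      100%       92%
EMBASE                             67  117    9   664       88%       85%       85%
KCI-Korean Journal Database         4    0   72   844        5%      100%       92%
MEDLINE                            28   74   48   746       37%       91%       86%
PubMed                             57   81   19   710       75%       90%       88%
SciELO Citation Index               0    2   76   846        0%      100%       92%
Web of Science Core Collection     51   75   25   722       67%       91%       89%
==============================================================================
95% intervals are exact (Clopper-Pearson); accuracy interval treats TP+TN as one
binomial count.
```

Reading the table: EMBASE covers 67 of the 76 eligible trials (Se 88%,
the best single database) but at the price of 117 irrelevant records in
its yield (Sp 85%); the trial-specialized Cochrane Central is nearly as
sensitive (87%) with a much cleaner yield. No single database reaches
full coverage.

With per-record data (here, a seeded synthetic reconstruction of the same
study) the combination engine answers the follow-up question:

```python
from refcover import DatabaseCoverage, synthetic

corpus, truth, labels = synthetic.generate_study(seed=1)
res = DatabaseCoverage.from_corpus(corpus, labels).fit()
best = res.minimal_cover(target_se=1.0, max_size=2)[0]
print(best.databases, best.se.point, best.screening_load)
# ('Cochrane Central', 'PubMed') 1.0 279
```

Searching just Cochrane Central + PubMed covers all 76 trials while
cutting the screening load from the pooled total to 279 records.

There is also a CLI (`refcover ingest / dedup / screen / diagnose /
combos / simulate / run`) for running the pipeline from RIS, MEDLINE or
CSV exports; `refcover run config.yaml` executes every stage and writes
CSV + Markdown reports with a stage-by-stage run log.

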