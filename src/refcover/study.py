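"""Published marginal counts of the motivating coverage study.

A cross-sectional study of database indexing searched 12 literature
databases for randomized clinical trials on central serous
chorioretinopathy and reported, per database, the total search yield and
the number of the 76 eligible trials it covered, alongside the screening
flow (848 pooled records = 547 duplicates + 225 ineligible + 76 eligible).
These printed counts are inputs: together with the contingency convention
in :mod:`refcover.diagnostics` they determine every per-database 2x2 table
(TN is taken against the reported pooled total of 848).

Note the reported per-database yields sum to 900, not to the reported
pooled total of 848; the discrepancy is unexplained in the source and both
figures are kept as reported.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "study_counts",
    "N_ELIGIBLE",
    "POOLED_TOTAL",
    "FLOW",
]

N_ELIGIBLE = 76
#: Reported pooled screening total (used for TN in the reported tables).
POOLED_TOTAL = 848
#: Reported screening flow: (pooled, duplicates, ineligible, eligible).
FLOW = (848, 547, 225, 76)

_ROWS = [
    # database, eligible trials covered (of 76), total yield
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
]


def study_counts() -> pd.DataFrame:
    """Per-database reported marginals: columns ``database, tp, yield``."""
    return pd.DataFrame(_ROWS, columns=["database", "tp", "yield"])
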