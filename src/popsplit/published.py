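"""Published summary tables from an exome study of house mice
(Mus musculus domesticus) sampled in Western Europe and along the eastern
US seaboard.

These small printed tables are bundled as reference inputs for the
report-aggregation helpers: pairwise Weir-Cockerham F_st between the two
European and five eastern North American population samples, and
per-population diversity summaries (Watterson's theta, nucleotide
diversity, Tajima's D, all from folded exome spectra).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

POPULATIONS = [
    "France",
    "Germany",
    "New Hampshire/Vermont",
    "Pennsylvania",
    "Virginia",
    "Georgia",
    "Florida",
]

EUROPE = ["France", "Germany"]
NORTH_AMERICA = [
    "New Hampshire/Vermont",
    "Pennsylvania",
    "Virginia",
    "Georgia",
    "Florida",
]

# lower-triangle pairwise F_st (weighted Weir-Cockerham), row vs column
_FST_PAIRS = {
    ("Germany", "France"): 0.168,
    ("New Hampshire/Vermont", "France"): 0.281,
    ("New Hampshire/Vermont", "Germany"): 0.202,
    ("Pennsylvania", "France"): 0.215,
    ("Pennsylvania", "Germany"): 0.143,
    ("Pennsylvania", "New Hampshire/Vermont"): 0.124,
    ("Virginia", "France"): 0.222,
    ("Virginia", "Germany"): 0.146,
    ("Virginia", "New Hampshire/Vermont"): 0.135,
    ("Virginia", "Pennsylvania"): 0.087,
    ("Georgia", "France"): 0.237,
    ("Georgia", "Germany"): 0.170,
    ("Georgia", "New Hampshire/Vermont"): 0.159,
    ("Georgia", "Pennsylvania"): 0.106,
    ("Georgia", "Virginia"): 0.056,
    ("Florida", "France"): 0.161,
    ("Florida", "Germany"): 0.101,
    ("Florida", "New Hampshire/Vermont"): 0.096,
    ("Florida", "Pennsylvania"): 0.041,
    ("Florida", "Virginia"): 0.054,
    ("Florida", "Georgia"): 0.063,
}


def pairwise_fst_table() -> pd.DataFrame:
    """Symmetric F_st matrix (NaN diagonal) over the seven populations."""
    mat = pd.DataFrame(np.nan, index=POPULATIONS, columns=POPULATIONS)
    for (a, b), v in _FST_PAIRS.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def diversity_table() -> pd.DataFrame:
    """Per-population theta_W (%), pi (%), and Tajima's D."""
    rows = [
        ("France", 0.269, 0.289, 0.438),
        ("Germany", 0.252, 0.271, 0.440),
        ("New Hampshire/Vermont", 0.121, 0.140, 0.754),
        ("Pennsylvania", 0.149, 0.169, 0.649),
        ("Virginia", 0.155, 0.170, 0.472),
        ("Georgia", 0.133, 0.151, 0.641),
        ("Florida", 0.188, 0.205, 0.453),
    ]
    return pd.DataFrame(
        rows, columns=["population", "theta_w_pct", "pi_pct", "tajima_d"]
    ).set_index("population")


# the eight panels entering the admixture f3 scan (the seven house-mouse
# population samples plus an M. spretus outgroup panel)
F3_PANELS = POPULATIONS + ["M. spretus"]
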