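"""Reference tables from the GSE68086 tumor-educated-platelet cohort.

These are published summary numbers, not expression data: the per-class
sample breakdown of the 285-sample cohort, and the top of the MaxRel
feature list (gene, mutual information with the class target, and rank in
the mRMR list) reported for that cohort.  They serve as worked-example
inputs for the biomarker-extraction operations and as the default class
sizes of the synthetic generator.
"""

from __future__ import annotations

import pandas as pd

#: Per-class sample counts of the GSE68086 cohort (285 samples total).
GSE68086_CLASS_SIZES: dict[str, int] = {
    "breast": 39,
    "colorectal": 42,
    "glioblastoma": 40,
    "hepatobiliary": 14,
    "lung": 60,
    "pancreatic": 35,
    "healthy": 55,
}

_TOP_MAXREL_ROWS = [
    # (maxrel order, Ensembl gene ID, symbol, MI bits-scale value, mRMR rank)
    (1, "ENSG00000155657", "TTN", 0.416, 1),
    (2, "ENSG00000008988", "RPS20", 0.407, 13),
    (3, "ENSG00000177600", "RPLP2", 0.405, 6),
    (4, "ENSG00000211772", "TRBC2", 0.396, 19),
    (5, "ENSG00000168028", "RPSA", 0.393, 35),
    (6, "ENSG00000142534", "RPS11", 0.384, 64),
    (7, "ENSG00000142676", "RPL11", 0.381, 48),
    (8, "ENSG00000105193", "RPS16", 0.380, 57),
    (9, "ENSG00000160654", "CD3G", 0.379, 25),
    (10, "ENSG00000168421", "RHOH", 0.373, 3),
    (11, "ENSG00000139193", "CD27", 0.369, 8),
    (12, "ENSG00000131469", "RPL27", 0.368, 106),
    (13, "ENSG00000163682", "RPL9", 0.368, 86),
    (14, "ENSG00000071082", "RPL31", 0.367, 78),
    (15, "ENSG00000149311", "ATM", 0.367, 17),
    (16, "ENSG00000149806", "FAU", 0.366, 31),
    (17, "ENSG00000109475", "RPL34", 0.366, 122),
    (18, "ENSG00000089009", "RPL6", 0.366, 117),
]


def gse68086_class_sizes() -> dict[str, int]:
    """Ordered class -> sample-count map of the published cohort."""
    return dict(GSE68086_CLASS_SIZES)


def gse68086_top_maxrel() -> pd.DataFrame:
    """Top of the published MaxRel list as a DataFrame.

    Columns: ``order`` (1-based MaxRel position), ``gene_id``, ``symbol``,
    ``mi`` (mutual information with the 7-class target), ``mrmr_rank``
    (1-based position in the published mRMR list).
    """
    return pd.DataFrame(
        _TOP_MAXREL_ROWS,
        columns=["order", "gene_id", "symbol", "mi", "mrmr_rank"],
    )
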