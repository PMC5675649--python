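"""MI-threshold biomarker extraction and the clustering report.

A biomarker set is the prefix of the MaxRel list whose MI with the class
target strictly exceeds a threshold; cross-referencing attaches each
biomarker's rank in the mRMR list, which shows whether the whole set falls
inside a given optimal feature subset.  The report step hierarchically
clusters the biomarker submatrix (samples and genes) and cuts the gene
dendrogram into groups, the standard expression-heatmap view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .mrmr import RankedFeatureList


@dataclass(frozen=True)
class BiomarkerSet:
    """Genes passing the MI threshold, with MaxRel order and mRMR rank."""

    entries: pd.DataFrame  # columns: gene, mi, maxrel_order, mrmr_rank (NaN until joined)
    mi_threshold: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return self.entries["gene"].tolist()

    @property
    def max_mrmr_rank(self) -> int:
        ranks = self.entries["mrmr_rank"]
        if len(ranks) == 0 or ranks.isna().any():
            raise ValueError("mRMR ranks not available; run cross_reference_ranks first")
        return int(ranks.max())

    def contained_in_subset(self, subset_size: int) -> bool:
        """True if every biomarker's mRMR rank is within ``subset_size``."""
        return self.max_mrmr_rank <= subset_size

    def to_table(self) -> pd.DataFrame:
        return self.entries.copy()


def extract_important(maxrel: RankedFeatureList, mi_threshold: float = 0.360) -> BiomarkerSet:
    """Prefix of the MaxRel list with MI strictly greater than the threshold."""
    if maxrel.kind != "maxrel":
        raise ValueError("extract_important expects a MaxRel list")
    scores = maxrel.scores
    n = int(np.sum(scores > mi_threshold))
    entries = pd.DataFrame(
        {
            "gene": maxrel.features[:n],
            "mi": scores[:n],
            "maxrel_order": np.arange(1, n + 1),
            "mrmr_rank": np.full(n, np.nan),
        }
    )
    return BiomarkerSet(entries, mi_threshold)


def cross_reference_ranks(
    b: BiomarkerSet, mrmr: RankedFeatureList | Mapping[str, int]
) -> BiomarkerSet:
    """Attach each biomarker's 1-based mRMR rank (a pure join, order kept).

    ``mrmr`` is either the mRMR RankedFeatureList or a plain gene -> rank
    mapping (e.g. published ranks).  Raises ``KeyError`` for a biomarker
    absent from it.
    """
    ranks = mrmr.rank_of() if isinstance(mrmr, RankedFeatureList) else dict(mrmr)
    missing = [g for g in b.genes if g not in ranks]
    if missing:
        raise KeyError(f"biomarkers absent from mRMR ranks: {missing[:5]}")
    entries = b.entries.copy()
    entries["mrmr_rank"] = [ranks[g] for g in b.genes]
    return BiomarkerSet(entries, b.mi_threshold)


@dataclass(frozen=True)
class ClusterReport:
    """Dendrogram orders and group assignments of the biomarker submatrix."""

    gene_order: list[str]
    sample_order: list[str]
    gene_groups: pd.Series  # gene -> group label 1..n_gene_groups
    labels: pd.Series


def _linkage(X: np.ndarray):
    # correlation distance; rows constant across columns get distance 1 to
    # everything rather than NaN
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = pdist(X, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    return hierarchy.linkage(dist, method="average")


def cluster_heatmap(
    m: pd.DataFrame,
    b: BiomarkerSet,
    labels: pd.Series,
    n_gene_groups: int = 3,
    out_png=None,
) -> ClusterReport:
    """Hierarchically cluster samples and biomarker genes; cut genes into groups.

    Average-linkage agglomerative clustering on correlation distance, the
    usual choice for expression heatmaps.  If ``out_png`` is given, a
    heatmap with both dendrogram orders applied is written there.
    """
    genes = [g for g in b.genes if g in m.index]
    if len(genes) < len(b.genes):
        raise KeyError("biomarker genes missing from the matrix")
    if n_gene_groups > len(genes):
        raise ValueError(f"n_gene_groups={n_gene_groups} exceeds {len(genes)} genes")
    sub = m.loc[genes]

    gene_link = _linkage(sub.to_numpy())
    sample_link = _linkage(sub.to_numpy().T)
    gene_order = [genes[i] for i in hierarchy.leaves_list(gene_link)]
    sample_order = [sub.columns[i] for i in hierarchy.leaves_list(sample_link)]
    groups = hierarchy.fcluster(gene_link, t=n_gene_groups, criterion="maxclust")
    gene_groups = pd.Series(groups, index=genes, name="group")

    if out_png is not None:
        _draw_heatmap(sub.loc[gene_order, sample_order], labels, out_png)
    return ClusterReport(gene_order, sample_order, gene_groups, labels.loc[sub.columns])


def _draw_heatmap(ordered: pd.DataFrame, labels: pd.Series, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # z-score rows for display only
    vals = ordered.to_numpy(dtype=float)
    sd = vals.std(axis=1, keepdims=True)
    z = (vals - vals.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)

    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(ordered))))
    im = ax.imshow(z, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel(f"{ordered.shape[1]} samples ({labels.nunique()} classes)")
    fig.colorbar(im, ax=ax, shrink=0.6, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
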