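"""Two-stage incremental feature selection over the mRMR list.

Incremental feature selection (IFS) evaluates nested prefixes F_i of a
ranked feature list with the cross-validated SVM and picks the prefix size
maximizing overall accuracy.  Scanning every size is expensive at ~10^4
features, so the scan is staged: stage 1 walks a coarse grid (every
``step``-th size), a band of near-maximal sizes is read off the stage-1
curve, and stage 2 scans that band exhaustively.  One fold partition is
shared by every evaluation in a run, so the curve compares feature subsets
rather than fold luck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    ConfusionMatrix,
    FoldPartition,
    cross_validate,
    overall_accuracy,
    per_class_metrics,
)
from .mrmr import RankedFeatureList, discretize, mrmr_list

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IFSPoint:
    size: int
    tacc: float
    per_class: pd.DataFrame  # ACC/SN/SP indexed by class


@dataclass(frozen=True)
class IFSCurve:
    """TACC (and per-class metrics) as a function of feature-subset size."""

    points: list[IFSPoint]
    stage: int

    def __post_init__(self):
        sizes = [p.size for p in self.points]
        if sizes != sorted(set(sizes)):
            raise ValueError("subset sizes must be strictly increasing")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.points])

    @property
    def taccs(self) -> np.ndarray:
        return np.array([p.tacc for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row: dict = {"n_features": p.size, "TACC": p.tacc}
            for cls, metrics in p.per_class.iterrows():
                row[f"ACC:{cls}"] = metrics["ACC"]
                row[f"SP:{cls}"] = metrics["SP"]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OptimalModelReport:
    """The best prefix of the mRMR list and its cross-validated performance."""

    optimal_size: int
    optimal_features: list[str] = field(repr=False)
    confusion: ConfusionMatrix
    tacc: float
    per_class: pd.DataFrame

    def __post_init__(self):
        if self.optimal_size != len(self.optimal_features):
            raise ValueError("optimal_size must equal len(optimal_features)")


def _evaluate_sizes(m, labels, mrmr: RankedFeatureList, sizes, partition, stage) -> IFSCurve:
    points = []
    for size in sizes:
        cm = cross_validate(m, labels, mrmr.top(size), partition)
        point = IFSPoint(int(size), overall_accuracy(cm), per_class_metrics(cm))
        points.append(point)
        logger.info("stage %d: %d features -> TACC %.3f", stage, size, point.tacc)
    return IFSCurve(points, stage)


def ifs_stage1(
    m: pd.DataFrame,
    labels: pd.Series,
    mrmr: RankedFeatureList,
    partition: FoldPartition,
    step: int = 10,
    max_size: int | None = None,
) -> IFSCurve:
    """Coarse scan: evaluate prefix sizes step, 2*step, ... up to the list length.

    ``max_size`` optionally caps the grid (the near-optimal band is normally
    far below the full feature count).
    """
    n = len(mrmr) if max_size is None else min(max_size, len(mrmr))
    if step < 1 or step > n:
        raise ValueError(f"need 1 <= step <= {n}, got {step}")
    sizes = np.arange(step, n + 1, step)
    return _evaluate_sizes(m, labels, mrmr, sizes, partition, stage=1)


def select_range(
    curve: IFSCurve, delta: float = 0.01, pad: int = 1, n_features: int | None = None
) -> tuple[int, int]:
    """Band of sizes whose TACC is within ``delta`` of the curve maximum.

    The smallest and largest qualifying tested sizes are widened by ``pad``
    grid steps and clipped to [1, n_features] (default: the largest tested
    size).  Deterministic given the curve.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    sizes, taccs = curve.sizes, curve.taccs
    grid = int(sizes[1] - sizes[0]) if len(sizes) > 1 else 1
    good = sizes[taccs >= taccs.max() - delta]
    upper = int(sizes.max()) if n_features is None else n_features
    lo = max(1, int(good.min()) - pad * grid)
    hi = min(upper, int(good.max()) + pad * grid)
    return lo, hi


def ifs_stage2(
    m: pd.DataFrame,
    labels: pd.Series,
    mrmr: RankedFeatureList,
    lo: int,
    hi: int,
    partition: FoldPartition,
) -> IFSCurve:
    """Exhaustive scan of every prefix size in [lo, hi]."""
    if not 1 <= lo <= hi <= len(mrmr):
        raise ValueError(f"need 1 <= lo <= hi <= {len(mrmr)}, got [{lo}, {hi}]")
    return _evaluate_sizes(m, labels, mrmr, np.arange(lo, hi + 1), partition, stage=2)


def optimal_model(
    stage2: IFSCurve,
    mrmr: RankedFeatureList,
    m: pd.DataFrame,
    labels: pd.Series,
    partition: FoldPartition,
) -> OptimalModelReport:
    """Smallest size achieving the curve's maximum TACC, re-evaluated in full."""
    if not stage2.points:
        raise ValueError("empty IFS curve")
    taccs = stage2.taccs
    best_size = int(stage2.sizes[np.flatnonzero(taccs == taccs.max())[0]])
    features = mrmr.top(best_size)
    cm = cross_validate(m, labels, features, partition)
    return OptimalModelReport(
        best_size, features, cm, overall_accuracy(cm), per_class_metrics(cm)
    )


def run_ifs(
    m: pd.DataFrame,
    labels: pd.Series,
    mrmr: RankedFeatureList,
    partition: FoldPartition,
    step: int = 10,
    delta: float = 0.01,
    pad: int = 1,
    max_size: int | None = None,
) -> tuple[IFSCurve, IFSCurve, OptimalModelReport]:
    """Stage 1 -> band selection -> stage 2 -> optimal model, in one call."""
    step = min(step, len(mrmr))
    stage1 = ifs_stage1(m, labels, mrmr, partition, step=step, max_size=max_size)
    lo, hi = select_range(stage1, delta=delta, pad=pad, n_features=len(mrmr))
    stage2 = ifs_stage2(m, labels, mrmr, lo, hi, partition)
    return stage1, stage2, optimal_model(stage2, mrmr, m, labels, partition)


def panel_evaluation(
    m: pd.DataFrame,
    labels: pd.Series,
    panel_genes,
    partition: FoldPartition,
    step: int = 10,
    delta: float = 0.01,
    pad: int = 1,
    n_bins: int = 3,
    k_sigma: float = 1.0,
    max_size: int | None = None,
) -> OptimalModelReport:
    """Re-run the full ranking + IFS protocol restricted to a gene panel.

    The matrix is cut to the intersection of the panel with its genes (order
    preserved); the mRMR list, both IFS stages, and the optimal model are
    recomputed on that restricted set, mirroring how external gene panels
    are benchmarked against the unrestricted model.
    """
    panel = set(panel_genes)
    keep = m.index[m.index.isin(panel)]
    if len(keep) == 0:
        raise ValueError("panel has no genes in common with the matrix")
    logger.info("panel evaluation: %d of %d panel genes present", len(keep), len(panel))
    sub = m.loc[keep]
    d = discretize(sub, n_bins=n_bins, k_sigma=k_sigma)
    ranked = mrmr_list(d, labels, n_select=max_size)
    _, _, report = run_ifs(
        sub, labels, ranked, partition, step=step, delta=delta, pad=pad, max_size=max_size
    )
    return report


def plot_ifs_curve(curve: IFSCurve, path, title: str = "IFS curve") -> None:
    """Save a subset-size vs TACC curve as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.sizes, curve.taccs, marker="o", ms=3)
    ax.set_xlabel("number of features")
    ax.set_ylabel("TACC")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
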