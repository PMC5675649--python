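"""Discretization, plug-in mutual information, and mRMR feature ranking.

Expression values are discretized per gene into three states around the
gene's mean (below -k*sigma, within, above +k*sigma).  Mutual information
is the discrete plug-in estimate from the empirical joint frequency table,
in bits, with 0*log(0) = 0.

Two rankings are produced from the discretized matrix:

* the **MaxRel list** — features sorted by I(f, c) with the class target,
  descending; and
* the **mRMR list** — the greedy minimum-redundancy maximum-relevance
  order: starting from an empty selected set, repeatedly move the feature
  maximizing D - R from the candidate pool to the selected set, where
  D = I(f, c) and R is the mean pairwise MI between f and the already
  selected features (R = 0 at the first step, so both lists share their
  first element).  Ties break by input gene order, so runs are
  reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscreteMatrix:
    """Integer-state version of an expression matrix (genes x samples)."""

    states: pd.DataFrame  # int states, same index/columns as the source

    @property
    def gene_ids(self) -> pd.Index:
        return self.states.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.states.columns


@dataclass(frozen=True)
class RankedFeatureList:
    """Ordered (feature, score) pairs from one ranking criterion.

    For ``kind="maxrel"`` the score is I(f, c); for ``kind="mrmr"`` it is
    the D - R value at the iteration where the feature was selected.
    """

    entries: pd.DataFrame  # columns: feature, score
    kind: Literal["maxrel", "mrmr"]

    def __post_init__(self):
        if list(self.entries.columns) != ["feature", "score"]:
            raise ValueError("entries must have columns [feature, score]")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def features(self) -> list[str]:
        return self.entries["feature"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.entries["score"].to_numpy()

    def top(self, n: int) -> list[str]:
        return self.features[:n]

    def rank_of(self) -> dict[str, int]:
        """Map feature -> 1-based rank."""
        return {f: i + 1 for i, f in enumerate(self.features)}

    def to_table(self) -> pd.DataFrame:
        out = self.entries.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        return out


def discretize(m: pd.DataFrame, n_bins: int = 3, k_sigma: float = 1.0) -> DiscreteMatrix:
    """Per-gene discretization of an expression matrix.

    Default (``n_bins=3``): z-score each gene and assign state 0 below
    ``-k_sigma``, state 2 above ``+k_sigma``, state 1 otherwise; constant
    genes map entirely to state 1.  Any other ``n_bins`` falls back to
    per-gene equal-frequency binning (a notice is logged).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if m.shape[1] < 2:
        raise ValueError("discretization needs at least 2 samples")
    values = m.to_numpy(dtype=float)
    if n_bins == 3:
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        safe_sd = np.where(sd > 0, sd, 1.0)
        z = (values - mean) / safe_sd
        states = np.ones_like(values, dtype=np.int64)
        states[z < -k_sigma] = 0
        states[z > k_sigma] = 2
        states[np.broadcast_to(sd == 0, states.shape)] = 1
    else:
        logger.info("n_bins=%d: using equal-frequency binning instead of the sigma scheme", n_bins)
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1], axis=1).T
        states = np.zeros_like(values, dtype=np.int64)
        for b in range(n_bins - 1):
            states += values > qs[:, [b]]
    return DiscreteMatrix(pd.DataFrame(states, index=m.index, columns=m.columns))


def _as_codes(v) -> np.ndarray:
    v = np.asarray(v)
    _, codes = np.unique(v, return_inverse=True)
    return codes


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information between two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError(f"need equal-length 1-D vectors, got {x.shape} and {y.shape}")
    xc, yc = _as_codes(x), _as_codes(y)
    counts = _joint_counts(xc[None, :], xc.max() + 1, yc, yc.max() + 1)[0]
    return float(_mi_from_counts(counts[None, ...])[0])


def entropy(x: Sequence) -> float:
    """Plug-in Shannon entropy of a discrete vector, in bits."""
    _, counts = np.unique(np.asarray(x), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_counts(states: np.ndarray, ns: int, y: np.ndarray, ny: int) -> np.ndarray:
    """Joint count tables between every row of ``states`` and vector ``y``.

    Returns an array of shape (n_rows, ns, ny); the matmul formulation keeps
    the mRMR loop's per-iteration cost at a few small BLAS calls.
    """
    onehot = np.eye(ny, dtype=float)[y]  # samples x ny
    return np.stack([(states == a).astype(float) @ onehot for a in range(ns)], axis=1)


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI in bits from a batch of joint count tables (batch, ns, ny)."""
    n = counts.sum(axis=(1, 2), keepdims=True)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    mi = np.nansum(terms, axis=(1, 2))
    return np.maximum(mi, 0.0)


def _encode_labels(labels: pd.Series, sample_ids: pd.Index) -> np.ndarray:
    return _as_codes(labels.loc[sample_ids].to_numpy())


def _target_mi(d: DiscreteMatrix, labels: pd.Series) -> np.ndarray:
    states = d.states.to_numpy()
    y = _encode_labels(labels, d.sample_ids)
    counts = _joint_counts(states, int(states.max()) + 1, y, int(y.max()) + 1)
    return _mi_from_counts(counts)


def max_rel_list(d: DiscreteMatrix, labels: pd.Series) -> RankedFeatureList:
    """Features sorted by MI with the class target, descending (stable ties)."""
    mi = _target_mi(d, labels)
    order = np.argsort(-mi, kind="stable")
    entries = pd.DataFrame(
        {"feature": d.gene_ids.to_numpy()[order], "score": mi[order]}
    )
    return RankedFeatureList(entries, "maxrel")


def mrmr_list(
    d: DiscreteMatrix, labels: pd.Series, n_select: int | None = None
) -> RankedFeatureList:
    """Greedy mRMR selection order with the running D - R score.

    ``n_select`` caps the number of greedy iterations (default: rank every
    feature).  Pairwise MI with each newly selected feature is computed once
    against all remaining candidates, so each feature pair is evaluated at
    most once.
    """
    states = d.states.to_numpy()
    n_genes = states.shape[0]
    ns = int(states.max()) + 1
    if n_select is None:
        n_select = n_genes
    n_select = min(n_select, n_genes)

    relevance = _target_mi(d, labels)
    remaining = np.arange(n_genes)  # kept in input order => stable ties
    red_sum = np.zeros(n_genes)
    picked: list[int] = []
    scores: list[float] = []

    for it in range(n_select):
        if it == 0:
            crit = relevance[remaining]
        else:
            crit = relevance[remaining] - red_sum[remaining] / it
        best = int(np.argmax(crit))
        j = int(remaining[best])
        picked.append(j)
        scores.append(float(crit[best]))
        remaining = np.delete(remaining, best)
        if len(remaining) and it + 1 < n_select:
            counts = _joint_counts(
                states[remaining], ns, states[j], int(states[j].max()) + 1
            )
            red_sum[remaining] += _mi_from_counts(counts)

    entries = pd.DataFrame(
        {"feature": d.gene_ids.to_numpy()[picked], "score": scores}
    )
    return RankedFeatureList(entries, "mrmr")


def write_ranked_list(ranked: RankedFeatureList, path) -> None:
    """Write a ranked list as TSV (rank, feature, score)."""
    ranked.to_table().to_csv(path, sep="\t", index=False)
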