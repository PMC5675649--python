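"""Expression-table IO and the three-step preprocessing chain.

The expression container is a pandas DataFrame with unique gene IDs as the
index and unique sample IDs as the columns; labels are a sample -> class
Series.  Preprocessing follows the order used for platelet RNA-seq
profiles: drop genes zero in more than 90% of samples, quantile-normalize
the samples to a common reference distribution, then log2(x + 1).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed expression or label table."""


def _check_matrix(m: pd.DataFrame, source: str = "expression table") -> pd.DataFrame:
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise FormatError(f"{source}: duplicated gene ID {dup!r}")
    if m.columns.has_duplicates:
        dup = m.columns[m.columns.duplicated()][0]
        raise FormatError(f"{source}: duplicated sample ID {dup!r}")
    return m


def read_expression_table(path) -> pd.DataFrame:
    """Read a TSV with gene IDs in the first column and sample IDs as header."""
    try:
        m = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    non_numeric = [c for c in m.columns if not np.issubdtype(m[c].dtype, np.number)]
    if non_numeric:
        bad = m[non_numeric[0]]
        row = bad[pd.to_numeric(bad, errors="coerce").isna()].index
        raise FormatError(
            f"{path}: non-numeric value in column {non_numeric[0]!r}"
            + (f" at gene {row[0]!r}" if len(row) else "")
        )
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return _check_matrix(m.astype(float), str(path))


def write_expression_table(m: pd.DataFrame, path) -> None:
    """Write the TSV format read back by :func:`read_expression_table`."""
    m.rename_axis("gene_id").to_csv(path, sep="\t")


def read_labels_table(path) -> pd.Series:
    """Read a two-column TSV (sample ID, class label), header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns, found {df.shape[1]}")
    if df.iloc[0, 0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated sample ID {dup!r}")
    return labels


def read_series_matrix(path) -> pd.DataFrame:
    """Read a GEO series-matrix-style expression table.

    Lines starting with ``!`` are metadata and skipped; the remaining block
    is the usual gene x sample table (the optional begin/end sentinel rows
    of the format are also dropped).
    """
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("!")]
    rows = [r for r in rows if r.strip()]
    from io import StringIO

    m = pd.read_csv(StringIO("".join(rows)), sep="\t", index_col=0)
    m.index = m.index.astype(str).str.strip('"')
    m.columns = m.columns.astype(str).str.strip('"')
    return _check_matrix(m.astype(float), str(path))


def align_labels(m: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Reorder labels to the matrix columns, failing on uncovered samples."""
    missing = m.columns.difference(labels.index)
    if len(missing):
        raise FormatError(f"samples without a label: {list(missing[:5])}")
    return labels.loc[m.columns]


def filter_low_expressed(m: pd.DataFrame, zero_fraction_threshold: float = 0.90) -> pd.DataFrame:
    """Drop genes whose zero fraction strictly exceeds the threshold.

    A gene zero in exactly 90% of samples is kept under the default: the
    filter discards only "more than 90% zero" genes.
    """
    if not 0 <= zero_fraction_threshold <= 1:
        raise ValueError("zero_fraction_threshold must be in [0, 1]")
    zero_frac = (m == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_threshold
    if not keep.any():
        warnings.warn("all genes discarded by the zero-fraction filter", stacklevel=2)
    logger.info("zero-fraction filter: %d of %d genes retained", int(keep.sum()), len(m))
    return m.loc[keep]


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean-of-sorted reference distribution.

    Within-sample ranks are preserved; ties receive the mean of the
    reference values across the tied ranks.
    """
    if m.shape[1] < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples", stacklevel=2)
        return m.copy()
    values = m.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="stable")
        col_sorted = values[order, j]
        assigned = reference.copy()
        # average the reference over each run of tied input values
        start = 0
        for end in range(1, len(col_sorted) + 1):
            if end == len(col_sorted) or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = assigned
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def log2_transform(m: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Replace every value v by log2(v + offset)."""
    shifted = m.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        raise ValueError(f"log2 transform undefined: min(value + {offset}) <= 0")
    return pd.DataFrame(np.log2(shifted), index=m.index, columns=m.columns)


def preprocess(
    m: pd.DataFrame,
    zero_fraction_threshold: float = 0.90,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Filter, quantile-normalize, then log2-transform, in that order."""
    return log2_transform(quantile_normalize(filter_low_expressed(m, zero_fraction_threshold)), log_offset)
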