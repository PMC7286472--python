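"""Expression preprocessing and sample-network quality control.

Sample outliers are flagged with the standardized sample-network statistics
of Oldham-style intersample adjacency (ISA) networks: every pair of samples
gets an adjacency ``A_ij = (1 + cor(i, j)) / 2`` from the Pearson correlation
of their expression profiles, and each sample is summarized by its
connectivity ``K`` (sum of adjacencies) and clustering coefficient ``C``.
Standardized versions (Z.K, Z.C) are thresholded to flag outliers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = ["quantile_normalize", "log2_transform", "sample_network_qc"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean distribution.

    After normalization the sorted values of every column equal the
    across-column mean of order statistics.  Ties within a column receive the
    mean reference value of their tied ranks (average-rank convention).

    Parameters
    ----------
    matrix : DataFrame
        Features x samples, no missing values, at least 2 columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    x = matrix.to_numpy(dtype=float)
    n_rows = x.shape[0]
    # reference distribution: mean across columns of the column-sorted values
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = _sps.rankdata(x[:, j], method="average")  # 1..n, halves on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        hi = np.minimum(hi, n_rows - 1)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log2(x + offset)``; rejects nonpositive shifted values."""
    x = matrix.to_numpy(dtype=float) + offset
    if (x <= 0).any():
        raise ValueError("log2_transform: values + offset must be positive")
    return pd.DataFrame(np.log2(x), index=matrix.index, columns=matrix.columns)


def sample_network_qc(
    matrix: pd.DataFrame,
    zk_cut: float = -2.0,
    zc_cut: float = 2.0,
) -> pd.DataFrame:
    """Compute per-sample network statistics and flag outliers.

    The intersample adjacency is ``A_ij = (1 + cor(sample_i, sample_j)) / 2``
    (Pearson over genes, zero diagonal).  For sample ``i``::

        K_i = sum_j A_ij
        C_i = sum_{j != k} A_ij A_jk A_ki / (K_i^2 - sum_j A_ij^2)

    Z.K and Z.C standardize K and C over samples (mean 0, sd 1, ddof=1).
    A sample is an outlier iff ``Z.K < zk_cut`` or ``Z.C > zc_cut``.

    Returns a DataFrame indexed by sample with columns
    ``K, C, Z.K, Z.C, outlier``.
    """
    if matrix.shape[1] < 4:
        raise ValueError("sample_network_qc needs at least 4 samples")
    x = matrix.to_numpy(dtype=float)
    sds = x.std(axis=0)
    if (sds == 0).any():
        bad = matrix.columns[np.flatnonzero(sds == 0)[0]]
        raise ValueError(f"zero-variance sample: {bad!r}")
    corr = np.corrcoef(x, rowvar=False)
    adj = (1.0 + corr) / 2.0
    np.fill_diagonal(adj, 0.0)

    k = adj.sum(axis=1)
    # with zero diagonal, (A^3)_ii sums exactly the ordered (j, k) triangles
    numer = np.einsum("ij,jk,ki->i", adj, adj, adj)
    denom = k**2 - (adj**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)

    zk = _standardize(k)
    zc = _standardize(c)
    report = pd.DataFrame(
        {
            "K": k,
            "C": c,
            "Z.K": zk,
            "Z.C": zc,
            "outlier": (zk < zk_cut) | (zc > zc_cut),
        },
        index=matrix.columns,
    )
    report.index.name = "sample"
    return report


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd
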