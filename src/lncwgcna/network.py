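"""Weighted coexpression network construction and module detection.

The network is unsigned: the adjacency between genes i and j is
``|cor(x_i, x_j)|^beta`` for a soft-thresholding power ``beta`` chosen so the
resulting connectivity distribution is approximately scale-free.  The
adjacency is converted to the topological overlap matrix (TOM), whose
dissimilarity ``1 - TOM`` feeds average-linkage hierarchical clustering;
modules are the clusters below a static cut that meet a minimum size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "ModuleAssignment",
    "adjacency",
    "scale_free_fit",
    "power_scan",
    "pick_power",
    "tom_similarity",
    "average_linkage",
    "detect_modules",
]

#: display colors for module labels 1, 2, ...; label 0 is always "grey"
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
)


def _correlation(matrix: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation; rejects zero-variance genes."""
    x = matrix.to_numpy(dtype=float)
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sds = x.std(axis=1)
    if (sds == 0).any():
        bad = matrix.index[np.flatnonzero(sds == 0)[0]]
        raise ValueError(f"zero-variance gene: {bad!r}")
    return np.corrcoef(x)


def adjacency(matrix: pd.DataFrame, power: float, corr: np.ndarray | None = None) -> np.ndarray:
    """Unsigned weighted adjacency ``a_ij = |cor(x_i, x_j)|^power``, diag 1.

    ``corr`` may supply a precomputed gene correlation matrix (used by
    :func:`power_scan` to avoid recomputing it per power).
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    if corr is None:
        corr = _correlation(matrix)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Whole-network connectivity ``k_i = sum_{j != i} a_ij``."""
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of an adjacency matrix.

    Bins the connectivities into ``n_bins`` equal-width bins and regresses
    log10(bin frequency) on log10(bin mean connectivity) over non-empty bins.
    Returns ``(signed_r2, slope)`` with ``signed_r2 = -sign(slope) * R^2``, so
    a decaying (power-law-like) degree distribution scores positively.
    """
    if adj.shape[0] < 20:
        raise ValueError("scale_free_fit needs at least 20 genes")
    k = connectivity(adj)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size and members.mean() > 0:
            freqs.append(members.size / k.size)
            means.append(members.mean())
    if len(freqs) < 3:
        raise ValueError(
            f"only {len(freqs)} non-empty connectivity bins; "
            "degree distribution too degenerate for a scale-free fit"
        )
    fit = _sps.linregress(np.log10(means), np.log10(freqs))
    signed_r2 = -np.sign(fit.slope) * fit.rvalue**2
    return float(signed_r2), float(fit.slope)


def power_scan(
    matrix: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free fit and connectivity summaries over a grid of powers.

    Returns a DataFrame with columns ``power, r2, slope, mean_k, median_k``.
    """
    corr = _correlation(matrix)
    rows = []
    for beta in powers:
        adj = adjacency(matrix, beta, corr=corr)
        k = connectivity(adj)
        try:
            r2, slope = scale_free_fit(adj, n_bins=n_bins)
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append(
            {"power": beta, "r2": r2, "slope": slope,
             "mean_k": k.mean(), "median_k": float(np.median(k))}
        )
    return pd.DataFrame(rows)


def pick_power(scan: pd.DataFrame, r2_threshold: float = 0.80) -> int:
    """Smallest power whose signed R^2 reaches the threshold.

    Falls back to the power with maximal R^2 (with a warning) when no power
    crosses the threshold.
    """
    if scan.empty:
        raise ValueError("empty power scan")
    ok = scan[scan["r2"] >= r2_threshold]
    if not ok.empty:
        return int(ok.iloc[0]["power"])
    best = scan.loc[scan["r2"].idxmax()]
    warnings.warn(
        f"no power reached scale-free R^2 >= {r2_threshold}; "
        f"using power {int(best['power'])} with R^2 = {best['r2']:.3f}",
        stacklevel=2,
    )
    return int(best["power"])


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a weighted adjacency matrix.

    With ``k_i = sum_{u != i} a_iu`` and ``l_ij = sum_{u != i,j} a_iu a_uj``::

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   TOM_ii = 1

    Values are in [0, 1]; a clique maps to all-ones.
    """
    a = np.asarray(adj, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    k = a.sum(axis=1) - np.diag(a)
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    # (off @ off)_ij sums a_iu a_uj over all u, and u = i, j contribute 0
    l = off @ off
    denom = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 1e-10, (l + off) / np.where(denom > 1e-10, denom, 1.0), 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def average_linkage(dissimilarity: np.ndarray) -> np.ndarray:
    """UPGMA merge tree of a symmetric zero-diagonal dissimilarity matrix.

    Returns a scipy linkage matrix; merge heights are non-decreasing.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity diagonal must be zero")
    return linkage(squareform(d, checks=False), method="average")


@dataclass
class ModuleAssignment:
    """Per-gene module labels; label 0 is the unassigned 'grey' pool."""

    labels: pd.Series  # gene -> int
    cut_height: float
    colors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.colors:
            self.colors = {0: "grey"}
            for lab in sorted(set(self.labels) - {0}):
                self.colors[lab] = MODULE_COLORS[(lab - 1) % len(MODULE_COLORS)]

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() != 0).sum())

    def genes_in(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"module": self.labels})
        out["color"] = out["module"].map(self.colors)
        out.index.name = "gene"
        return out


def detect_modules(
    merge_tree: np.ndarray,
    gene_ids: pd.Index,
    min_module_size: int = 30,
    cut_quantile: float = 0.99,
) -> ModuleAssignment:
    """Static-cut module detection on an average-linkage tree.

    The tree is cut at ``cut_quantile`` times the maximum merge height,
    with that maximum floored at 1 (the ceiling of the TOM-dissimilarity
    scale): the cut separates clusters from the near-1 "grey sea" of
    unclustered genes, and a homogeneous dataset whose merges all sit far
    below 1 stays one cluster instead of being shattered.  Clusters of at
    least ``min_module_size`` genes become modules numbered 1..M by
    decreasing size (ties broken by cluster order); everything else is grey
    (label 0).
    """
    n = len(gene_ids)
    if n != merge_tree.shape[0] + 1:
        raise ValueError("gene_ids length does not match merge tree")
    cut = float(cut_quantile * max(merge_tree[:, 2].max(), 1.0))
    raw = fcluster(merge_tree, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= min_module_size]
    # decreasing size; equal sizes keep the smaller raw cluster id first
    order = sorted(kept.index, key=lambda c: (-kept[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [relabel.get(c, 0) for c in raw], index=gene_ids, name="module"
    )
    return ModuleAssignment(labels=labels, cut_height=cut)
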