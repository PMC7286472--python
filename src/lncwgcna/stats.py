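"""Downstream statistics: gene-set over-representation and survival.

These are generic, locally reproducible replacements for the web services
usually driven point-and-click in this kind of study: hypergeometric
over-representation with Benjamini-Hochberg FDR control, and Kaplan-Meier /
log-rank survival comparison of median-dichotomized expression groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "LogRankResult",
    "hypergeometric_enrichment",
    "bh_adjust",
    "median_split",
    "km_curve",
    "logrank_test",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with a category tag per set."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def hypergeometric_enrichment(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    Sets are intersected with the universe before testing; the p-value is
    ``P(X >= overlap)`` for drawing ``|query|`` genes from the universe.
    BH adjustment runs across all tested sets; ``significant`` flags
    FDR < ``fdr_cutoff``.  Result sorted by p ascending.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe
        overlap = len(in_universe & query)
        k_set = len(in_universe)
        p = float(_sps.hypergeom.sf(overlap - 1, n_universe, k_set, n_query))
        rows.append(
            {
                "set": name,
                "category": collection.categories.get(name, ""),
                "overlap": overlap,
                "set_size": k_set,
                "query_size": n_query,
                "universe_size": n_universe,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["fdr"] < fdr_cutoff
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_split(expression: pd.Series) -> pd.Series:
    """Dichotomize samples at the median: strictly above -> ``high``.

    Values at or below the median (ties included) are ``low``.
    """
    if expression.size < 4:
        raise ValueError("median_split needs at least 4 samples")
    if expression.nunique() == 1:
        raise ValueError("all expression values identical; cannot split")
    med = expression.median()
    return pd.Series(
        np.where(expression > med, "high", "low"),
        index=expression.index,
        name="group",
    )


def km_curve(
    time: pd.Series, event: pd.Series, group: pd.Series
) -> pd.DataFrame:
    """Per-group Kaplan-Meier product-limit survival estimates.

    Returns a long DataFrame with columns ``group, time, survival``; the
    estimate is right-continuous, non-increasing, and starts at S(0) = 1.
    """
    time = pd.Series(time, dtype=float)
    if (time < 0).any():
        raise ValueError("negative survival times")
    event = pd.Series(event).astype(int)
    if not set(event.unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    frames = []
    for name in pd.unique(group):
        mask = (group == name).to_numpy()
        km = KaplanMeierFitter()
        km.fit(time[mask], event_observed=event[mask])
        sf = km.survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p: float
    groups: pd.DataFrame  # per group: n, events, expected_events


def logrank_test(
    time: pd.Series, event: pd.Series, group: pd.Series
) -> LogRankResult:
    """Two-group log-rank test with the hypergeometric variance.

    At each distinct event time the observed events in group 1 are compared
    with their conditional expectation given the risk sets;
    ``chi2 = (sum_t (O_1t - E_1t))^2 / sum_t V_t`` is referred to a 1-df
    chi-square distribution.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    names = pd.unique(pd.Series(group))
    if len(names) != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {len(names)}")
    g1 = np.asarray(group) == names[0]
    if g1.all() or not g1.any():
        raise ValueError("one group is empty")
    if event.sum() < 1:
        raise ValueError("need at least one event")

    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    expected = {names[0]: 0.0, names[1]: 0.0}
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        n1_t = (at_risk & g1).sum()
        d_t = ((time == t) & (event == 1)).sum()
        d1_t = ((time == t) & (event == 1) & g1).sum()
        e1_t = d_t * n1_t / n_t
        expected[names[0]] += e1_t
        expected[names[1]] += d_t - e1_t
        o_minus_e += d1_t - e1_t
        if n_t > 1:
            var += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    statistic = 0.0 if var == 0 else float(o_minus_e**2 / var)
    p = float(_sps.chi2.sf(statistic, df=1)) if var > 0 else 1.0
    groups = pd.DataFrame(
        {
            "n": [int(g1.sum()), int((~g1).sum())],
            "events": [int(event[g1].sum()), int(event[~g1].sum())],
            "expected_events": [expected[names[0]], expected[names[1]]],
        },
        index=pd.Index(names, name="group"),
    )
    return LogRankResult(statistic=statistic, p=p, groups=groups)
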