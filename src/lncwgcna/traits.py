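"""Module eigengenes, module-trait statistics, hub screening, stage ANOVA.

The clinical trait is the ordinal tumor stage (1 = normal duct ... 4 =
invasive lesion), z-scored.  Gene significance (GS) is the absolute Pearson
correlation of a gene with the trait; module significance (MS) averages GS
over a module's members.  The stage-relevant module is the one maximizing
MS, cross-checked against the module-eigengene/trait correlation.  Hubs are
the module members passing the dual rule |cor.Standard| > t AND
|cor.Weighted| > t (default t = 0.8), where cor.Weighted blends the gene
profile with its module eigengene before correlating with the trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .network import ModuleAssignment

__all__ = [
    "P_FLOOR",
    "trait_scores",
    "cor_with_p",
    "module_eigengene",
    "module_eigengenes",
    "module_significance",
    "select_significant_module",
    "screening_stats",
    "identify_hubs",
    "stage_anova",
]

#: smallest reported p-value (R's .Machine$double.eps convention)
P_FLOOR = 2.2e-16


def trait_scores(stages: pd.Series, order: tuple[str, ...]) -> pd.Series:
    """Map ordered stage labels to z-scored ordinal scores 1..len(order).

    ``order`` lists the stage names from least to most advanced; the returned
    series is indexed by sample.
    """
    unknown = set(stages) - set(order)
    if unknown:
        raise ValueError(f"stage labels not in declared order: {sorted(unknown)}")
    scores = stages.map({s: i + 1 for i, s in enumerate(order)}).astype(float)
    if scores.nunique() < 2:
        raise ValueError("trait needs at least 2 distinct stages")
    z = (scores - scores.mean()) / scores.std(ddof=0)
    return z.rename("stage_score")


def cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided Student-t p-value.

    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on ``n - 2`` degrees of freedom;
    p is floored at ``P_FLOOR`` so it stays in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector in correlation")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, P_FLOOR
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return r, float(np.clip(p, P_FLOOR, 1.0))


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene in module")
    return (x - mu) / sd


def module_eigengene(
    matrix: pd.DataFrame, genes: pd.Index | list[str]
) -> tuple[pd.Series, float]:
    """First principal component of a module, as a sample profile.

    The module submatrix is gene-standardized, decomposed by SVD, and the
    leading right singular vector is scaled to unit variance and sign-aligned
    so it correlates positively with the module's mean standardized profile.
    Returns ``(eigengene, proportion of variance explained)``.
    """
    sub = matrix.loc[list(genes)]
    if sub.shape[0] < 2:
        raise ValueError("module needs at least 2 genes")
    z = _zscore_rows(sub.to_numpy(dtype=float))
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    pc = pc / pc.std(ddof=1)
    return pd.Series(pc, index=matrix.columns, name="ME"), var_explained


def module_eigengenes(
    matrix: pd.DataFrame, assignment: ModuleAssignment
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Eigengenes for every non-grey module (samples x modules)."""
    cols, varexp = {}, {}
    for label in sorted(set(assignment.labels) - {0}):
        me, ve = module_eigengene(matrix, assignment.genes_in(label))
        cols[label] = me
        varexp[label] = ve
    return pd.DataFrame(cols), varexp


def module_significance(
    matrix: pd.DataFrame,
    trait: pd.Series,
    assignment: ModuleAssignment,
    eigengenes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-module MS and eigengene-trait correlation.

    MS is the mean absolute gene-trait Pearson correlation over the module's
    members.  The grey pool (label 0) is excluded.  Returns a DataFrame
    indexed by module label with columns ``size, MS, me_trait_r, me_trait_p``.
    """
    if eigengenes is None:
        eigengenes, _ = module_eigengenes(matrix, assignment)
    t = trait.loc[matrix.columns].to_numpy()
    rows = {}
    for label in sorted(set(assignment.labels) - {0}):
        genes = assignment.genes_in(label)
        if len(genes) == 0:
            warnings.warn(f"module {label} is empty; skipped", stacklevel=2)
            continue
        gs = [abs(cor_with_p(matrix.loc[g].to_numpy(), t)[0]) for g in genes]
        r, p = cor_with_p(eigengenes[label].loc[matrix.columns].to_numpy(), t)
        rows[label] = {"size": len(genes), "MS": float(np.mean(gs)),
                       "me_trait_r": r, "me_trait_p": p}
    out = pd.DataFrame(rows).T
    out.index.name = "module"
    if not out.empty:
        out["size"] = out["size"].astype(int)
    return out


def select_significant_module(stats: pd.DataFrame) -> int:
    """Module maximizing MS, verified against the eigengene-trait criterion.

    Ties on MS break toward the lower label (the larger module).  If the MS
    winner does not also maximize |eigengene-trait r|, it is still returned,
    with a warning that the two selection methods disagree.
    """
    if stats.empty:
        raise ValueError("no non-grey modules to select from")
    ms_winner = int(stats["MS"].idxmax())  # idxmax: first (lowest label) on ties
    me_winner = int(stats["me_trait_r"].abs().idxmax())
    if (stats["MS"] == stats.loc[ms_winner, "MS"]).sum() > 1:
        warnings.warn(
            f"MS tie; selecting module {ms_winner} (lower label)", stacklevel=2
        )
    if me_winner != ms_winner:
        warnings.warn(
            f"module selection methods disagree: MS favors {ms_winner}, "
            f"eigengene-trait correlation favors {me_winner}; using MS",
            stacklevel=2,
        )
    return ms_winner


def screening_stats(
    matrix: pd.DataFrame,
    trait: pd.Series,
    assignment: ModuleAssignment,
    eigengenes: pd.DataFrame,
    mix_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene hub-screening statistics.

    ``cor.Standard`` is the plain gene-trait Pearson correlation.
    ``cor.Weighted`` correlates the trait with a blend
    ``(1 - w) * z(gene) + w * z(module eigengene)`` (w = ``mix_weight``),
    which denoises the gene profile with its module's summary; grey genes
    have no eigengene and use w = 0.  ``kME_<m>`` columns give module
    membership (correlation with each module eigengene).
    """
    if not 0.0 <= mix_weight <= 1.0:
        raise ValueError("mix_weight must be in [0, 1]")
    t = trait.loc[matrix.columns].to_numpy()
    me = eigengenes.loc[matrix.columns]
    me_z = {
        m: (me[m] - me[m].mean()).to_numpy() / me[m].std(ddof=1)
        for m in me.columns
    }
    rows = []
    for gene in matrix.index:
        x = matrix.loc[gene].to_numpy(dtype=float)
        label = int(assignment.labels[gene])
        r_s, p_s = cor_with_p(x, t)
        if label == 0 or mix_weight == 0.0:
            blend = x
        else:
            z = (x - x.mean()) / x.std(ddof=1)
            blend = (1.0 - mix_weight) * z + mix_weight * me_z[label]
        r_w, p_w = cor_with_p(blend, t)
        row = {
            "gene": gene, "module": label,
            "cor.Standard": r_s, "p.Standard": p_s,
            "cor.Weighted": r_w, "p.Weighted": p_w,
        }
        for m in me.columns:
            row[f"kME_{m}"] = float(np.corrcoef(x, me[m].to_numpy())[0, 1])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def identify_hubs(
    stats: pd.DataFrame, module: int, threshold: float = 0.8
) -> pd.DataFrame:
    """Hub genes of a module: |cor.Standard| > t AND |cor.Weighted| > t.

    Both inequalities are strict; the result is sorted by |cor.Weighted|
    descending and may be empty.
    """
    members = stats[stats["module"] == module]
    hubs = members[
        (members["cor.Standard"].abs() > threshold)
        & (members["cor.Weighted"].abs() > threshold)
    ]
    return hubs.reindex(hubs["cor.Weighted"].abs().sort_values(ascending=False).index)


@dataclass
class _AnovaGroups:
    arrays: list[np.ndarray]
    names: list[str]


def _anova_groups(matrix: pd.DataFrame, stages: pd.Series) -> _AnovaGroups:
    stages = stages.loc[matrix.columns]
    arrays, names = [], []
    for name in pd.unique(stages):
        cols = stages.index[stages == name]
        if len(cols) < 2:
            raise ValueError(f"stage {name!r} has fewer than 2 samples")
        arrays.append(matrix[cols].to_numpy(dtype=float))
        names.append(str(name))
    if len(arrays) < 2:
        raise ValueError("need at least 2 stage groups")
    return _AnovaGroups(arrays, names)


def stage_anova(matrix: pd.DataFrame, stages: pd.Series) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of each gene across stage groups.

    Returns per-gene F and upper-tail p with (k-1, N-k) degrees of freedom.
    Zero within-group variance with distinct group means yields ``F = inf``
    and the floored p-value ``P_FLOOR``; zero between-group variance yields
    ``F = 0, p = 1``.
    """
    groups = _anova_groups(matrix, stages)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = _sps.f_oneway(*groups.arrays, axis=1)
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    group_means = np.stack([g.mean(axis=1) for g in groups.arrays])
    no_between = np.ptp(group_means, axis=0) == 0
    f = np.where(no_between, 0.0, f)
    p = np.where(no_between, 1.0, p)
    degenerate = (np.isinf(f) | np.isnan(p)) & ~no_between
    f = np.where(degenerate, np.inf, f)
    p = np.where(degenerate, P_FLOOR, p)
    out = pd.DataFrame(
        {"F": f, "p": np.clip(p, P_FLOOR, 1.0)}, index=matrix.index
    )
    out.index.name = "gene"
    return out
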