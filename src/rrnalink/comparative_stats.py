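"""Statistical comparisons between operon-linkage classes.

Covers the comparisons used downstream of classification: PCA of the
standardized genomic features; Kruskal–Wallis with Dunn's post-hoc
z-tests (Holm-adjusted) for three-class contrasts; Welch's unequal-variance
t-test for two-class contrasts; one-way ANOVA with Tukey's HSD; paired
t-tests across phyla on COG functional-category mean counts; and
phylogenetic generalized least squares (PGLS) under a Brownian-motion
covariance model for RNase copy numbers.

PGLS model: y = a + b·x + ε with Cov(ε_i, ε_j) equal to the shared
root-to-MRCA path length of taxa i and j on the supplied tree.  The slope
is tested with a two-sided t statistic on n − 2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# rank / location tests

class KruskalDunnResult(NamedTuple):
    h_statistic: float
    p_value: float
    dunn: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj (Holm)


def _group_samples(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    return {g: values[groups == g] for g in pd.unique(groups)}


def kruskal_dunn(values: Sequence[float], groups: Sequence) -> KruskalDunnResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise z-tests.

    Dunn's z uses the rank-variance formula with tie correction; raw
    two-sided normal p-values are Holm-adjusted (the adjustment method is
    echoed in the output column name).  Requires >= 3 groups with n >= 2
    each; for two groups use :func:`welch_t`.
    """
    samples = _group_samples(values, groups)
    if len(samples) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use welch_t for two")
    for g, s in samples.items():
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    h, p = stats.kruskal(*samples.values())

    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    ranks = stats.rankdata(vals)
    n_total = vals.size
    _, tie_counts = np.unique(vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    labels = list(samples)
    mean_rank = {g: ranks[grp == g].mean() for g in labels}
    n = {g: int((grp == g).sum()) for g in labels}

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = math.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_raw": 2.0 * stats.norm.sf(abs(z))})
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    dunn["p_holm"] = multipletests(dunn["p_raw"], method="holm")[1]
    return KruskalDunnResult(float(h), float(p), dunn)


class WelchResult(NamedTuple):
    t: float
    df: float  # Satterthwaite degrees of freedom
    p: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs n >= 2 in each sample")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("welch_t needs nonzero variance in at least one sample")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


class AnovaTukeyResult(NamedTuple):
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group_a, group_b, statistic, p_adj


def anova_tukey(values: Sequence[float], groups: Sequence) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Degenerate input (all values identical) reports F = 0 with all pairwise
    p-values 1 rather than erroring.
    """
    samples = _group_samples(values, groups)
    if len(samples) < 2:
        raise ValueError("anova_tukey needs >= 2 groups")
    for g, s in samples.items():
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    labels = list(samples)

    vals = np.asarray(values, dtype=float)
    if np.ptp(vals) == 0:
        pairs = [
            {"group_a": labels[i], "group_b": labels[j], "statistic": 0.0, "p_adj": 1.0}
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        ]
        return AnovaTukeyResult(0.0, 1.0, pd.DataFrame(pairs))

    f, p = stats.f_oneway(*samples.values())
    hsd = stats.tukey_hsd(*samples.values())
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "statistic": float(hsd.statistic[i, j]),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(float(f), float(p), pd.DataFrame(pairs))


def paired_t_by_category(
    table_linked: pd.DataFrame, table_unlinked: pd.DataFrame
) -> pd.DataFrame:
    """Paired t-test per functional category across taxa.

    Rows are the pairing unit (per-phylum group means, paired across
    linkage status); columns are functional categories.  Only categories
    present in both tables are tested.
    """
    common_rows = table_linked.index.intersection(table_unlinked.index)
    if len(common_rows) < 2:
        raise ValueError("paired_t_by_category needs >= 2 paired rows")
    common_cols = [c for c in table_linked.columns if c in table_unlinked.columns]
    rows = []
    for cat in common_cols:
        a = table_linked.loc[common_rows, cat].astype(float)
        b = table_unlinked.loc[common_rows, cat].astype(float)
        if np.allclose(a - b, (a - b).iloc[0]) and np.isclose((a - b).std(ddof=1), 0):
            # constant difference: t undefined unless the difference is 0
            t = 0.0 if np.allclose(a, b) else math.inf
            p = 1.0 if np.allclose(a, b) else 0.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "category": cat,
                "mean_linked": float(a.mean()),
                "mean_unlinked": float(b.mean()),
                "ratio_unlinked_to_linked": float(b.mean() / a.mean()) if a.mean() else math.nan,
                "t": t,
                "p": p,
                "n_pairs": int(len(common_rows)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ordination

class PcaResult(NamedTuple):
    scores: pd.DataFrame
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(X: Union[pd.DataFrame, np.ndarray], n_components: Optional[int] = None) -> PcaResult:
    """PCA on columns standardized to zero mean and unit variance (ddof=1).

    Constant columns carry no variance and are dropped with a warning.
    """
    df = pd.DataFrame(X).astype(float)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("pca needs at least 2 rows and 2 columns")
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns from PCA: {constant}")
        df = df.drop(columns=constant)
        sd = sd.drop(constant)
        if df.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant columns remain")
    Z = (df - df.mean()) / sd
    model = _SkPCA(n_components=n_components)
    scores = model.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=df.columns, columns=comp_names),
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# phylogenetic GLS

@dataclass(frozen=True)
class PglsFit:
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    tree_taxa: tuple[str, ...]


TreeLike = Union[dendropy.Tree, str, Path]


def _load_tree(tree: TreeLike) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" in text:  # newick string
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=text, schema="newick")


def brownian_covariance(tree: TreeLike, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix for the given taxon order.

    V[i, j] is the shared root-to-MRCA path length of taxa i and j;
    V[i, i] is the root-to-tip distance.  Tip labels must exactly match
    ``taxa`` as a set.
    """
    t = _load_tree(tree)
    label_of = {}
    for leaf in t.leaf_node_iter():
        label_of[leaf.taxon.label] = leaf
    tip_labels = set(label_of)
    wanted = set(taxa)
    if tip_labels != wanted:
        missing = sorted(wanted - tip_labels)
        extra = sorted(tip_labels - wanted)
        raise ValueError(
            f"tree/taxa mismatch: missing from tree {missing}; extra tips {extra}"
        )
    depth: dict[dendropy.Node, float] = {}
    for node in t.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)
    pdm = t.phylogenetic_distance_matrix()
    n = len(taxa)
    V = np.zeros((n, n))
    taxon_of = {lab: label_of[lab].taxon for lab in taxa}
    for i in range(n):
        V[i, i] = depth[label_of[taxa[i]]]
        for j in range(i + 1, n):
            mrca = pdm.mrca(taxon_of[taxa[i]], taxon_of[taxa[j]])
            V[i, j] = V[j, i] = depth[mrca]
    return V


def pgls_brownian(
    tree: TreeLike,
    y: Union[pd.Series, dict],
    x: Union[pd.Series, dict],
    V: Optional[np.ndarray] = None,
) -> PglsFit:
    """GLS regression of y on x with Brownian phylogenetic covariance.

    b = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, with residual variance RSS/(n−2) scaling the
    GLS parameter covariance; the slope is tested two-sided against a t
    distribution with n − 2 degrees of freedom.  A precomputed ``V`` (from
    :func:`brownian_covariance`, same taxon order as y) skips tree work —
    useful in simulation loops.
    """
    ys = pd.Series(y, dtype=float)
    xs = pd.Series(x, dtype=float)
    taxa = list(ys.index)
    if set(taxa) != set(xs.index):
        raise ValueError("y and x must be indexed by the same taxa")
    xs = xs.reindex(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("pgls needs at least 3 taxa")
    if V is None:
        V = brownian_covariance(tree, taxa)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(f"covariance matrix is singular: {err}") from err
    X = np.column_stack([np.ones(n), xs.to_numpy()])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, ys.to_numpy(), lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = math.sqrt(cov[1, 1])
    t_stat = float(beta[1]) / se
    p = 2.0 * stats.t.sf(abs(t_stat), dof)
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=se,
        t_stat=t_stat,
        p_value=float(p),
        tree_taxa=tuple(taxa),
    )
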