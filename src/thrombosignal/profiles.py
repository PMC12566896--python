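"""Multivariate structure of the drug x event signal matrix.

Each flagged drug is described by its profile of ln-ROR values across the
individual thrombosis preferred terms (one 2x2 per drug/term pair, Haldane-
corrected where a cell is zero, so every entry is finite).  The matrix is
column-standardized and decomposed by PCA; the first component typically
orders drugs by overall thrombogenicity while later components separate
venous from arterial event profiles.  Drugs are then grouped by Ward
agglomerative clustering on their scores over the first three components,
and the venous/arterial contrast on a chosen component is summarized by
Welch's unequal-variance t test over the term loadings (mixed-vessel terms
excluded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.stats import ttest_ind
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from thrombosignal.signals import ContingencyTable, haldane
from thrombosignal.terms import SmqTermSet

__all__ = [
    "build_matrix",
    "ScaledPCA",
    "pca",
    "ClusterTree",
    "WardClusterer",
    "ward_cluster",
    "cut_tree",
    "SmqAxisComparison",
    "smq_axis_comparison",
    "identify_vessel_axis",
    "export_dendrogram",
    "tree_to_dict",
    "tree_from_dict",
    "tree_to_newick",
]


def build_matrix(rows: pd.DataFrame, drugs: list[str], pts: list[str],
                 min_pt_reports: int = 0) -> pd.DataFrame:
    """ln-ROR matrix: one cell per (drug, single preferred term).

    For each pair the 2x2 is (drug & pt) vs (drug & other pt) vs (other
    drugs & pt) vs the rest, over the full integrated table; zero cells are
    Haldane-corrected so every ln ROR is finite.  Terms with fewer than
    ``min_pt_reports`` total rows are dropped.
    """
    if not drugs or not pts:
        raise ValueError("drug and PT lists must be nonempty")
    counts = pd.crosstab(rows["drug_name"], rows["pt"])
    counts = counts.reindex(index=drugs, columns=pts, fill_value=0)
    pt_totals = rows["pt"].value_counts().reindex(pts, fill_value=0)
    kept = [p for p in pts if pt_totals[p] >= min_pt_reports]
    if not kept:
        raise ValueError("no preferred term meets min_pt_reports")
    counts = counts[kept]
    pt_totals = pt_totals[kept]

    n = len(rows)
    drug_totals = rows["drug_name"].value_counts().reindex(
        drugs, fill_value=0)

    a = counts.to_numpy(dtype=float)
    b = drug_totals.to_numpy(dtype=float)[:, None] - a
    c = pt_totals.to_numpy(dtype=float)[None, :] - a
    d = n - a - b - c
    # per-pair Haldane: only tables containing a zero get the 0.5 shift
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    shift = np.where(zero, 0.5, 0.0)
    ln_ror = (np.log(a + shift) + np.log(d + shift)
              - np.log(b + shift) - np.log(c + shift))
    return pd.DataFrame(ln_ror, index=list(drugs), columns=kept)


class ScaledPCA(BaseEstimator):
    """PCA of a signal matrix on the correlation scale.

    Columns are standardized to zero mean and unit variance before the
    singular value decomposition (``scale=False`` gives covariance-scale
    PCA).  Zero-variance columns are dropped with a warning.  Component
    signs are fixed so each component's largest-magnitude loading is
    positive.

    Attributes
    ----------
    loadings_ : pandas.DataFrame, terms x components
    scores_ : pandas.DataFrame, drugs x components
    explained_ratio_ : numpy.ndarray
        Per-component fraction of total variance, non-increasing.
    dropped_columns_ : list of str
    """

    def __init__(self, n_components: int | None = None, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None) -> "ScaledPCA":
        X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("PCA needs at least 2 rows and 2 columns")
        var = X.var(axis=0, ddof=0)
        self.dropped_columns_ = list(X.columns[var == 0])
        if self.dropped_columns_:
            warnings.warn("dropping zero-variance column(s): "
                          f"{self.dropped_columns_}", stacklevel=2)
            X = X.loc[:, var > 0]
        Z = X - X.mean(axis=0)
        if self.scale:
            Z = Z / X.std(axis=0, ddof=0)
        k = self.n_components
        if k is not None and k > min(Z.shape):
            raise ValueError("n_components exceeds matrix rank bound")
        model = PCA(n_components=k, svd_solver="full")
        scores = model.fit_transform(Z.to_numpy())
        loadings = model.components_.T  # (terms, components)
        # deterministic orientation: dominant loading positive
        flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                                np.arange(loadings.shape[1])])
        flip[flip == 0] = 1.0
        loadings = loadings * flip
        scores = scores * flip
        comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
        self.loadings_ = pd.DataFrame(loadings, index=X.columns,
                                      columns=comp_names)
        self.scores_ = pd.DataFrame(scores, index=X.index,
                                    columns=comp_names)
        self.explained_ratio_ = model.explained_variance_ratio_
        self.standardized_ = Z
        return self


def pca(matrix: pd.DataFrame, k: int | None = None,
        scale: bool = True) -> ScaledPCA:
    """Fit a :class:`ScaledPCA` and return it."""
    return ScaledPCA(n_components=k, scale=scale).fit(matrix)


@dataclass
class ClusterTree:
    """Ward merge history: scipy linkage matrix plus the leaf labels.

    Merge ``i`` of the linkage joins nodes ``Z[i, 0]`` and ``Z[i, 1]``
    (leaves are 0..n-1, internal nodes n..2n-2) at height ``Z[i, 2]``;
    heights are non-decreasing for Ward's criterion.
    """

    linkage: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Each merge as the two leaf-label sets joined, with its height."""
        members: dict[int, frozenset] = {
            i: frozenset([lbl]) for i, lbl in enumerate(self.leaves)}
        out = []
        n = self.n_leaves
        for i, (u, v, h, _) in enumerate(self.linkage):
            a, b = members[int(u)], members[int(v)]
            out.append((a, b, float(h)))
            members[n + i] = a | b
        return out


class WardClusterer(BaseEstimator):
    """Ward agglomerative clustering of PCA scores.

    Uses Ward's minimum-variance criterion (the Ward.D2 update on Euclidean
    distances): each merge minimizes the increase in total within-cluster
    sum of squares.  By default the first ``n_components=3`` score columns
    are used.

    Attributes
    ----------
    tree_ : ClusterTree
    labels_ : numpy.ndarray
        Cluster ids 1..k from cutting the tree at ``n_clusters``.
    """

    def __init__(self, n_clusters: int = 4, n_components: int | None = 3):
        self.n_clusters = n_clusters
        self.n_components = n_components

    def fit(self, scores: pd.DataFrame, y=None) -> "WardClusterer":
        scores = pd.DataFrame(scores)
        if len(scores) < 2:
            raise ValueError("clustering needs at least 2 observations")
        X = scores.iloc[:, :self.n_components] if self.n_components else scores
        Z = linkage(X.to_numpy(), method="ward")
        self.tree_ = ClusterTree(Z, [str(i) for i in scores.index])
        self.labels_ = cut_tree(self.tree_,
                                min(self.n_clusters, len(scores)))
        return self


def ward_cluster(scores: pd.DataFrame,
                 n_components: int | None = 3) -> ClusterTree:
    """Functional wrapper: Ward tree over the first PCA score columns."""
    return WardClusterer(n_components=n_components).fit(scores).tree_


def cut_tree(tree: ClusterTree, k: int) -> np.ndarray:
    """Flat cluster ids (1..k) for each leaf, cutting the tree at k groups."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError("k must be between 1 and the number of leaves")
    return fcluster(tree.linkage, t=k, criterion="maxclust")


@dataclass(frozen=True)
class SmqAxisComparison:
    mean_venous: float
    mean_arterial: float
    t: float
    p: float


def smq_axis_comparison(model: ScaledPCA, term_set: SmqTermSet,
                        component: int = 2) -> SmqAxisComparison:
    """Welch's t on a component's term loadings, venous vs arterial scope.

    Mixed-vessel terms are excluded.  ``component`` is 1-based (2 = the
    venous/arterial axis).
    """
    col = f"PC{component}"
    if col not in model.loadings_.columns:
        raise ValueError(f"component {component} not fitted")
    load = model.loadings_[col]
    groups = {}
    for scope in ("venous", "arterial"):
        keys = [pt for pt in load.index if
                pt in term_set.pts and term_set.scope(pt) == scope]
        if len(keys) < 2:
            raise ValueError(f"need >= 2 {scope} terms with loadings")
        groups[scope] = load[keys].to_numpy()
    res = ttest_ind(groups["venous"], groups["arterial"], equal_var=False)
    return SmqAxisComparison(float(groups["venous"].mean()),
                             float(groups["arterial"].mean()),
                             float(res.statistic), float(res.pvalue))


def identify_vessel_axis(model: ScaledPCA, term_set: SmqTermSet) -> int:
    """1-based index of the component best separating venous from arterial.

    Components are labelled by their loadings, not their rank: the
    vessel-type axis is the fitted component whose venous-scope and
    arterial-scope term loadings differ the most (largest |mean gap|).
    """
    best, best_gap = 1, -1.0
    for i in range(1, model.loadings_.shape[1] + 1):
        cmp = smq_axis_comparison(model, term_set, component=i)
        gap = abs(cmp.mean_venous - cmp.mean_arterial)
        if gap > best_gap:
            best, best_gap = i, gap
    return best


# ---------------------------------------------------------------------------
# Serialization of the merge history

def tree_to_dict(tree: ClusterTree) -> dict:
    """Nested-merge JSON structure with heights (leaves have height 0)."""
    root, _ = to_tree(tree.linkage, rd=True)

    def node(t):
        if t.is_leaf():
            return {"leaf": tree.leaves[t.get_id()], "height": 0.0}
        return {"height": float(t.dist),
                "children": [node(t.get_left()), node(t.get_right())]}

    return node(root)


def tree_from_dict(d: dict) -> ClusterTree:
    """Inverse of :func:`tree_to_dict` (merge sets and heights round-trip)."""
    leaves: list[str] = []

    def collect(node):
        if "leaf" in node:
            leaves.append(node["leaf"])
    _walk(d, collect)
    index = {lbl: i for i, lbl in enumerate(leaves)}
    n = len(leaves)
    merges: list[tuple[int, int, float, int]] = []

    def build(node) -> tuple[int, int]:
        if "leaf" in node:
            return index[node["leaf"]], 1
        (lid, ln), (rid, rn) = (build(c) for c in node["children"])
        merges.append((lid, rid, node["height"], ln + rn))
        return n + len(merges) - 1, ln + rn

    build(d)
    # reorder merges by height (stable, so children precede parents on
    # ties) and renumber internal ids accordingly
    order = sorted(range(len(merges)), key=lambda i: merges[i][2])
    newid = {n + old: n + new for new, old in enumerate(order)}

    def remap(i: int) -> int:
        return newid.get(i, i)

    Z = np.array([(remap(merges[i][0]), remap(merges[i][1]),
                   merges[i][2], merges[i][3]) for i in order], dtype=float)
    return ClusterTree(Z, leaves)


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick string; branch lengths are merge-height differences."""
    root, _ = to_tree(tree.linkage, rd=True)

    def node(t, parent_height: float) -> str:
        length = parent_height - t.dist
        if t.is_leaf():
            name = tree.leaves[t.get_id()].replace(" ", "_")
            return f"{name}:{parent_height:g}"
        inner = ",".join(node(c, t.dist)
                         for c in (t.get_left(), t.get_right()))
        return f"({inner}):{length:g}"

    inner = ",".join(node(c, root.dist)
                     for c in (root.get_left(), root.get_right()))
    return f"({inner});"


def _walk(node: dict, fn) -> None:
    fn(node)
    for child in node.get("children", []):
        _walk(child, fn)


def export_dendrogram(tree: ClusterTree, scores: pd.DataFrame, out_dir,
                      n_clusters: int = 4) -> dict[str, str]:
    """Write dendrogram.json, dendrogram.nwk and clusters.csv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    with open(out / "dendrogram.json", "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1)
    paths["json"] = str(out / "dendrogram.json")
    (out / "dendrogram.nwk").write_text(tree_to_newick(tree) + "\n")
    paths["newick"] = str(out / "dendrogram.nwk")
    labels = cut_tree(tree, n_clusters)
    clusters = scores.copy()
    clusters.insert(0, "cluster", labels)
    clusters.index.name = "drug_name"
    clusters.to_csv(out / "clusters.csv")
    paths["clusters"] = str(out / "clusters.csv")
    return paths
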