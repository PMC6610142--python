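"""Beta-diversity distances (Bray-Curtis, UniFrac, Euclidean) and
ordination (PCoA, NMDS).

UniFrac is computed from a branch-by-tip incidence decomposition of the
rooted tree: the abundance descending a branch is the post-order sum of
tip relative abundances below it, and the root's own branch (if any) is
excluded. Weighted UniFrac is normalized by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from sklearn.manifold import MDS


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample-by-sample distance matrix."""

    ids: list[str]
    data: np.ndarray
    metric: str = "unknown"
    level: str = "otu"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if np.abs(d - d.T).max() > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if (d < 0).any():
            raise ValueError("negative distances")
        self.data = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class Ordination:
    coords: pd.DataFrame
    eigvals: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    negative_eigvals: np.ndarray = field(default_factory=lambda: np.array([]))
    stress: float | None = None
    converged: bool | None = None
    n_restarts: int | None = None


# ---------------------------------------------------------------------------
# distances

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC = sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(abund: pd.DataFrame, metric: str = "braycurtis",
                    level: str = "otu") -> DistanceMatrix:
    """Pairwise Bray-Curtis or Euclidean distances over table rows."""
    name = {"braycurtis": "bray-curtis", "euclidean": "euclidean"}[metric]
    d = squareform(pdist(abund.to_numpy(dtype=float), metric=metric))
    return DistanceMatrix(list(abund.index), d, metric=name, level=level)


def _branch_decomposition(tree: TreeNode) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (incidence M: branches x tips, lengths, tip names); one row
    per non-root node carrying a branch length."""
    tips = [t.name for t in tree.tips()]
    tip_pos = {name: i for i, name in enumerate(tips)}
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise ValueError(f"node {node.name!r} lacks a branch length")
        mask = np.zeros(len(tips), dtype=bool)
        for t in node.tips(include_self=True):
            mask[tip_pos[t.name]] = True
        rows.append(mask)
        lengths.append(float(node.length))
    return np.array(rows), np.array(lengths), tips


def _align_to_tips(vec: dict | pd.Series, tips: list[str]) -> np.ndarray:
    s = pd.Series(vec, dtype=float)
    unknown = s.index.difference(tips)
    if len(unknown):
        raise ValueError(f"taxa not in tree: {list(unknown)[:5]}")
    return s.reindex(tips, fill_value=0.0).to_numpy()


def unweighted_unifrac(tree: TreeNode, presence_a, presence_b) -> float:
    """Fraction of branch length leading exclusively to one sample's taxa,
    over branch length leading to taxa of either sample."""
    m, lengths, tips = _branch_decomposition(tree)
    a = _align_to_tips(pd.Series(1.0, index=list(presence_a)), tips) > 0
    b = _align_to_tips(pd.Series(1.0, index=list(presence_b)), tips) > 0
    if not a.any() or not b.any():
        raise ValueError("each sample must contain at least one taxon")
    in_a = m @ a > 0
    in_b = m @ b > 0
    unique = lengths[in_a ^ in_b].sum()
    union = lengths[in_a | in_b].sum()
    return float(unique / union)


def weighted_unifrac(tree: TreeNode, relabund_a, relabund_b,
                     normalized: bool = True) -> float:
    """sum_i b_i |A_i - B_i| over branches, A_i/B_i the fractions of each
    sample's abundance descending branch i; normalized divides by
    sum_i b_i (A_i + B_i)."""
    m, lengths, tips = _branch_decomposition(tree)
    a = _align_to_tips(relabund_a, tips)
    b = _align_to_tips(relabund_b, tips)
    a = a / a.sum()
    b = b / b.sum()
    branch_a = m @ a
    branch_b = m @ b
    raw = float((lengths * np.abs(branch_a - branch_b)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (branch_a + branch_b)).sum())
    return raw / denom


def unifrac_matrix(tree: TreeNode, rel_abund: pd.DataFrame,
                   weighted: bool = True, normalized: bool = True,
                   level: str = "otu") -> DistanceMatrix:
    """All pairwise UniFrac distances for a relative-abundance table whose
    columns are tree tips."""
    m, lengths, tips = _branch_decomposition(tree)
    x = rel_abund.reindex(columns=tips, fill_value=0.0).to_numpy(dtype=float)
    unknown = rel_abund.columns.difference(tips)
    if len(unknown) and rel_abund[list(unknown)].to_numpy().any():
        raise ValueError("abundance on taxa absent from the tree")
    x = x / x.sum(axis=1, keepdims=True)
    branch = x @ m.T  # samples x branches
    n = x.shape[0]
    d = np.zeros((n, n))
    if weighted:
        for i in range(n):
            diff = (lengths * np.abs(branch[i] - branch[i + 1:])).sum(axis=1)
            if normalized:
                diff = diff / (lengths * (branch[i] + branch[i + 1:])).sum(axis=1)
            d[i, i + 1:] = diff
    else:
        pres = branch > 0
        for i in range(n):
            uniq = (lengths * (pres[i] ^ pres[i + 1:])).sum(axis=1)
            union = (lengths * (pres[i] | pres[i + 1:])).sum(axis=1)
            d[i, i + 1:] = uniq / union
    d = d + d.T
    name = ("weighted-unifrac" if weighted else "unweighted-unifrac")
    return DistanceMatrix(list(rel_abund.index), d, metric=name, level=level)


# ---------------------------------------------------------------------------
# ordination

def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical metric scaling: Gower double-centering of -D^2/2 followed
    by eigendecomposition; axes with negative eigenvalues are excluded
    (reported, not corrected)."""
    d2 = dm.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-8 * max(abs(eigvals[0]), 1.0)
    pos = eigvals > tol
    neg = eigvals[eigvals < -tol]
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating axes")
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    prop = eigvals[:n_axes] / eigvals[pos].sum()
    return Ordination(coords=pd.DataFrame(coords, index=dm.ids, columns=cols),
                      eigvals=eigvals, proportion_explained=prop,
                      negative_eigvals=neg)


def nmds(dm: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         max_iter: int = 300, seed: int = 0, tol: float = 1e-7) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1 (SMACOF with isotonic
    regression); best configuration over ``n_restarts`` random starts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    model = MDS(n_components=k, metric=False, dissimilarity="precomputed",
                n_init=n_restarts, max_iter=max_iter, eps=tol,
                random_state=seed, normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(dm.data)
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn("NMDS did not converge; returning best configuration")
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return Ordination(coords=pd.DataFrame(coords, index=dm.ids, columns=cols),
                      stress=float(model.stress_), converged=converged,
                      n_restarts=n_restarts)
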