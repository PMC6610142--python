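"""Discriminant-genus analysis.

Univariate screening combines a Fisher exact test on presence/absence
with a Mann-Whitney U test on relative abundances, each family of tests
BH-adjusted separately; a genus counts as significant when either
adjusted p-value clears alpha. Multivariate ranking uses PLS-DA (NIPALS
against a one-hot class matrix), its sparse variant with soft-thresholded
loading weights under cross-validated ROC-AUC, and sparse k-means with
lasso-constrained feature weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

PSEUDO_ABUNDANCE = 1e-6  # keeps log fold changes finite for exclusive genera


# ---------------------------------------------------------------------------
# univariate tests

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small tie-free
    samples (n_x + n_y <= 20), otherwise the normal approximation with tie
    and continuity corrections. Returns (U of the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding the observed table's); a zero margin yields p = 1."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment:
    p_adj(i) = min_{j >= i} (m/j) p(j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per-genus statistics
    alpha: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def differential_genera(genus_relabund: pd.DataFrame, labels: pd.Series,
                        alpha: float = 0.05) -> DifferentialResult:
    """Per-genus Fisher (presence/absence) + Mann-Whitney (abundance)
    screening between two community types, BH-adjusted per test family."""
    lab = labels.reindex(genus_relabund.index)
    groups = sorted(pd.unique(lab.dropna()))
    if len(groups) != 2:
        raise ValueError("exactly two community types required")
    m1 = (lab == groups[0]).to_numpy()
    m2 = (lab == groups[1]).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each community needs at least 3 samples")
    rows = {}
    for genus in genus_relabund.columns:
        v = genus_relabund[genus].to_numpy(dtype=float)
        x, y = v[m1], v[m2]
        pres1, pres2 = int((x > 0).sum()), int((y > 0).sum())
        if np.ptp(v) == 0:  # constant genus: nothing to test
            p_mw = p_fi = 1.0
            lfc = 0.0
        else:
            _, p_mw = mann_whitney_u(x, y)
            p_fi = fisher_exact_2x2([[pres1, len(x) - pres1],
                                     [pres2, len(y) - pres2]])
            lfc = float(np.log((x.mean() + PSEUDO_ABUNDANCE)
                               / (y.mean() + PSEUDO_ABUNDANCE)))
        exclusive = ""
        if pres1 > 0 and pres2 == 0:
            exclusive = str(groups[0])
        elif pres2 > 0 and pres1 == 0:
            exclusive = str(groups[1])
        rows[genus] = {"lfc": lfc, "p_mw": p_mw, "p_fisher": p_fi,
                       "prevalence_1": pres1 / m1.sum(),
                       "prevalence_2": pres2 / m2.sum(),
                       "exclusive_to": exclusive}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["q_mw"] = bh_adjust(table["p_mw"].to_numpy())
    table["q_fisher"] = bh_adjust(table["p_fisher"].to_numpy())
    table["significant"] = (table["q_mw"] < alpha) | (table["q_fisher"] < alpha)
    return DifferentialResult(table, alpha)


# ---------------------------------------------------------------------------
# PLS-DA

def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so that exactly ``keep`` entries stay nonzero
    (mixOmics-style cardinality constraint)."""
    if keep >= len(w):
        return w
    absw = np.abs(w)
    lam = np.sort(absw)[len(w) - keep - 1]
    return np.sign(w) * np.maximum(absw - lam, 0.0)


@dataclass
class PlsdaModel:
    weights: pd.DataFrame     # genus x component loading weights
    loadings: pd.DataFrame    # genus x component X-loadings (p vectors)
    scores: pd.DataFrame      # sample x component
    class_weights: np.ndarray
    classes: list
    ranking: list[str]        # genera by decreasing max |weight|
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray

    def decision_scores(self, x_new: pd.DataFrame) -> np.ndarray:
        """Continuous score for the second class (one-vs-rest column)."""
        xc = (x_new[self.weights.index].to_numpy(dtype=float)
              - self.x_mean) / self.x_scale
        w = self.weights.to_numpy()
        p = self.loadings.to_numpy()
        b = w @ np.linalg.pinv(p.T @ w) @ self.class_weights  # (p, 2)
        return (xc @ b + self.y_mean)[:, -1]


def plsda_fit(x: pd.DataFrame, labels: pd.Series, n_components: int = 2,
              scale: bool = True, keep: int | None = None) -> PlsdaModel:
    """PLS-DA by NIPALS against the one-hot class matrix, with deflation
    after each component; ``keep`` soft-thresholds each component's
    loading-weight vector to that many genera (sparse PLS-DA)."""
    lab = labels.reindex(x.index)
    classes = sorted(pd.unique(lab))
    if len(classes) != 2:
        raise ValueError("two classes required")
    y = np.column_stack([(lab == c).to_numpy(float) for c in classes])
    xm = x.to_numpy(dtype=float)
    x_mean = xm.mean(axis=0)
    sd = xm.std(axis=0, ddof=1)
    x_scale = np.where(sd > 0, sd, 1.0) if scale else np.ones_like(sd)
    e = (xm - x_mean) / x_scale
    y_mean = y.mean(axis=0)
    f = y - y_mean
    max_rank = int(np.linalg.matrix_rank(e))
    if n_components > max_rank:
        warnings.warn(f"n_components truncated to rank {max_rank}")
        n_components = max_rank
    ws, ps, ts, cs = [], [], [], []
    for _ in range(n_components):
        u = f[:, [0]]
        w = np.zeros((e.shape[1], 1))
        for _ in range(500):
            w_new = e.T @ u
            if keep is not None:
                w_new = _soft_threshold_keep(w_new.ravel(), keep)[:, None]
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new = w_new / norm
            t = e @ w_new
            c = f.T @ t / (t.T @ t)
            u_new = f @ c / (c.T @ c)
            done = np.linalg.norm(w_new - w) < 1e-10
            w, u = w_new, u_new
            if done:
                break
        t = e @ w
        p = e.T @ t / (t.T @ t)
        c = f.T @ t / (t.T @ t)
        e = e - t @ p.T
        f = f - t @ c.T
        ws.append(w.ravel())
        ps.append(p.ravel())
        ts.append(t.ravel())
        cs.append(c.ravel())
    comp = [f"comp{i + 1}" for i in range(n_components)]
    weights = pd.DataFrame(np.column_stack(ws), index=x.columns, columns=comp)
    max_abs = weights.abs().max(axis=1)
    ranking = list(max_abs.sort_values(ascending=False, kind="stable").index)
    return PlsdaModel(weights=weights,
                      loadings=pd.DataFrame(np.column_stack(ps), index=x.columns,
                                            columns=comp),
                      scores=pd.DataFrame(np.column_stack(ts), index=x.index,
                                          columns=comp),
                      class_weights=np.column_stack(cs).T,
                      classes=classes, ranking=ranking,
                      x_mean=x_mean, x_scale=x_scale, y_mean=y_mean)


@dataclass
class SparseSelection:
    selected: list[str]
    sparsity: int
    cv_auc: float
    auc_by_sparsity: dict[int, float]


def sparse_plsda_cv(x: pd.DataFrame, labels: pd.Series,
                    sparsity_grid=(1, 2, 3, 5, 7, 10, 15, 20),
                    n_components: int = 2, folds: int = 10, seed: int = 0,
                    tolerance: float = 0.01) -> SparseSelection:
    """Pick the smallest per-component genus count whose stratified-CV
    ROC-AUC is within ``tolerance`` of the best over the sparsity grid;
    the returned set is the union of nonzero-weight genera of the
    full-data sparse fit at that sparsity."""
    lab = labels.reindex(x.index)
    classes = sorted(pd.unique(lab))
    y_true = (lab == classes[-1]).to_numpy(int)
    min_class = min((lab == c).sum() for c in classes)
    if folds > min_class:
        warnings.warn(f"folds reduced to smallest class size {min_class}")
        folds = int(min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs: dict[int, float] = {}
    for s in sparsity_grid:
        pred = np.zeros(len(lab))
        for tr, te in skf.split(x, y_true):
            model = plsda_fit(x.iloc[tr], lab.iloc[tr],
                              n_components=n_components, keep=int(s))
            pred[te] = model.decision_scores(x.iloc[te])
        aucs[int(s)] = float(roc_auc_score(y_true, pred))
    best = max(aucs.values())
    chosen = min(s for s, a in aucs.items() if a >= best - tolerance)
    full = plsda_fit(x, lab, n_components=n_components, keep=chosen)
    nonzero = full.weights.abs().max(axis=1) > 0
    return SparseSelection(selected=list(full.weights.index[nonzero]),
                           sparsity=chosen, cv_auc=aucs[chosen],
                           auc_by_sparsity=aucs)


# ---------------------------------------------------------------------------
# sparse k-means (lasso-weighted features, Witten-Tibshirani scheme)

@dataclass
class SparseKMeansResult:
    labels: pd.Series
    weights: pd.Series   # feasible: ||w||_2 <= 1, ||w||_1 <= l1_bound
    n_iter: int
    converged: bool

    @property
    def weights_sum1(self) -> pd.Series:
        return self.weights / self.weights.sum()


def _bcss(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature between-cluster sum of squares."""
    total = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
    within = np.zeros(x.shape[1])
    for g in np.unique(labels):
        xg = x[labels == g]
        within += ((xg - xg.mean(axis=0)) ** 2).sum(axis=0)
    return total - within


def _lasso_weights(a: np.ndarray, l1_bound: float) -> np.ndarray:
    """argmax w.a subject to ||w||_2 <= 1, ||w||_1 <= l1_bound, w >= 0,
    solved by soft-thresholding with a bisection on the threshold."""
    a = np.maximum(a, 0.0)
    if a.max() == 0:
        return np.ones_like(a) / np.sqrt(len(a))

    def w_of(delta):
        w = np.maximum(a - delta, 0.0)
        n = np.linalg.norm(w)
        return w / n if n > 0 else w

    if np.abs(w_of(0.0)).sum() <= l1_bound:
        return w_of(0.0)
    lo, hi = 0.0, a.max()
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.abs(w_of(mid)).sum() > l1_bound:
            lo = mid
        else:
            hi = mid
    return w_of(hi)


def _sparse_kmeans_once(xm: np.ndarray, k: int, l1_bound: float,
                        w0: np.ndarray, seed: int, max_iter: int):
    w = w0
    labels = None
    converged = False
    for it in range(1, max_iter + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(xm * np.sqrt(w))
        w_new = _lasso_weights(_bcss(xm, labels), l1_bound)
        if np.abs(w_new - w).sum() / max(np.abs(w).sum(), 1e-12) < 1e-4:
            w = w_new
            converged = True
            break
        w = w_new
    objective = float(w @ _bcss(xm, labels))
    return labels, w, it, converged, objective


def sparse_kmeans(x: pd.DataFrame, k: int, l1_bound: float, seed: int = 0,
                  max_iter: int = 30, standardize: bool = True,
                  n_restarts: int = 10) -> SparseKMeansResult:
    """Alternate k-means on weight-scaled features with lasso-constrained
    weight updates maximizing the weighted between-cluster sum of squares.

    When only a small fraction of features carries cluster structure, the
    uniform-weight start can lock onto a noise partition; the procedure is
    therefore restarted from random sparse weight vectors (first restart
    uniform) and the run with the highest weighted between-cluster sum of
    squares is returned.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if l1_bound < 1:
        raise ValueError("l1_bound must be >= 1")
    xm = x.to_numpy(dtype=float)
    if standardize:
        sd = xm.std(axis=0, ddof=0)
        xm = (xm - xm.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    p = xm.shape[1]
    rng = np.random.default_rng(seed)
    subset = min(p, max(3, int(np.ceil(l1_bound ** 2))))
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            w0 = np.ones(p) / np.sqrt(p)
        else:
            w0 = np.zeros(p)
            w0[rng.choice(p, size=subset, replace=False)] = 1 / np.sqrt(subset)
        run = _sparse_kmeans_once(xm, k, l1_bound, w0, seed, max_iter)
        if best is None or run[-1] > best[-1]:
            best = run
    labels, w, it, converged, _ = best
    return SparseKMeansResult(
        labels=pd.Series(labels + 1, index=x.index, name="cluster"),
        weights=pd.Series(w, index=x.columns, name="weight"),
        n_iter=it, converged=converged)
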