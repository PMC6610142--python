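"""Community typing: PAM (k-medoids) with silhouette-based selection of
the number of community types, cross-distance concordance, and the
top-k genus-deletion robustness procedure.

PAM is run as classic BUILD + SWAP on a precomputed distance matrix; the
number of clusters is chosen by maximizing the silhouette coefficient
(mean silhouette width), with SC > 0.5 read as "reasonable structure".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .beta import DistanceMatrix, distance_matrix


@dataclass
class CommunityTypes:
    labels: pd.Series          # 1..K per sample
    k: int
    medoids: list[str]
    silhouette_widths: pd.Series
    silhouette_coefficient: float
    metric: str
    reasonable_structure: bool | None = None


@dataclass
class RobustnessProfile:
    """Misclassification and silhouette after deleting the top-k ranked
    genera, for k on a grid starting at 0 (reference partition)."""
    table: pd.DataFrame  # columns: k, misclassified, silhouette


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam(dm: DistanceMatrix, k: int) -> CommunityTypes:
    """Partitioning around medoids.

    BUILD seeds the medoids greedily, SWAP exchanges (medoid, non-medoid)
    pairs while the total dissimilarity to the nearest medoid strictly
    decreases. Ties are broken by the lowest candidate index, making the
    result deterministic in the distance matrix alone.
    """
    d = dm.data
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError("need 2 <= K < n samples")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP
    best_cost = _pam_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(sorted(medoids)):
            others = [x for x in medoids if x != m]
            for h in range(n):
                if h in medoids:
                    continue
                cost = _pam_cost(d, others + [h])
                if cost < best_cost - 1e-12:
                    if best_swap is None or cost < best_swap[0] - 1e-12:
                        best_swap = (cost, m, h)
        if best_swap is not None:
            best_cost, m, h = best_swap
            medoids = [x for x in medoids if x != m] + [h]
            improved = True

    medoids = sorted(medoids)
    assign = np.argmin(d[:, medoids], axis=1)
    labels = pd.Series(assign + 1, index=dm.ids, name="community")
    widths, sc = silhouette(dm, labels)
    return CommunityTypes(labels=labels, k=k,
                          medoids=[dm.ids[m] for m in medoids],
                          silhouette_widths=widths,
                          silhouette_coefficient=sc, metric=dm.metric)


def silhouette(dm: DistanceMatrix, labels: pd.Series) -> tuple[pd.Series, float]:
    """Per-sample silhouette widths s(i) = (b-a)/max(a,b) on a precomputed
    distance matrix (singleton clusters score 0) and their mean (SC)."""
    lab = np.asarray(labels.reindex(dm.ids))
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    widths = silhouette_samples(dm.data, lab, metric="precomputed")
    s = pd.Series(widths, index=dm.ids, name="silhouette")
    return s, float(s.mean())


def select_k(dm: DistanceMatrix, k_max: int = 10) -> CommunityTypes:
    """PAM for K = 2..k_max; return the partition maximizing the
    silhouette coefficient, flagged reasonable when SC > 0.5."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, dm.shape[0] - 1)
    best = None
    for k in range(2, k_max + 1):
        cand = pam(dm, k)
        if best is None or cand.silhouette_coefficient > best.silhouette_coefficient:
            best = cand
    best.reasonable_structure = best.silhouette_coefficient > 0.5
    return best


def label_agreement(a: pd.Series, b: pd.Series) -> float:
    """Fraction of samples on which two partitions agree after optimal
    (Hungarian) label matching."""
    ids = a.index
    av = np.asarray(a)
    bv = np.asarray(b.reindex(ids))
    la, lb = np.unique(av), np.unique(bv)
    conf = np.zeros((len(la), len(lb)))
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            conf[i, j] = np.sum((av == x) & (bv == y))
    ri, ci = linear_sum_assignment(-conf)
    return float(conf[ri, ci].sum() / len(ids))


def concordance(partitions: list[CommunityTypes]) -> pd.DataFrame:
    """Pairwise adjusted Rand index and exact-match flag (after best label
    matching) across partitions of the same sample set."""
    ids = partitions[0].labels.index
    for p in partitions[1:]:
        if set(p.labels.index) != set(ids):
            raise ValueError("partitions cover different sample sets")
    rows = []
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            a, b = partitions[i], partitions[j]
            ari = adjusted_rand_score(np.asarray(a.labels),
                                      np.asarray(b.labels.reindex(ids)))
            exact = label_agreement(a.labels, b.labels) == 1.0
            rows.append({"a": a.metric, "b": b.metric,
                         "ari": float(ari), "exact_match": exact})
    return pd.DataFrame(rows)


def topk_deletion(genus_relabund: pd.DataFrame, reference: CommunityTypes,
                  ranking: list[str], k_max: int = 100) -> RobustnessProfile:
    """Delete the top-k ranked genera (k = 0..k_max), re-normalize rows,
    recompute Bray-Curtis, re-run PAM at the reference K and count samples
    misclassified against the reference partition."""
    n_genera = genus_relabund.shape[1]
    if k_max >= n_genera:
        warnings.warn(f"k_max {k_max} >= {n_genera} genera; truncating")
        k_max = n_genera - 1
    if len(ranking) < k_max:
        raise ValueError("ranking covers fewer genera than k_max")
    n = genus_relabund.shape[0]
    rows = []
    for k in range(0, k_max + 1):
        kept = genus_relabund.drop(columns=ranking[:k])
        kept = kept.div(kept.sum(axis=1), axis=0)
        dm = distance_matrix(kept, "braycurtis", level="genus")
        part = pam(dm, reference.k)
        agree = label_agreement(reference.labels, part.labels)
        rows.append({"k": k, "misclassified": int(round((1 - agree) * n)),
                     "silhouette": part.silhouette_coefficient})
    return RobustnessProfile(pd.DataFrame(rows))
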