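"""Genus co-occurrence networks with PCIT filtering.

PCIT (partial correlation + information theory) visits every trio of
genera, computes the three first-order partial correlations, and uses
their average ratio to the direct correlations as a data-driven
tolerance: an edge survives only if no third genus explains it. Surviving
correlations are further thresholded on |r| and the correlation p-value,
and scored for node-level topology with networkx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def pcit_filter(r: np.ndarray) -> np.ndarray:
    """Boolean mask of PCIT-significant entries of a correlation matrix.

    For each trio (x, y, z) the first-order partials
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) are
    computed for all three pairs and the trio tolerance is the mean of the
    three partial-to-direct ratios; the edge (x, y) is flagged
    non-significant if for some z both |r_xy| <= eps |r_xz| and
    |r_xy| <= eps |r_yz|. Trios containing a perfect correlation are
    skipped (partials undefined).
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if r.shape != (n, n) or np.abs(r - r.T).max() > 1e-10:
        raise ValueError("correlation matrix must be square and symmetric")
    if np.abs(np.diag(r) - 1.0).max() > 1e-10 or np.abs(r).max() > 1 + 1e-10:
        raise ValueError("need unit diagonal and |r| <= 1")
    mask = np.ones((n, n), dtype=bool)
    if n < 3:
        return mask

    # partials[c, i, j] = r_ij.c (first-order partial conditioning on c)
    partials = np.empty((n, n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in range(n):
            rc = r[:, c]
            denom = np.sqrt(np.maximum(
                (1 - rc[:, None] ** 2) * (1 - rc[None, :] ** 2), 0.0))
            partials[c] = (r - rc[:, None] * rc[None, :]) / denom

    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = r[:, z]
            p3 = partials[:, :, z]              # p3[c, i] = r_iz.c
            ratio_xy = partials[z] / r          # r_xy.z / r_xy
            ratio_xz = p3.T / rz[:, None]       # [x, y] -> r_xz.y / r_xz
            ratio_yz = p3 / rz[None, :]         # [x, y] -> r_yz.x / r_yz
            eps = (ratio_xy + ratio_xz + ratio_yz) / 3.0
            # trio valid only where every partial is defined
            valid = (np.isfinite(eps)
                     & (np.abs(rz)[:, None] < 1.0)
                     & (np.abs(rz)[None, :] < 1.0))
            cond = (valid
                    & (np.abs(r) <= eps * np.abs(rz)[:, None])
                    & (np.abs(r) <= eps * np.abs(rz)[None, :]))
            cond[z, :] = cond[:, z] = False
            np.fill_diagonal(cond, False)
            mask &= ~(cond | cond.T)
    np.fill_diagonal(mask, True)
    return mask


@dataclass
class GenusNetwork:
    graph: nx.Graph                 # nodes carry abundance/phylum, edges r/strong
    correlations: pd.DataFrame      # retained-genus correlation matrix
    pcit_mask: pd.DataFrame
    r_cut: float
    strong_cut: float = 0.60

    @property
    def edges(self) -> pd.DataFrame:
        rows = [{"genus_a": a, "genus_b": b, "r": d["r"], "strong": d["strong"]}
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["genus_a", "genus_b", "r", "strong"])


def build_network(genus_relabund: pd.DataFrame,
                  phylum_map: dict[str, str] | None = None,
                  min_mean_abund: float = 0.001, r_cut: float = 0.35,
                  p_cut: float = 0.05, strong_cut: float = 0.60) -> GenusNetwork:
    """Co-occurrence network for one community type.

    Genera under ``min_mean_abund`` mean relative abundance (default 0.1%)
    are excluded; edges require PCIT significance, |r| >= ``r_cut`` and a
    two-sided correlation p-value <= ``p_cut``; |r| >= ``strong_cut``
    marks strong edges.
    """
    n = genus_relabund.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for stable correlations")
    mean_abund = genus_relabund.mean(axis=0)
    kept = genus_relabund.loc[:, mean_abund >= min_mean_abund]
    kept = kept.loc[:, kept.std(axis=0) > 0]
    genera = list(kept.columns)
    r = np.corrcoef(kept.to_numpy(dtype=float), rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    mask = pcit_filter(r)
    # two-sided t-test on n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)

    g = nx.Graph()
    for genus in genera:
        g.add_node(genus, mean_abundance=float(mean_abund[genus]),
                   phylum=(phylum_map or {}).get(genus, "unknown"))
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            if mask[i, j] and abs(r[i, j]) >= r_cut and p[i, j] <= p_cut:
                g.add_edge(genera[i], genera[j], r=float(r[i, j]),
                           sign=int(np.sign(r[i, j])),
                           strong=bool(abs(r[i, j]) >= strong_cut))
    rdf = pd.DataFrame(r, index=genera, columns=genera)
    mdf = pd.DataFrame(mask, index=genera, columns=genera)
    return GenusNetwork(graph=g, correlations=rdf, pcit_mask=mdf,
                        r_cut=r_cut, strong_cut=strong_cut)


def topology(network: GenusNetwork | nx.Graph) -> tuple[pd.DataFrame, float]:
    """Per-node degree, normalized betweenness centrality and clustering
    coefficient, plus the scale-free R^2: the squared correlation of
    log frequency vs log degree over observed degrees >= 1."""
    g = network.graph if isinstance(network, GenusNetwork) else network
    if g.number_of_edges() == 0:
        raise ValueError("empty network")
    degree = dict(g.degree())
    betw = nx.betweenness_centrality(g, normalized=True)
    clust = nx.clustering(g)
    nodes = pd.DataFrame({"degree": degree, "betweenness": betw,
                          "clustering": clust})
    degs = np.array([d for d in degree.values() if d >= 1])
    vals, counts = np.unique(degs, return_counts=True)
    if len(vals) < 2:
        warnings.warn("fewer than 2 distinct degrees; scale-free R^2 undefined")
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(np.log(vals), np.log(counts))[0, 1] ** 2)
    return nodes, r2
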