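"""Alpha diversity, rarefaction and the core microbiota.

Indices operate on rarefied counts (richness-type indices are depth
sensitive); rarefaction is subsampling without replacement via the
multivariate hypergeometric distribution. Pielou's evenness is undefined
for a single observed taxon and reported as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, to_relative_abundance


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without
    replacement; samples shallower than ``depth`` are dropped with a
    warning. Deterministic given ``seed``."""
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep = table.depths >= depth
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} sample(s) below depth {depth}")
    counts = table.counts.loc[keep]
    out = np.vstack([rng.multivariate_hypergeometric(row, depth)
                     for row in counts.to_numpy()])
    return OtuTable(pd.DataFrame(out, index=counts.index, columns=counts.columns),
                    table.taxonomy)


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1)), with F1/F2 the
    singleton and doubleton counts."""
    c = np.asarray(counts)
    if (c < 0).any() or not (c > 0).any():
        raise ValueError("counts must be non-negative with at least one taxon")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of the relative abundances."""
    c = np.asarray(counts, dtype=float)
    p = c[c > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(counts: np.ndarray) -> float:
    """J = H / ln(S); NaN when only one taxon is observed (0/0)."""
    c = np.asarray(counts, dtype=float)
    s = int((c > 0).sum())
    if s < 1:
        raise ValueError("needs at least one nonzero taxon")
    if s == 1:
        return float("nan")
    return shannon(c) / np.log(s)


def dominance_and_rarity(rel_abund: np.ndarray,
                         rarity_detection_threshold: float = 0.002
                         ) -> tuple[float, float]:
    """Dominance = relative abundance of the most abundant taxon; rarity =
    total relative abundance of taxa individually below the threshold
    (default 0.2%)."""
    p = np.asarray(rel_abund, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("relative abundances must sum to 1")
    dominance = float(p.max())
    rarity = float(p[(p > 0) & (p < rarity_detection_threshold)].sum())
    return dominance, rarity


@dataclass
class AlphaDiversityReport:
    table: pd.DataFrame  # per-sample indices
    rarefaction_depth: int | None
    seed: int | None


def alpha_diversity_report(table: OtuTable, rarefaction_depth: int | None = None,
                           seed: int = 0,
                           rarity_detection_threshold: float = 0.002
                           ) -> AlphaDiversityReport:
    """Per-sample observed richness, Chao1, Shannon, Pielou, dominance and
    rarity, computed on rarefied counts when a depth is given."""
    if rarefaction_depth is not None:
        table = rarefy(table, rarefaction_depth, seed)
    rel = to_relative_abundance(table)
    rows = {}
    for sid in table.sample_ids:
        c = table.counts.loc[sid].to_numpy()
        dom, rar = dominance_and_rarity(rel.loc[sid].to_numpy(),
                                        rarity_detection_threshold)
        rows[sid] = {
            "observed": int((c > 0).sum()),
            "chao1": chao1(c),
            "shannon": shannon(c),
            "pielou": pielou_evenness(c),
            "dominance": dom,
            "rarity": rar,
        }
    return AlphaDiversityReport(pd.DataFrame.from_dict(rows, orient="index"),
                                rarefaction_depth, seed)


def core_taxa(rel_abund: pd.DataFrame, detection: float = 1e-5,
              prevalence: float = 0.999) -> list[str]:
    """Taxa whose relative abundance exceeds ``detection`` in at least a
    ``prevalence`` fraction of samples (defaults 0.001% / 99.9%)."""
    for name, v in (("detection", detection), ("prevalence", prevalence)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    frac = (rel_abund > detection).mean(axis=0)
    return list(rel_abund.columns[frac >= prevalence])
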