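"""Synthetic endurance-cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
cohort of ~52 animals whose fecal microbiota falls into two latent
community types. OTU counts follow a Dirichlet-multinomial with
community-specific concentration vectors; a configurable number of
discriminant genera are multiplicatively shifted between communities by
``exp(±effect_size)`` and a further set of genera is exclusive to one
community. Sequencing depth is log-normal. Host variables (age, sex,
breed) are community-independent by default while race elimination, diet
intakes, fecal SCFA proportions and a handful of blood metabolite bins
carry community-linked shifts.

Each genus owns a contiguous clade of tips in the simulated phylogeny so
that genus-level abundance shifts are visible to UniFrac.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .io import OtuTable

SCFA_NAMES = ("acetate", "propionate", "butyrate", "iso_butyrate",
              "valerate", "iso_valerate")

# Dirichlet concentrations for fecal SCFA proportions: community 1 skews
# toward acetate, community 2 toward propionate + butyrate.
_SCFA_ALPHA = {
    1: np.array([210.0, 33.0, 21.0, 9.0, 15.0, 12.0]),
    2: np.array([180.0, 54.0, 36.0, 9.0, 12.0, 9.0]),
}

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")

# variable -> (community-1 spec, community-2 spec); a spec is
# ("normal", mean, sd) | ("bernoulli", p) | ("categorical", {level: prob}).
DEFAULT_METADATA_EFFECTS: dict[str, tuple] = {
    "age": (("normal", 9.3, 2.2), ("normal", 9.3, 2.2)),
    "sex": (("categorical", {"F": 0.4, "G": 0.45, "M": 0.15}),) * 2,
    "breed": (("categorical", {"AR": 0.55, "AA": 0.25, "CS": 0.2}),) * 2,
    "eliminated": (("bernoulli", 0.33), ("bernoulli", 0.16)),
    "top25": (("bernoulli", 0.27), ("bernoulli", 0.31)),
    "distance_km": (("categorical", {"90": 0.3, "120": 0.3, "160": 0.4}),) * 2,
    "speed_kmh": (("normal", 16.7, 1.68), ("normal", 17.2, 1.60)),
    "pulse_bpm": (("normal", 56.1, 3.57), ("normal", 54.5, 5.7)),
    "telomere_ratio": (("normal", 1.0, 0.15), ("normal", 1.0, 0.15)),
    "travel_hours": (("normal", 4.0, 2.0), ("normal", 4.0, 2.0)),
    "protein_intake_kg": (("normal", 0.90, 0.15), ("normal", 1.10, 0.15)),
    "fiber_intake_kg": (("normal", 2.80, 0.40), ("normal", 3.30, 0.40)),
    "ash_intake_kg": (("normal", 0.35, 0.06), ("normal", 0.42, 0.06)),
    "forage_intake_kg": (("normal", 7.0, 1.0), ("normal", 8.5, 1.0)),
    "ufc_intake": (("normal", 4.2, 0.6), ("normal", 4.8, 0.6)),
    "feces_ph": (("normal", 6.6, 0.3), ("normal", 6.5, 0.3)),
}


@dataclass
class SyntheticConfig:
    """Parameters of the generative model; defaults reproduce the cohort
    structure the analysis targets (51 animals split 15/36)."""

    n_samples: int = 51
    n_otus: int = 200
    n_genera: int = 60
    community_proportions: tuple[float, ...] = (15 / 51, 36 / 51)
    effect_size: float = 2.0
    n_discriminant_genera: int = 30
    n_exclusive_genera: int = 6
    depth_log_mean: float = float(np.log(5000.0))
    depth_log_sd: float = 0.3
    n_metabolite_bins: int = 120
    metadata_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_METADATA_EFFECTS))
    # None: exclusive genera alternate between communities; 1 or 2: that
    # community lacks all of them (and is therefore the sparser one)
    exclusive_absent_from: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_otus, self.n_genera) < 1:
            raise ValueError("counts must be >= 1")
        if abs(sum(self.community_proportions) - 1.0) > 1e-9:
            raise ValueError("community_proportions must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_discriminant_genera + self.n_exclusive_genera > self.n_genera:
            raise ValueError("discriminant + exclusive genera exceed n_genera")
        if self.n_otus < self.n_genera:
            raise ValueError("need at least one OTU per genus")


@dataclass
class SyntheticCohort:
    otu_table: OtuTable
    tree: TreeNode
    true_labels: pd.Series
    metadata: pd.DataFrame
    scfa: pd.DataFrame
    metabolite_bins: pd.DataFrame
    provenance: SyntheticConfig

    # Expected genus-level relative abundance per community, for
    # Monte-Carlo checks against the analytic Dirichlet mean.
    expected_genus_profiles: pd.DataFrame | None = None


def _random_join(subtrees: list[TreeNode], rng: np.random.Generator) -> TreeNode:
    """Join subtrees pairwise in random order into a rooted binary tree."""
    nodes = list(subtrees)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        left.length = float(rng.exponential(0.1) + 0.01)
        right.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_tree(n_otus: int, seed: int) -> TreeNode:
    """Random rooted binary tree with ``n_otus`` tips named ``otu0001``…

    Branch lengths are exponential(0.1) + 0.01, hence strictly positive;
    the topology and lengths are deterministic given ``seed``.
    """
    if n_otus < 2:
        raise ValueError("a rooted binary tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    tips = [TreeNode(name=f"otu{i + 1:04d}") for i in range(n_otus)]
    return _random_join(tips, rng)


def _genus_tree(otu_names: list[list[str]], rng: np.random.Generator) -> TreeNode:
    """Tree in which each genus' OTUs form a contiguous clade."""
    clades = []
    for names in otu_names:
        tips = [TreeNode(name=n) for n in names]
        clades.append(tips[0] if len(tips) == 1 else _random_join(tips, rng))
    if len(clades) == 1:
        return clades[0]
    tree = _random_join(clades, rng)
    for child in tree.traverse(include_self=False):
        if child.length is None:
            child.length = float(rng.exponential(0.1) + 0.01)
    return tree


def _partition(n_items: int, n_groups: int) -> list[int]:
    base, extra = divmod(n_items, n_groups)
    return [base + (1 if g < extra else 0) for g in range(n_groups)]


def _draw_variable(spec: tuple, n: int, rng: np.random.Generator):
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "bernoulli":
        return rng.random(n) < spec[1]
    if kind == "categorical":
        levels, probs = zip(*spec[1].items())
        return rng.choice(levels, size=n, p=np.asarray(probs) / sum(probs))
    raise ValueError(f"unknown distribution kind {kind!r}")


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw a complete synthetic cohort from ``config`` (see module docs)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- genus layout and taxonomy --------------------------------------
    sizes = _partition(cfg.n_otus, cfg.n_genera)
    genus_names, families, phyla = [], [], []
    for g in range(cfg.n_genera):
        fam = f"f{g + 1:03d}"
        # every 7th genus mirrors unclassified-family genus labels
        name = f"unclassified {fam}" if (g + 1) % 7 == 0 else f"g{g + 1:03d}"
        genus_names.append(name)
        families.append(fam)
        phyla.append(_PHYLA[g % len(_PHYLA)])
    otu_by_genus: list[list[str]] = []
    otu_ids, tax_rows = [], []
    k = 0
    for g, size in enumerate(sizes):
        names = [f"otu{k + i + 1:04d}" for i in range(size)]
        k += size
        otu_by_genus.append(names)
        for n in names:
            otu_ids.append(n)
            tax_rows.append((phyla[g], "c", "o", families[g], genus_names[g]))
    taxonomy = pd.DataFrame(tax_rows, index=otu_ids,
                            columns=["phylum", "class", "order", "family", "genus"])

    tree = _genus_tree(otu_by_genus, rng)

    # --- community-specific Dirichlet concentrations --------------------
    conc_total = 60.0  # overdispersion: smaller => noisier compositions
    base_w = rng.lognormal(0.0, 1.2, size=cfg.n_genera)
    base_alpha = conc_total * base_w / base_w.sum()

    roles = np.array(["shared"] * cfg.n_genera, dtype=object)
    special = rng.choice(cfg.n_genera,
                         size=cfg.n_discriminant_genera + cfg.n_exclusive_genera,
                         replace=False)
    disc_idx = special[:cfg.n_discriminant_genera]
    excl_idx = special[cfg.n_discriminant_genera:]
    roles[disc_idx] = "discriminant"
    roles[excl_idx] = "exclusive"

    alpha1, alpha2 = base_alpha.copy(), base_alpha.copy()
    for j, g in enumerate(disc_idx):  # alternate shift direction
        if j % 2 == 0:
            alpha1[g] *= np.exp(cfg.effect_size)
        else:
            alpha2[g] *= np.exp(cfg.effect_size)
    for j, g in enumerate(excl_idx):
        absent = cfg.exclusive_absent_from
        if absent is None:  # alternate the community losing each genus
            absent = 2 if j % 2 == 0 else 1
        if absent == 2:
            alpha2[g] = 0.0
        else:
            alpha1[g] = 0.0

    within = [rng.dirichlet(np.full(size, 2.0)) if size > 1 else np.ones(1)
              for size in sizes]

    def otu_alpha(genus_alpha: np.ndarray) -> np.ndarray:
        return np.concatenate([genus_alpha[g] * within[g]
                               for g in range(cfg.n_genera)])

    otu_alphas = {1: otu_alpha(alpha1), 2: otu_alpha(alpha2)}

    # --- sample labels, depths and counts -------------------------------
    n1 = int(round(cfg.n_samples * cfg.community_proportions[0]))
    labels = np.array([1] * n1 + [2] * (cfg.n_samples - n1))
    rng.shuffle(labels)
    sample_ids = [f"s{i + 1:03d}" for i in range(cfg.n_samples)]

    depths = np.maximum(
        rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd,
                      size=cfg.n_samples).round().astype(int), 100)
    counts = np.zeros((cfg.n_samples, cfg.n_otus), dtype=np.int64)
    for i in range(cfg.n_samples):
        a = otu_alphas[labels[i]]
        pos = a > 0
        p = np.zeros(cfg.n_otus)
        p[pos] = rng.dirichlet(a[pos])
        counts[i] = rng.multinomial(depths[i], p)

    otu_table = OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
                         taxonomy)
    true_labels = pd.Series(labels, index=sample_ids, name="community")

    # --- metadata --------------------------------------------------------
    meta = pd.DataFrame(index=sample_ids)
    for var, (spec1, spec2) in cfg.metadata_effects.items():
        col = np.empty(cfg.n_samples, dtype=object)
        for comm, spec in ((1, spec1), (2, spec2)):
            mask = labels == comm
            col[mask] = _draw_variable(spec, int(mask.sum()), rng)
        meta[var] = col
    for var in meta.columns:  # tidy dtypes
        kind = cfg.metadata_effects[var][0][0]
        if kind == "normal":
            meta[var] = meta[var].astype(float)
        elif kind == "bernoulli":
            meta[var] = meta[var].astype(bool)

    # stable/trainer/breeding ids, community-independent
    for var, n_levels in (("stable", 8), ("trainer", 10), ("breeding", 6)):
        meta[var] = rng.integers(1, n_levels + 1, size=cfg.n_samples)
        meta[var] = var[0].upper() + meta[var].astype(str)

    # --- SCFA proportions -------------------------------------------------
    scfa = np.zeros((cfg.n_samples, len(SCFA_NAMES)))
    for i in range(cfg.n_samples):
        scfa[i] = rng.dirichlet(_SCFA_ALPHA[labels[i]])
    scfa = pd.DataFrame(scfa, index=sample_ids, columns=SCFA_NAMES)

    # --- metabolite bins: low-rank structure + log-normal noise ----------
    n_bins = cfg.n_metabolite_bins
    scores = rng.normal(size=(cfg.n_samples, 2))
    loadings = rng.normal(scale=0.3, size=(2, n_bins))
    base_log = rng.normal(2.0, 0.5, size=n_bins)
    log_int = base_log + scores @ loadings + rng.normal(scale=0.2,
                                                        size=(cfg.n_samples, n_bins))
    # alanine/valine-proxy bins elevated in community 1
    shifted = [10, 11, 12, 13]
    shift = np.zeros((cfg.n_samples, n_bins))
    shift[np.ix_(labels == 1, shifted)] = 0.5
    bins = np.exp(log_int + shift)
    bin_names = [f"bin{b + 1:04d}" for b in range(n_bins)]
    bin_names[10], bin_names[11] = "alanine", "valine"
    bin_names[12], bin_names[13] = "choline", "isoleucine"
    metabolite_bins = pd.DataFrame(bins, index=sample_ids, columns=bin_names)

    # --- analytic genus-level Dirichlet means for MC checks --------------
    with np.errstate(invalid="ignore"):
        prof = pd.DataFrame(
            {1: alpha1 / alpha1.sum(), 2: alpha2 / alpha2.sum()},
            index=genus_names)
    prof["role"] = roles

    return SyntheticCohort(otu_table=otu_table, tree=tree,
                           true_labels=true_labels, metadata=meta, scfa=scfa,
                           metabolite_bins=metabolite_bins, provenance=cfg,
                           expected_genus_profiles=prof)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write all cohort tables as TSV, the tree as Newick and the config
    as YAML next to them."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.otu_table.counts.to_csv(out / "otu_counts.tsv", sep="\t")
    cohort.otu_table.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
    buf = _io.StringIO()
    cohort.tree.write(buf)
    (out / "tree.nwk").write_text(buf.getvalue())
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    cohort.scfa.to_csv(out / "scfa.tsv", sep="\t")
    cohort.metabolite_bins.to_csv(out / "metabolite_bins.tsv", sep="\t")
    cohort.true_labels.to_csv(out / "true_labels.tsv", sep="\t")
    cfg = asdict(cohort.provenance)
    cfg["community_proportions"] = list(cfg["community_proportions"])
    cfg["metadata_effects"] = {k: json.loads(json.dumps(v))
                               for k, v in cfg["metadata_effects"].items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
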