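"""Readers, writers and the core abundance-table container.

All on-disk matrices are plain TSV with samples as rows. Taxonomy is a
two-column (or multi-rank) TSV mapping OTU ids to lineages. Trees are
Newick. Unclassified genus-level taxa carry labels of the form
``"unclassified <family>"`` so they can participate in genus tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")


class FormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) plus a taxonomy lineage map.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, rows indexed by sample id, columns by
        OTU id. Row and column ids must be unique.
    taxonomy : pandas.DataFrame
        One row per OTU, columns a subset of ``RANKS``; OTUs missing from
        the map are assigned fully unclassified lineages.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise FormatError("duplicate sample or OTU ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric counts")
        if (arr < 0).any():
            raise FormatError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("non-integer counts")
        self.counts = c.astype(np.int64)
        if self.taxonomy.empty:
            self.taxonomy = pd.DataFrame(index=c.columns, columns=list(RANKS))
        extra = self.taxonomy.index.difference(c.columns)
        if len(extra):
            warnings.warn(f"{len(extra)} taxonomy entries have no matching OTU")
            self.taxonomy = self.taxonomy.loc[self.taxonomy.index.intersection(c.columns)]
        missing = c.columns.difference(self.taxonomy.index)
        if len(missing):
            warnings.warn(f"{len(missing)} OTUs missing from taxonomy; set to unclassified")
            pad = pd.DataFrame("unclassified", index=missing, columns=self.taxonomy.columns)
            self.taxonomy = pd.concat([self.taxonomy, pad]).loc[c.columns]
        else:
            self.taxonomy = self.taxonomy.loc[c.columns]

    # -- basic views ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def genus_table(self) -> pd.DataFrame:
        """Collapse OTU counts to genus level by summing OTUs that share a
        genus label (``"unclassified <family>"`` counts as a genus)."""
        genus = self.taxonomy["genus"].fillna("unclassified")
        return self.counts.T.groupby(genus.values).sum().T

    def genus_phylum_map(self) -> dict[str, str]:
        tax = self.taxonomy
        out: dict[str, str] = {}
        for otu in tax.index:
            out.setdefault(str(tax.loc[otu, "genus"]), str(tax.loc[otu, "phylum"]))
        return out


def to_relative_abundance(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's counts by its total depth.

    Zero-depth samples cannot be normalized; they are dropped with a
    warning. Every retained row sums to 1 (to within 1e-9).
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    depths = counts.sum(axis=1)
    empty = depths == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} zero-depth sample(s): "
                      f"{list(counts.index[empty])}")
        counts = counts.loc[~empty]
        depths = depths.loc[~empty]
    return counts.div(depths, axis=0)


def read_otu_table(path: str | Path, taxonomy_path: str | Path | None = None) -> OtuTable:
    """Read a samples-x-OTUs count TSV (first column = sample id) and an
    optional taxonomy TSV (first column = OTU id, remaining columns ranks)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = pd.DataFrame()
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy.columns = [c.lower() for c in taxonomy.columns]
    try:
        return OtuTable(counts, taxonomy)
    except FormatError:
        raise
    except ValueError as exc:  # e.g. unparseable cells
        raise FormatError(str(exc)) from exc


def write_otu_table(table: OtuTable, path: str | Path,
                    taxonomy_path: str | Path | None = None) -> None:
    table.counts.to_csv(path, sep="\t")
    if taxonomy_path is not None:
        table.taxonomy.to_csv(taxonomy_path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-sample metadata TSV; empty cells stay NaN (pairwise deletion is
    the caller's responsibility — nothing is imputed here)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t")
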