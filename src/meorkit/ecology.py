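"""Community-composition metrics on OTU count tables.

Amplicon pipelines summarize 16S communities as OTU-by-sample count tables
with a taxonomy lookup per OTU.  This module covers the downstream numeric
stages: Shannon diversity per sample, Bray-Curtis dissimilarity between
samples, UPGMA (average-linkage) clustering into an ultrametric dendrogram,
and collapsing counts to relative abundances at a taxonomic rank.

Shannon is computed in natural log by default (the mothur convention);
Bray-Curtis on relative abundances by default, since sequencing depth varies
between samples.  UPGMA tie-breaks are lexicographic on the smallest leaf id
in each cluster, so results are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "shannon_index",
    "bray_curtis",
    "bray_curtis_matrix",
    "upgma_tree",
    "aggregate_rank",
]

RANKS = ("phylum", "class", "genus")


@dataclass(frozen=True)
class OtuTable:
    """Integer counts, taxa as rows and samples as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if (df.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(df.values.dtype, np.integer):
            if not np.allclose(df.values, np.round(df.values)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
        col_sums = self.counts.sum(axis=0)
        empty = col_sums[col_sums == 0].index.tolist()
        if empty:
            raise ValueError(f"samples with zero total counts: {empty}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def relative(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OtuTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TaxonomyMap:
    """taxon id -> (phylum, class, genus) lineage labels."""

    lineages: Mapping[str, tuple[str, str, str]]

    def label(self, taxon: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}")
        lineage = self.lineages.get(taxon)
        if lineage is None:
            return "unclassified"
        return lineage[RANKS.index(rank)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"taxon_id", "phylum", "class", "genus"}
        if not required <= set(df.columns):
            raise ValueError(f"taxonomy file needs columns {sorted(required)}")
        # "class" is a keyword, so itertuples would mangle it; index by label
        return cls(
            {
                row["taxon_id"]: (row["phylum"], row["class"], row["genus"])
                for _, row in df.iterrows()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(t, *lin) for t, lin in self.lineages.items()],
            columns=["taxon_id", "phylum", "class", "genus"],
        ).to_csv(path, sep="\t", index=False)


def shannon_index(counts: Sequence[float] | np.ndarray, base: float = np.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def bray_curtis(
    a: Sequence[float], b: Sequence[float], relative: bool = True
) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum a + sum b).

    Computed on relative abundances by default (``relative=False`` for raw
    counts).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for empty samples")
    if relative:
        x = x / x.sum()
        y = y / y.sum()
    return float(_scipy_braycurtis(x, y))


def bray_curtis_matrix(table: OtuTable, relative: bool = True) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances as a validated symmetric matrix."""
    ids = table.samples
    n = len(ids)
    mat = np.zeros((n, n))
    cols = table.counts.values
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(cols[:, i], cols[:, j], relative)
    return DistanceMatrix(mat, ids)


def upgma_tree(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration into an ultrametric dendrogram.

    Cluster-to-cluster distance is the unweighted mean of all leaf-pair
    distances (maintained by the Lance-Williams update); a pair merges at
    height d/2.  Ties are broken by the lexicographically smallest pair of
    cluster leaf ids.  Returns a rooted tree with branch lengths; node
    heights are non-decreasing toward the root.
    """
    if isinstance(d, np.ndarray):
        d = DistanceMatrix(d)
    ids = list(d.ids)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    if np.isnan(d.data).any():
        raise ValueError("distance matrix contains NaN")

    dist: dict[frozenset, float] = {}
    clusters: dict[str, dict] = {
        i: {"node": TreeNode(name=i), "height": 0.0, "size": 1, "key": i}
        for i in ids
    }
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dist[frozenset((a, b))] = float(d[a, b])

    while len(clusters) > 1:
        # smallest distance; ties -> lexicographically smallest (key_a, key_b)
        best = min(
            (
                (dist[frozenset((a, b))], *sorted((clusters[a]["key"], clusters[b]["key"])), a, b)
                for i, a in enumerate(list(clusters))
                for b in list(clusters)[i + 1:]
            ),
        )
        dmin, _, _, a, b = best
        ca, cb = clusters.pop(a), clusters.pop(b)
        height = dmin / 2.0
        parent = TreeNode(children=[ca["node"], cb["node"]])
        ca["node"].length = height - ca["height"]
        cb["node"].length = height - cb["height"]
        new_id = f"({a},{b})"
        new_key = min(ca["key"], cb["key"])
        size = ca["size"] + cb["size"]
        for other in clusters:
            dao = dist.pop(frozenset((a, other)))
            dbo = dist.pop(frozenset((b, other)))
            dist[frozenset((new_id, other))] = (
                ca["size"] * dao + cb["size"] * dbo
            ) / size
        dist.pop(frozenset((a, b)))
        clusters[new_id] = {"node": parent, "height": height, "size": size, "key": new_key}

    root = next(iter(clusters.values()))["node"]
    root.length = None
    return root


def aggregate_rank(table: OtuTable, tax: TaxonomyMap, rank: str) -> pd.DataFrame:
    """Collapse an OTU table to per-sample relative abundances at a rank.

    OTUs without a taxonomy entry go to an ``unclassified`` bucket (with a
    warning).  Each sample column sums to 1.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    unmapped = [t for t in table.taxa if t not in tax.lineages]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} taxa without taxonomy routed to 'unclassified'"
        )
    labels = [tax.label(t, rank) for t in table.taxa]
    rel = table.relative()
    rel.index = pd.Index(labels, name=rank)
    return rel.groupby(level=0).sum()
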