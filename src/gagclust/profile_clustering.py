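"""Species profiles: presence/absence matrices, Jaccard distances, merging,
hierarchical clustering and partitioning.

Per enzyme family, a binary species x sequence-cluster matrix records which
species contributed at least one sequence to each cluster (presence, not
count).  Each matrix is turned into a species x species Jaccard distance
matrix; matrices from several families are merged by element-wise
(optionally weighted) averaging over a shared canonical species order, and
the merged matrix is clustered agglomeratively (UPGMA/average linkage by
default).  Cutting the dendrogram by undoing its last k-1 merges yields a
k-group species partition labeled C1..Ck in dendrogram leaf order.

Empty-profile convention: two species with all-zero profiles are at distance
0, an all-zero against a non-zero profile at distance 1 (Jaccard is 0/0
undefined; species lacking a family entirely must still be placeable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .family_clustering import FamilyClustering

__all__ = [
    "PresenceMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "Partition",
    "build_presence_matrix",
    "jaccard_distances",
    "merge_distance_matrices",
    "concat_presence_matrices",
    "hierarchical_cluster",
    "cut_dendrogram",
]

_LINKAGES = ("average", "complete", "single")


@dataclass
class PresenceMatrix:
    """Binary species x cluster matrix for one enzyme family.

    ``data`` is indexed by the canonical species order shared across
    families; columns are cluster ids in centroid discovery order.
    """

    family: str
    data: pd.DataFrame  # int8 0/1, index=species, columns=cluster ids

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class DistanceMatrix:
    """Symmetric species x species dissimilarity matrix with entries in [0, 1]."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


@dataclass
class Dendrogram:
    """Agglomerative clustering result: scipy linkage matrix plus leaf names."""

    species: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 linkage encoding
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.species[i] for i in sch.leaves_list(self.linkage_matrix)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.species)
        return str(tree).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


@dataclass
class Partition:
    """Mapping species -> cluster label (C1..Ck, numbered in leaf order)."""

    assignment: dict[str, str]

    @property
    def species(self) -> list[str]:
        return list(self.assignment)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def members(self, label: str) -> list[str]:
        return [s for s, l in self.assignment.items() if l == label]

    def restricted_to(self, species: Sequence[str]) -> "Partition":
        return Partition({s: self.assignment[s] for s in species})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tcluster\n")
            for s, l in self.assignment.items():
                fh.write(f"{s}\t{l}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def build_presence_matrix(
    clustering: FamilyClustering, canonical_species: Sequence[str]
) -> PresenceMatrix:
    """Binary species x cluster matrix from one family clustering.

    Species absent from the family get all-zero rows; a species with several
    paralogs in one cluster still scores a single 1.
    """
    canonical = list(canonical_species)
    if len(set(canonical)) != len(canonical):
        raise ValueError("canonical species list contains duplicates")
    known = set(canonical)
    seen = {m.species for c in clustering.clusters for m in c.members}
    offenders = sorted(seen - known)
    if offenders:
        raise ValueError(
            f"species in clustering missing from canonical list: {offenders}"
        )
    columns = [f"{clustering.family}:c{i + 1}" for i in range(clustering.n_clusters)]
    data = pd.DataFrame(0, index=canonical, columns=columns, dtype=np.int8)
    for col, cluster in zip(columns, clustering.clusters):
        for sp in cluster.species:
            data.loc[sp, col] = 1
    data.index.name = "species"
    return PresenceMatrix(family=clustering.family, data=data)


def jaccard_distances(matrix: PresenceMatrix) -> DistanceMatrix:
    """Species x species Jaccard distance matrix from one presence matrix."""
    X = matrix.data.to_numpy(dtype=bool)
    d = squareform(pdist(X, metric="jaccard"))
    return DistanceMatrix(species=matrix.species, values=d)


def merge_distance_matrices(
    matrices: Sequence[DistanceMatrix],
    weights: Sequence[float] | None = None,
) -> DistanceMatrix:
    """Element-wise (weighted) mean of per-family distance matrices."""
    if not matrices:
        raise ValueError("no distance matrices to merge")
    species = matrices[0].species
    for m in matrices[1:]:
        if m.species != species:
            raise ValueError("distance matrices disagree on species order")
    stack = np.stack([m.values for m in matrices])
    merged = np.average(stack, axis=0, weights=weights)
    return DistanceMatrix(species=list(species), values=merged)


def concat_presence_matrices(matrices: Sequence[PresenceMatrix]) -> PresenceMatrix:
    """Column-wise concatenation of per-family presence matrices.

    Supports the alternative merge mode in which one Jaccard distance is
    computed over the concatenated binary profiles instead of averaging
    per-family distances.
    """
    if not matrices:
        raise ValueError("no presence matrices to concatenate")
    species = matrices[0].species
    for m in matrices[1:]:
        if m.species != species:
            raise ValueError("presence matrices disagree on species order")
    data = pd.concat([m.data for m in matrices], axis=1)
    return PresenceMatrix(family="+".join(m.family for m in matrices), data=data)


def hierarchical_cluster(
    dist: DistanceMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of the species distance matrix.

    ``linkage`` is one of ``average`` (UPGMA, default), ``complete`` or
    ``single``.  Ward linkage is refused: it assumes squared Euclidean
    geometry, which Jaccard distances do not provide.
    """
    if linkage == "ward":
        raise ValueError(
            "ward linkage is ill-defined on Jaccard distances; "
            f"choose one of {_LINKAGES}"
        )
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose one of {_LINKAGES}")
    if len(dist.species) < 2:
        raise ValueError("hierarchical clustering requires at least 2 species")
    condensed = squareform(dist.values, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    return Dendrogram(species=list(dist.species), linkage_matrix=Z, method=linkage)


def cut_dendrogram(dendro: Dendrogram, k: int) -> Partition:
    """Cut into exactly k groups by undoing the last k-1 merges.

    Labels C1..Ck are assigned in dendrogram leaf order, so the labeling is
    reproducible across runs and platforms.
    """
    n = len(dendro.species)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # apply the first n-k merges; each linkage row i creates node n+i
    for i, (a, b, _h, _c) in enumerate(dendro.linkage_matrix[: n - k]):
        node = n + i
        parent[find(int(a))] = node
        parent[find(int(b))] = node

    label_of_root: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for leaf in dendro.leaf_order:
        root = find(dendro.species.index(leaf))
        if root not in label_of_root:
            label_of_root[root] = f"C{len(label_of_root) + 1}"
        assignment[leaf] = label_of_root[root]
    # report species in canonical input order
    return Partition({s: assignment[s] for s in dendro.species})
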