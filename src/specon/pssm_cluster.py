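"""Per-domain group-frequency PSSMs, the family master matrix, and clustering.

Each family member's ortholog alignment is condensed into a position-specific
scoring matrix: equivalency-group occurrence counts over the 60 canonical
positions, converted to per-position frequencies. Stacking the flattened
frequency rows of all members gives the family master matrix (28 x 360 with
the defaults), whose surface-restricted columns drive k-means partitions and
agglomerative dendrograms of the family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .alignment_io import Alignment, CanonicalMap
from .conservation import (
    DEFAULT_SCHEME,
    EquivalencyScheme,
    SurfaceDefinition,
)

__all__ = [
    "PSSM",
    "MasterMatrix",
    "ClusterResult",
    "build_pssm",
    "build_master_matrix",
    "subset_surface",
    "cluster_kmeans",
    "cluster_hierarchical",
    "linkage_to_newick",
]


@dataclass
class PSSM:
    """Equivalency-group occurrence counts/frequencies per canonical position.

    Rows are canonical positions 1..n_positions, columns the scheme's groups.
    Frequency rows sum to 1 where any residue was counted, 0 for all-gap
    positions (kept so column frames stay aligned across domains).
    """

    domain_name: str
    counts: pd.DataFrame
    scheme: EquivalencyScheme = DEFAULT_SCHEME

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        freq = self.counts.div(totals.where(totals > 0, 1), axis=0)
        freq[totals == 0] = 0.0
        return freq

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def flatten(self) -> pd.Series:
        """Position-major flattening: pos 1 groups 1..k, pos 2 groups 1..k, ..."""
        freq = self.frequencies
        data = {}
        for pos in freq.index:
            for group in freq.columns:
                data[f"{pos}:{group}"] = freq.at[pos, group]
        return pd.Series(data, name=self.domain_name)


def build_pssm(
    alignment: Alignment,
    cmap: CanonicalMap | None = None,
    scheme: EquivalencyScheme = DEFAULT_SCHEME,
    domain_name: str | None = None,
) -> PSSM:
    """Count equivalency-group occurrences at each canonical column.

    Insertion and flank columns are excluded; gaps and ambiguity letters are
    not counted anywhere.
    """
    if cmap is not None:
        if len(cmap.column_labels) != alignment.width:
            raise ValueError("canonical map inconsistent with alignment width")
        columns = cmap.canonical_columns
        numbers = [l.number for l in cmap.column_labels if l.is_canonical]
    else:
        columns = list(range(alignment.width))
        numbers = [i + 1 for i in columns]
    counts = np.zeros((len(columns), scheme.k), dtype=int)
    for out_row, col in enumerate(columns):
        for ch in alignment.column(col):
            g = scheme.group_of(ch)
            if g is not None:
                counts[out_row, g] += 1
    frame = pd.DataFrame(counts, index=numbers, columns=list(scheme.groups))
    name = domain_name or alignment.rows[0].id
    return PSSM(domain_name=name, counts=frame, scheme=scheme)


@dataclass
class MasterMatrix:
    """Family-wide matrix: one row per domain, 60 x k flattened frequencies."""

    data: pd.DataFrame  # index: domain names; columns: "<pos>:<group>"
    scheme: EquivalencyScheme = DEFAULT_SCHEME

    @property
    def domains(self) -> list[str]:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def build_master_matrix(pssms: Sequence[PSSM]) -> MasterMatrix:
    """Stack flattened PSSM frequency rows into the D x (positions*k) master
    matrix. All PSSMs must share the same scheme and position frame."""
    if not pssms:
        raise ValueError("need at least one PSSM")
    scheme = pssms[0].scheme
    frame0 = list(pssms[0].counts.index)
    for p in pssms[1:]:
        if p.scheme.groups != scheme.groups:
            raise ValueError("PSSMs built with different equivalency schemes")
        if list(p.counts.index) != frame0:
            raise ValueError("PSSMs built on different position frames")
    data = pd.DataFrame([p.flatten() for p in pssms])
    return MasterMatrix(data=data, scheme=scheme)


def subset_surface(master: MasterMatrix, surface: SurfaceDefinition) -> MasterMatrix:
    """Restrict the master matrix to one surface's position blocks.

    With the 6-group defaults SI keeps 9*6 = 54 columns, SII 13*6 = 78.
    """
    keep = [
        c for c in master.data.columns if int(c.split(":")[0]) in surface.positions
    ]
    if not keep:
        raise ValueError(f"surface {surface.name!r} selects no master-matrix columns")
    return MasterMatrix(data=master.data[keep], scheme=master.scheme)


@dataclass
class ClusterResult:
    """Outcome of clustering family members on a (surface-restricted) master
    matrix: a flat k-means partition and/or an agglomerative dendrogram."""

    surface_name: str
    method: str  # {"kmeans", "hierarchical"}
    labels: pd.Series | None = None
    k: int | None = None
    seed: int | None = None
    inertia: float | None = None
    linkage_matrix: np.ndarray | None = None
    newick: str | None = None
    cophenetic: pd.DataFrame | None = None


def cluster_kmeans(
    master: MasterMatrix,
    k: int = 4,
    seed: int = 0,
    n_init: int = 50,
    surface_name: str = "custom",
) -> ClusterResult:
    """k-means partition of the domains with multiple seeded restarts."""
    n = len(master.domains)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(master.values())
    return ClusterResult(
        surface_name=surface_name,
        method="kmeans",
        labels=pd.Series(labels, index=master.domains, name="cluster"),
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def cluster_hierarchical(
    master: MasterMatrix,
    linkage: str = "average",
    surface_name: str = "custom",
) -> ClusterResult:
    """Agglomerative dendrogram over the domains (Euclidean metric).

    The tree is exportable as a Newick string; the cophenetic distance table
    supports comparing overall family divergence between surfaces.
    """
    if len(master.domains) < 2:
        raise ValueError("hierarchical clustering needs at least 2 domains")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    values = master.values()
    Z = hierarchy.linkage(values, method=linkage, metric="euclidean")
    coph = squareform(hierarchy.cophenet(Z, pdist(values))[1])
    return ClusterResult(
        surface_name=surface_name,
        method="hierarchical",
        linkage_matrix=Z,
        newick=linkage_to_newick(Z, master.domains),
        cophenetic=pd.DataFrame(coph, index=master.domains, columns=master.domains),
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths
    equal to merge-height differences."""
    tree = hierarchy.to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = recurse(tree, tree.dist)
    # strip the root's zero-length branch
    body = body.rsplit(":", 1)[0]
    return body + ";"


def mean_pairwise_distance(master: MasterMatrix) -> float:
    """Mean Euclidean distance between all domain pairs."""
    return float(pdist(master.values()).mean())
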