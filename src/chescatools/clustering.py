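"""Agglomerative clustering of residues and states from correlation matrices.

Residues are clustered on the dissimilarity ``d = 1 - |r|`` (absolute value by
default, so strong anti-correlations — which also report on a shared
equilibrium — cluster together; a ``signed`` flag switches to ``1 - r``).
Single linkage merges clusters at the *minimum* inter-cluster distance, i.e.
one strong pairwise correlation suffices to join two groups, which is
exhaustive but prone to chaining artifacts.  Complete linkage merges at the
*maximum* distance, guaranteeing that every pair inside a reported cluster
correlates at or above the cutoff.

State dendrograms cluster the *columns* of **M** restricted to one residue
cluster; their deepest bipartition reveals whether the cluster tracks the
activation equilibrium (inhibited vs. active states) or mere ligand occupancy
(apo vs. bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform

from .ccs_core import CCSMatrix, CorrelationMatrix
from .exceptions import DegenerateInputError, MetadataError
from .shift_io import ACTIVE_CLASSES, INACTIVE_CLASSES, ActivityClass, StateMeta

__all__ = [
    "Dendrogram",
    "ClusterSet",
    "agglomerate",
    "cut_clusters",
    "chain_path",
    "state_dendrogram",
    "classify_cluster",
]

LINKAGES = ("single", "complete")


@dataclass
class Dendrogram:
    """Agglomerative merge tree on distance ``d = 1 - |r|``.

    ``merges`` is a scipy-format linkage matrix; row k merges nodes
    ``merges[k,0]`` and ``merges[k,1]`` at height ``merges[k,2]`` (nodes >= n
    index earlier merges).  ``leaves`` maps leaf indices to residue ids or
    state names.
    """

    merges: np.ndarray
    leaves: tuple
    linkage: str
    axis: str = "residues"

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        root = to_tree(self.merges)

        def fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.10g}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.10g}"

        if root.is_leaf():  # pragma: no cover - degenerate one-leaf tree
            return f"{self.leaves[root.id]};"
        inner = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


@dataclass
class ClusterSet:
    """Cutoff-derived residue clusters with linkage provenance."""

    clusters: tuple[frozenset, ...]
    cutoff: float
    linkage: str
    min_size: int

    def membership(self) -> dict:
        return {
            rid: cid
            for cid, members in enumerate(self.clusters, start=1)
            for rid in members
        }

    @property
    def residues(self) -> frozenset:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def __len__(self) -> int:
        return len(self.clusters)


def _distance_matrix(r: CorrelationMatrix, signed: bool) -> np.ndarray:
    vals = r.values.to_numpy(dtype=float)
    d = (1.0 - vals) if signed else (1.0 - np.abs(vals))
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def agglomerate(
    r: CorrelationMatrix, linkage: str = "single", signed: bool = False
) -> Dendrogram:
    """Merge tree over residues under single or complete linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = len(r.values)
    if n < 2:
        raise DegenerateInputError(f"clustering needs >= 2 residues, got {n}")
    d = _distance_matrix(r, signed)
    merges = scipy_linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(
        merges=merges, leaves=tuple(r.values.index), linkage=linkage
    )


def cut_clusters(
    dendrogram: Dendrogram, cutoff: float, min_size: int = 4
) -> ClusterSet:
    """Cut the tree at distance ``1 - cutoff`` and drop small clusters.

    ``cutoff`` is a correlation threshold in (0, 1]; ``min_size`` defaults to
    4 (clusters of more than three residues).
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    labels = fcluster(
        dendrogram.merges, t=(1.0 - cutoff) + 1e-12, criterion="distance"
    )
    groups: dict[int, set] = {}
    for leaf, lab in zip(dendrogram.leaves, labels):
        groups.setdefault(int(lab), set()).add(leaf)
    clusters = [frozenset(g) for g in groups.values() if len(g) >= min_size]
    clusters.sort(key=lambda c: min(c))
    return ClusterSet(
        clusters=tuple(clusters),
        cutoff=cutoff,
        linkage=dendrogram.linkage,
        min_size=min_size,
    )


def chain_path(
    r: CorrelationMatrix,
    cluster: Iterable,
    res_a,
    res_b,
    cutoff: float,
    signed: bool = False,
):
    """Chain of strong pairwise correlations linking two cluster members.

    Returns the shortest path from ``res_a`` to ``res_b`` in the graph whose
    edges are residue pairs with |r| >= cutoff (ties broken by maximal minimum
    edge correlation, then lexicographically), or ``None`` if the residues are
    not chained at this cutoff.  Such a path exists whenever both residues
    share a single-linkage cluster at the same cutoff.
    """
    cluster = set(cluster)
    if res_a not in cluster or res_b not in cluster:
        raise KeyError("both endpoint residues must belong to the cluster")
    vals = r.values
    g = nx.Graph()
    g.add_nodes_from(cluster)
    members = sorted(cluster)
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            rij = vals.at[u, v]
            score = rij if signed else abs(rij)
            if score >= cutoff:
                g.add_edge(u, v, strength=score)
    try:
        candidates = list(nx.all_shortest_paths(g, res_a, res_b))
    except nx.NetworkXNoPath:
        return None

    def bottleneck(path):
        return min(g.edges[u, v]["strength"] for u, v in zip(path, path[1:]))

    candidates.sort(key=lambda p: (-bottleneck(p), p))
    return candidates[0]


def state_dendrogram(m: CCSMatrix, cluster: Iterable) -> Dendrogram:
    """Complete-linkage tree over *states*, restricted to a residue cluster.

    Distances are ``1 - |r|`` with r the Pearson correlation between two
    state columns of **M** across the cluster's residues.  The columns are
    used uncentered: in the fast-exchange two-state model the residual
    dissimilarity then grows with the squared difference in activation
    fraction, so states group by functional similarity.  Requires >= 3
    residues in the cluster (state correlations over fewer observations are
    meaningless).
    """
    cluster = sorted(set(cluster))
    if len(cluster) < 3:
        raise DegenerateInputError(
            f"state dendrogram needs >= 3 cluster residues, got {len(cluster)}"
        )
    sub = m.values.loc[cluster]
    arr = sub.to_numpy(dtype=float)
    if (arr.std(axis=0) == 0).any():
        flat = [s for s, sd in zip(sub.columns, arr.std(axis=0)) if sd == 0]
        raise DegenerateInputError(
            f"state column(s) with zero variance over the cluster: {flat}"
        )
    r = np.clip(np.corrcoef(arr.T), -1.0, 1.0)
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    merges = scipy_linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(
        merges=merges, leaves=tuple(sub.columns), linkage="complete", axis="states"
    )


def _root_bipartition(dendro: Dendrogram) -> tuple[frozenset, frozenset]:
    root = to_tree(dendro.merges)
    left = frozenset(dendro.leaves[i] for i in root.left.pre_order())
    right = frozenset(dendro.leaves[i] for i in root.right.pre_order())
    return left, right


def classify_cluster(dendro: Dendrogram, states: Sequence[StateMeta]) -> str:
    """Functional label of a residue cluster from its state dendrogram.

    ``allosteric`` if the deepest split separates the inhibited states (apo,
    reverse agonists, antagonists) from the active ones (partial/full
    agonists); ``binding`` if it separates apo alone from every bound state;
    ``mixed`` otherwise.  When no reverse agonist or antagonist is present the
    two templates coincide and the allosteric label wins.
    """
    if dendro.axis != "states":
        raise ValueError("classify_cluster expects a state dendrogram")
    if dendro.n_leaves < 4:
        raise DegenerateInputError(
            f"classification needs >= 4 states, got {dendro.n_leaves}"
        )
    by_name = {s.state: s for s in states}
    missing = [name for name in dendro.leaves if name not in by_name]
    if missing:
        raise MetadataError(f"states without activity metadata: {missing}")
    inactive = frozenset(
        name
        for name in dendro.leaves
        if by_name[name].activity_class in INACTIVE_CLASSES
    )
    active = frozenset(dendro.leaves) - inactive
    apo_only = frozenset(
        name
        for name in dendro.leaves
        if by_name[name].activity_class is ActivityClass.APO
    )
    bound = frozenset(dendro.leaves) - apo_only
    split = frozenset(frozenset(side) for side in _root_bipartition(dendro))
    if inactive and active and split == frozenset({inactive, active}):
        return "allosteric"
    if apo_only and bound and split == frozenset({apo_only, bound}):
        return "binding"
    return "mixed"
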