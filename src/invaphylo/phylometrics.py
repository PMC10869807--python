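"""Phylogenetic distances and relatedness/diversity metrics.

All metrics are presence-based and built on patristic (cophenetic)
distances — the sum of branch lengths along the tree path between two tips:

* nonnative–native MPD: mean distance from a focal non-native species to
  all native species of a basin;
* nonnative–native MNTD: distance to the closest native relative;
* native MPD / MNTD: mean pairwise distance among the natives of a basin,
  and the mean distance of each native to its nearest native neighbour;
* the phylogenetic covariance matrix (shared root-to-MRCA path lengths),
  exposed for phylogenetically-correlated model residuals.

Trees are handled with dendropy; tip labels are normalised so underscores
and spaces are interchangeable.  Undefined values (a basin with no natives,
or fewer than two natives for community metrics) are returned as NaN, never
as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .occurrence_db import OccurrenceDatabase, normalize_species


class TreeError(ValueError):
    pass


def read_newick(path_or_string: str, *, from_string: bool = False) -> dendropy.Tree:
    """Parse a Newick tree and normalise its tip labels.

    Raises on duplicate tip labels (after normalisation) and on trees with
    fewer than two tips.
    """
    from dendropy.dataio.newickreader import NewickReader

    kwargs = {"schema": "newick", "preserve_underscores": True}
    try:
        if from_string:
            tree = dendropy.Tree.get(data=path_or_string, **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(path_or_string), **kwargs)
    except NewickReader.NewickReaderDuplicateTaxonError as err:
        raise TreeError(f"duplicate tip label: {err}") from err
    seen: set[str] = set()
    for taxon in tree.taxon_namespace:
        label = normalize_species(taxon.label)
        if label in seen:
            raise TreeError(f"duplicate tip label {label!r}")
        seen.add(label)
        taxon.label = label
    if len(seen) < 2:
        raise TreeError("tree must have at least 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError("negative branch length")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class DistanceMatrix:
    """Dense symmetric patristic distance matrix with label lookup."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, labels) -> np.ndarray:
        return np.array([self._index[l] for l in labels], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise path-length distances between all tips.

    Computed in one postorder sweep: at each internal node, tips in
    different child subtrees are at distance depth(i) + depth(j) − 2·depth(node).
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    idx = {lf: i for i, lf in enumerate(leaves)}
    tipdepth = np.array([depths[lf] for lf in leaves])
    n = len(leaves)
    out = np.zeros((n, n))
    subtree_tips: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            subtree_tips[node] = [idx[node]]
            continue
        children = [subtree_tips.pop(c) for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                dist = tipdepth[ia][:, None] + tipdepth[ib][None, :] - 2.0 * d
                out[ia[:, None], ib[None, :]] = dist
                out[ib[:, None], ia[None, :]] = dist.T
        merged = [i for ch in children for i in ch]
        subtree_tips[node] = merged
    return DistanceMatrix(labels=labels, values=out)


def phylo_covariance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Shared-path covariance matrix: C(i, j) = depth of mrca(i, j).

    Satisfies d(i, j) = C(i, i) + C(j, j) − 2 C(i, j) with the cophenetic
    distance d.  Requires a rooted tree.
    """
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise TreeError("tree has no root")
    if not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        raise TreeError("phylogenetic covariance requires a rooted tree")
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    idx = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    subtree_tips: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            C[idx[node], idx[node]] = depths[node]
            subtree_tips[node] = [idx[node]]
            continue
        children = [subtree_tips.pop(c) for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                C[ia[:, None], ib[None, :]] = d
                C[ib[:, None], ia[None, :]] = d
        subtree_tips[node] = [i for ch in children for i in ch]
    return pd.DataFrame(C, index=labels, columns=labels)


@dataclass(frozen=True)
class RelatednessPair:
    """Nonnative–native MPD and MNTD for one (species, basin)."""

    mpd: float
    mntd: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.mpd) or math.isnan(self.mntd))


@dataclass(frozen=True)
class CommunityDiversity:
    """Native richness and community phylogenetic diversity of a basin."""

    richness: int
    native_mpd: float
    native_mntd: float


def relatedness_to_natives(
    species: str, native_set, D: DistanceMatrix
) -> RelatednessPair:
    """MPD and MNTD from a focal species to a set of natives.

    An empty native set yields NaN for both metrics (the caller decides
    whether to drop the row); the focal species being in the native set is
    an error since a self-distance of zero would corrupt both metrics.
    """
    native_set = list(native_set)
    if species in native_set:
        raise ValueError(f"focal species {species!r} is in its own native set")
    if not native_set:
        return RelatednessPair(mpd=float("nan"), mntd=float("nan"))
    row = D.values[D.indices([species])[0], D.indices(native_set)]
    return RelatednessPair(mpd=float(row.mean()), mntd=float(row.min()))


def native_diversity(native_set, D: DistanceMatrix) -> CommunityDiversity:
    """Richness, native MPD (mean over unordered pairs) and native MNTD
    (mean nearest-neighbour distance).  Both NaN when richness < 2."""
    native_set = list(native_set)
    k = len(native_set)
    if k < 2:
        return CommunityDiversity(
            richness=k, native_mpd=float("nan"), native_mntd=float("nan")
        )
    ii = D.indices(native_set)
    sub = D.values[np.ix_(ii, ii)]
    iu = np.triu_indices(k, 1)
    mpd = float(sub[iu].mean())
    masked = sub + np.diag(np.full(k, np.inf))
    mntd = float(masked.min(axis=1).mean())
    return CommunityDiversity(richness=k, native_mpd=mpd, native_mntd=mntd)


def prune_to_database(
    tree: dendropy.Tree, db: OccurrenceDatabase
) -> tuple[dendropy.Tree, list[str]]:
    """Restrict the tree to species in the database; report absent species.

    Returns the pruned tree and the list of database species that are not
    tips of the tree (these must be dropped from downstream modeling, as
    their relatedness to natives cannot be computed).
    """
    db_species = db.species
    tree_species = set(tip_labels(tree))
    keep = db_species & tree_species
    dropped = sorted(db_species - tree_species)
    if len(keep) < 2:
        raise TreeError(
            "fewer than 2 database species present in the tree after pruning"
        )
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    return pruned, dropped
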