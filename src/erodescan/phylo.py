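"""Species trees and branch-length arithmetic.

The conservation and erosion statistics in this package all reduce to one
tree quantity: the branch length of the minimal (Steiner) subtree connecting
a set of leaves.  A :class:`PhyloTree` wraps a rooted dendropy tree and
precomputes, for every edge, the set of leaves below it, so that induced
subtree lengths can be evaluated quickly — including in batch over the
millions of alignment columns scored by the conservation profile.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "parse_newick"]


@dataclass
class PhyloTree:
    """Rooted species tree with branch lengths in substitutions/site.

    Parameters
    ----------
    leaves
        Leaf labels (species names), in a fixed order used by the batch API.
    edge_lengths
        Branch length of every edge (one per non-root node).
    edge_below
        For each edge, boolean mask over ``leaves`` marking the leaves in the
        subtree below that edge.
    """

    leaves: tuple[str, ...]
    edge_lengths: np.ndarray
    edge_below: np.ndarray  # (n_edges, n_leaves) bool
    newick: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf labels in tree")
        if np.any(self.edge_lengths < 0):
            raise ValueError("negative branch length in tree")
        self._index = {name: i for i, name in enumerate(self.leaves)}

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.leaves)

    def leaf_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"species {name!r} is not a leaf of the tree") from None

    def total_branch_length(self) -> float:
        """Sum of all branch lengths (substitutions/site)."""
        return float(self.edge_lengths.sum())

    def leaf_mask(self, names) -> np.ndarray:
        mask = np.zeros(len(self.leaves), dtype=bool)
        for name in names:
            mask[self.leaf_index(name)] = True
        return mask

    def induced_subtree_length(self, names) -> float:
        """Branch length of the minimal subtree spanning ``names``.

        An edge belongs to the spanning subtree iff it separates two members
        of the set, i.e. both the leaf set below the edge and its complement
        contain at least one selected leaf.  Returns 0.0 for sets of size
        ``<= 1``.
        """
        mask = self.leaf_mask(names)
        total = int(mask.sum())
        if total <= 1:
            return 0.0
        # count of selected leaves below each edge
        below = self.edge_below.astype(np.int32) @ mask.astype(np.int32)
        used = (below > 0) & (below < total)
        return float(self.edge_lengths[used].sum())

    def induced_length_batch(self, match: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`induced_subtree_length` over many leaf sets.

        Parameters
        ----------
        match
            Boolean array of shape ``(n_sets, n_leaves)`` with leaf columns in
            ``self.leaves`` order.

        Returns
        -------
        Array of shape ``(n_sets,)`` of induced subtree lengths.
        """
        match = np.asarray(match, dtype=bool)
        counts = match.sum(axis=1)
        below = match.astype(np.int32) @ self.edge_below.T.astype(np.int32)
        used = (below > 0) & (below < counts[:, None])
        return used @ self.edge_lengths


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string with branch lengths into a :class:`PhyloTree`.

    Every non-root edge must carry an explicit branch length; a missing
    length is an error rather than silently treated as zero.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed newick: {exc}") from exc

    leaves = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
    index = {name: i for i, name in enumerate(leaves)}
    lengths: list[float] = []
    below_masks: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"missing branch length on edge above {label!r}")
        mask = np.zeros(len(leaves), dtype=bool)
        for leaf in node.leaf_iter():
            mask[index[leaf.taxon.label]] = True
        lengths.append(float(node.edge.length))
        below_masks.append(mask)

    return PhyloTree(
        leaves=leaves,
        edge_lengths=np.asarray(lengths, dtype=float),
        edge_below=np.asarray(below_masks, dtype=bool),
        newick=text.strip(),
    )


def read_newick(path) -> PhyloTree:
    with io.open(path) as fh:
        return parse_newick(fh.read())
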