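"""Rooted trees, Brownian-motion covariance, and Pagel's λ rescaling.

The comparative machinery in :mod:`trianiche.signal` and
:mod:`trianiche.inference` is defined over a phylogenetic covariance
matrix ``C`` whose entries are shared root-to-MRCA path lengths: under
Brownian trait evolution the expected covariance of the trait values of
two tips is proportional to the time their lineages evolved together.
This module builds ``C`` from a rooted, branch-length-annotated tree and
implements the λ rescaling (off-diagonal shrinkage) used both for
maximum-likelihood signal estimation and for PGLS.

Newick parsing and serialization are delegated to :mod:`dendropy`; the
tree is wrapped in a thin validated container so every downstream
computation can rely on its invariants (unique non-empty tip labels,
finite non-negative branch lengths, at least two tips).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, TreeValidationError

logger = logging.getLogger("trianiche.phylo")

#: Relative tolerance for calling a tree ultrametric: the spread of
#: root-to-tip depths must not exceed this fraction of the max depth.
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class RootedTree:
    """A validated rooted tree with branch lengths in time units.

    Wraps a :class:`dendropy.Tree`; construct via :func:`parse_newick`
    or the simulators rather than directly.
    """

    _tree: dendropy.Tree
    tip_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree has an unlabelled tip")
            labels.append(leaf.taxon.label)
        if len(labels) < 2:
            raise TreeValidationError(f"tree needs >= 2 tips, got {len(labels)}")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge
                continue
            bl = edge.length
            if bl is None:
                raise TreeValidationError(
                    "missing branch length on a non-root edge "
                    "(configure default_branch_length to allow)"
                )
            if not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(f"invalid branch length {bl!r}")
        self.tip_labels = tuple(sorted(labels))

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def to_newick(self) -> str:
        """Serialize with branch lengths; round-trips through :func:`parse_newick`."""
        return (
            self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.distance_from_root()
        return depths

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(d.max() - d.min() <= rtol * max(d.max(), 1e-300))

    def prune_to(self, labels: Iterable[str]) -> "RootedTree":
        """Restriction to a tip subset (>= 2 labels), keeping path lengths."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeValidationError(f"labels not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return RootedTree(clone)


@dataclass(frozen=True)
class CovarianceMatrix:
    """Phylogenetic covariance ``C`` with its fixed tip order.

    ``matrix[i, j]`` is the depth of the MRCA of tips i and j (the
    root-to-tip path length on the diagonal), in the tree's time units.
    ``tip_order`` is lexicographic by label and is the species order used
    by every downstream computation.
    """

    matrix: np.ndarray
    tip_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.tip_order):
            raise ValueError("covariance matrix shape does not match tip order")

    def restrict(self, labels: Sequence[str]) -> "CovarianceMatrix":
        """Submatrix for a species subset, preserving lexicographic order.

        Restriction of C equals the covariance of the pruned tree, so
        per-trait missing species are handled here rather than by
        re-deriving trees.
        """
        keep = sorted(set(labels))
        idx = {l: i for i, l in enumerate(self.tip_order)}
        missing = [l for l in keep if l not in idx]
        if missing:
            raise KeyError(f"species not in covariance: {missing}")
        sel = np.array([idx[l] for l in keep])
        return CovarianceMatrix(self.matrix[np.ix_(sel, sel)], tuple(keep))


def parse_newick(text: str, default_branch_length: float | None = None) -> RootedTree:
    """Parse a single rooted newick description.

    Branch lengths are required on all non-root edges unless
    ``default_branch_length`` is given, in which case missing lengths are
    filled with it. Malformed input raises :class:`NewickParseError`
    naming the offending position; duplicate tip labels raise
    :class:`TreeValidationError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if default_branch_length is not None:
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None and edge.length is None:
                edge.length = default_branch_length
    return RootedTree(tree)


def brownian_covariance(tree: RootedTree) -> CovarianceMatrix:
    """Shared-path-length matrix ``C`` under Brownian motion.

    ``C[i, i]`` is the root-to-tip distance of tip i and ``C[i, j]`` the
    depth of MRCA(i, j). Tip order is lexicographic by label. The result
    is invariant to rotation/ladderization of the input newick.
    """
    order = tree.tip_labels
    idx = {l: i for i, l in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))

    dt = tree._tree
    # single postorder pass: each node carries its depth and tip-index set;
    # pairs of tips split across two child subtrees coalesce at this node.
    depth: dict[int, float] = {}
    tipsets: dict[int, np.ndarray] = {}
    for node in dt.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (0.0 if parent is None else depth[id(parent)]) + (
            node.edge.length or 0.0
        )
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            tipsets[id(node)] = np.array([i])
            C[i, i] = depth[id(node)]
            continue
        children = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                C[np.ix_(children[a], children[b])] = d
                C[np.ix_(children[b], children[a])] = d
        tipsets[id(node)] = np.concatenate(children)

    if not tree.is_ultrametric():
        logger.warning(
            "tree is not ultrametric (tip depth spread exceeds tolerance); "
            "analyses proceed but the dated-tree interpretation does not apply"
        )
    return CovarianceMatrix(C, order)


def lambda_transform(C: CovarianceMatrix, lam: float) -> CovarianceMatrix:
    """Pagel's λ rescaling: off-diagonals multiplied by λ, diagonal kept.

    λ = 1 returns the matrix unchanged (Brownian motion); λ = 0 removes
    all phylogenetic covariance (star phylogeny with the same tip
    variances). λ outside [0, 1] raises ``ValueError``.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    m = C.matrix * lam
    np.fill_diagonal(m, np.diag(C.matrix))
    return CovarianceMatrix(m, C.tip_order)


class TopologySet:
    """Ordered collection of rooted trees over an identical tip set.

    Used to propagate topological uncertainty: per-topology statistics
    are summarized as medians with 95% percentile intervals downstream.
    """

    def __init__(self, trees: Sequence[RootedTree]):
        if not trees:
            raise TreeValidationError("topology set must be non-empty")
        ref = set(trees[0].tip_labels)
        for k, t in enumerate(trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise TreeValidationError(
                    f"topology {k} has a different tip set from topology 0"
                )
        self.trees = list(trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> RootedTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self.trees[0].tip_labels

    @classmethod
    def from_newick_lines(cls, text: str) -> "TopologySet":
        """One newick per line; blank lines ignored."""
        trees = [parse_newick(line) for line in io.StringIO(text) if line.strip()]
        return cls(trees)

    def to_newick_lines(self) -> str:
        return "\n".join(t.to_newick() for t in self.trees) + "\n"
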