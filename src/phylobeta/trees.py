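"""Rooted phylogenetic trees with branch lengths.

:class:`PhyloTree` is a validated wrapper around a :class:`dendropy.Tree`
that provides the operations community-phylogenetic metrics need: patristic
(tip-to-tip path) distances, shared-depth (MRCA-depth) matrices, Pagel's
lambda transformation of internal node heights, and uniform random
resolution of polytomies.  :class:`PairwiseMatrix` is the labelled symmetric
matrix container used for every distance/similarity matrix in the package.
"""

from __future__ import annotations

import random
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix", "PhyloTree", "parse_newick"]

#: relative tolerance for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-9


class PairwiseMatrix:
    """A labelled symmetric matrix of distances or similarities.

    Parameters
    ----------
    labels : sequence of str
        Row/column labels, in order.
    values : (n, n) array-like
        Symmetric non-negative values.  The diagonal must be zero for
        ``orientation="dissimilarity"`` and one for
        ``orientation="similarity"``.
    orientation : {"dissimilarity", "similarity"}
    metric_name : str, optional
        Name of the quantity the matrix holds (e.g. ``"patristic"``).
    """

    def __init__(self, labels, values, orientation="dissimilarity", metric_name=""):
        labels = [str(l) for l in labels]
        values = np.asarray(values, dtype=float)
        if orientation not in ("dissimilarity", "similarity"):
            raise ValueError(f"unknown orientation: {orientation!r}")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("values must be a square matrix")
        if values.shape[0] != len(labels):
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in PairwiseMatrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite values in PairwiseMatrix")
        if np.any(values < 0):
            raise ValueError("negative values in PairwiseMatrix")
        if not np.allclose(values, values.T, rtol=1e-8, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        expected_diag = 0.0 if orientation == "dissimilarity" else 1.0
        if not np.allclose(np.diag(values), expected_diag, atol=1e-8):
            raise ValueError(
                f"diagonal must be {expected_diag} for orientation {orientation!r}"
            )
        self.labels = labels
        self.values = 0.5 * (values + values.T)  # enforce exact symmetry
        self.orientation = orientation
        self.metric_name = metric_name
        self._index = {l: i for i, l in enumerate(labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        """Value for the (a, b) label pair."""
        return float(self.values[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reordered(self, labels: Sequence[str]) -> "PairwiseMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self._index[l] for l in labels]
        return PairwiseMatrix(
            list(labels),
            self.values[np.ix_(idx, idx)],
            orientation=self.orientation,
            metric_name=self.metric_name,
        )

    def __repr__(self):
        return (
            f"<PairwiseMatrix {self.metric_name or 'unnamed'} "
            f"({self.orientation}, n={self.n})>"
        )


def _validate(dtree: dendropy.Tree) -> None:
    leaves = dtree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(l is None or l == "" for l in labels):
        raise ValueError("every tip must carry a non-empty label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        bl = nd.edge.length
        if bl is None or not np.isfinite(bl) or bl < 0:
            raise ValueError(
                f"every non-root node needs a finite branch length >= 0 (got {bl!r})"
            )


class PhyloTree:
    """A rooted tree with non-negative branch lengths on all non-root edges.

    Branches are attached to child nodes; the root carries no branch.
    Tip labels are unique non-empty strings.  The wrapped dendropy tree is
    treated as immutable: transforming operations return new trees.
    """

    def __init__(self, dtree: dendropy.Tree):
        _validate(dtree)
        self._tree = dtree
        self.tip_labels: list[str] = [
            lf.taxon.label for lf in dtree.leaf_node_iter()
        ]

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a newick string (missing branch lengths default to 1)."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy errors carry line/column info
            raise ValueError(f"malformed newick: {exc}") from exc
        for nd in dtree.preorder_node_iter():
            if nd is not dtree.seed_node and nd.edge.length is None:
                nd.edge.length = 1.0
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Serialise to a newick string with branch lengths."""
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return out.strip()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- properties

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def node_depths(self) -> dict:
        """Map each dendropy node to its distance from the root."""
        depths = {self._tree.seed_node: 0.0}
        for nd in self._tree.preorder_node_iter():
            if nd is self._tree.seed_node:
                continue
            depths[nd] = depths[nd.parent_node] + nd.edge.length
        return depths

    def tip_depths(self) -> np.ndarray:
        depths = self.node_depths()
        return np.array([depths[lf] for lf in self._tree.leaf_node_iter()])

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self.tip_depths().max())

    @property
    def is_ultrametric(self) -> bool:
        """True iff all root-to-tip path lengths agree to 1e-9 relative."""
        d = self.tip_depths()
        dmax = d.max()
        if dmax == 0:
            return True
        return bool((dmax - d.min()) <= ULTRAMETRIC_RTOL * dmax)

    @property
    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_internal_node_iter()
        )

    def total_branch_length(self) -> float:
        return float(
            sum(
                nd.edge.length
                for nd in self._tree.preorder_node_iter()
                if nd is not self._tree.seed_node
            )
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # ----------------------------------------------------------- distances

    def _depth_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Patristic and MRCA-depth matrices, tips in ``tip_labels`` order.

        A single postorder pass: tips whose subtrees first meet at node u
        have patristic distance depth_i + depth_j - 2*depth_u and shared
        depth (covariance under Brownian motion) depth_u.
        """
        n = self.n_tips
        idx = {lf: i for i, lf in enumerate(self._tree.leaf_node_iter())}
        depths = self.node_depths()
        tipd = np.array([depths[lf] for lf in self._tree.leaf_node_iter()])
        D = np.zeros((n, n))
        V = np.zeros((n, n))
        below: dict = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                below[nd] = np.array([idx[nd]])
                continue
            kids = [below.pop(c) for c in nd.child_nodes()]
            h = depths[nd]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia, ib = np.ix_(kids[a], kids[b])
                    d = tipd[kids[a]][:, None] + tipd[kids[b]][None, :] - 2.0 * h
                    D[ia, ib] = d
                    D[ib.T, ia.T] = d.T
                    V[ia, ib] = h
                    V[ib.T, ia.T] = h
            below[nd] = np.concatenate(kids)
        np.fill_diagonal(V, tipd)
        return D, V

    def patristic_matrix(self) -> PairwiseMatrix:
        """Tip-to-tip path-length (patristic) distance matrix."""
        D, _ = self._depth_matrices()
        return PairwiseMatrix(
            self.tip_labels, D, orientation="dissimilarity", metric_name="patristic"
        )

    def shared_depth_matrix(self) -> PairwiseMatrix:
        """Matrix of MRCA depths: V[i, j] = root-to-MRCA(i, j) distance.

        This is the trait covariance structure implied by Brownian motion,
        up to the diffusion rate; V[i, i] is the depth of tip i.
        """
        _, V = self._depth_matrices()
        labels = self.tip_labels
        pm = PairwiseMatrix.__new__(PairwiseMatrix)
        # V has a non-standard diagonal; bypass orientation validation
        pm.labels = list(labels)
        pm.values = 0.5 * (V + V.T)
        pm.orientation = "similarity"
        pm.metric_name = "shared_depth"
        pm._index = {l: i for i, l in enumerate(labels)}
        return pm

    # -------------------------------------------------------- lambda model

    def lambda_transform(self, lam: float) -> "PhyloTree":
        """Pagel's lambda transformation of an ultrametric tree.

        Every internal node's height above the root is scaled by ``lam``
        while tips stay at the original depth T, so terminal branches
        stretch to T - lam*h_parent.  ``lam = 1`` is the identity and
        ``lam -> 0`` approaches a star phylogeny where all tips attach
        directly to the root.

        Raises
        ------
        ValueError
            If the tree is not ultrametric or ``lam`` is outside [0, 1].
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        if not self.is_ultrametric:
            raise ValueError("lambda transform requires an ultrametric tree")
        T = self.depth
        new = self._tree.clone(depth=1)
        depths = {new.seed_node: 0.0}
        for nd in new.preorder_node_iter():
            if nd is new.seed_node:
                continue
            depths[nd] = depths[nd.parent_node] + nd.edge.length
        for nd in new.preorder_node_iter():
            if nd is new.seed_node:
                continue
            parent_h = lam * depths[nd.parent_node]
            if nd.is_leaf():
                nd.edge.length = T - parent_h
            else:
                nd.edge.length = lam * depths[nd] - parent_h
        return PhyloTree(new)

    # ---------------------------------------------------------- resolution

    def resolve_polytomies(self, seed: int) -> "PhyloTree":
        """Replace every polytomy by a uniformly random binary expansion.

        Each multifurcation over k child subtrees is resolved by sequential
        random attachment: subtrees are inserted one at a time onto an edge
        chosen uniformly among the 2m-1 edges of the partial resolution
        (including its root edge), which makes each of the (2k-3)!! rooted
        binary shapes equally likely.  Inserted nodes get branch length 0,
        so every patristic distance and the total tree length are conserved.
        Deterministic for a given ``seed``.
        """
        rng = random.Random(seed)
        new = self._tree.clone(depth=1)
        for nd in list(new.preorder_internal_node_iter()):
            kids = nd.child_nodes()
            if len(kids) <= 2:
                continue
            for c in kids:
                nd.remove_child(c)
            order = list(kids)
            rng.shuffle(order)
            partial = order[0]  # root of the growing binary resolution
            # edges of the partial tree strictly below the polytomy node,
            # plus the partial root's own (virtual) edge
            edges = [partial]
            for sub in order[1:]:
                target = edges[rng.randrange(len(edges))]
                joint = dendropy.Node()
                joint.edge.length = 0.0
                if target is partial:
                    joint.add_child(partial)
                    joint.add_child(sub)
                    partial = joint
                else:
                    parent = target.parent_node
                    parent.remove_child(target)
                    joint.add_child(target)
                    joint.add_child(sub)
                    parent.add_child(joint)
                edges.append(joint)
                edges.append(sub)
            # the expansion root replaces the polytomy node's child set
            # (its own edge is virtual, so no length is lost)
            for c in list(partial.child_nodes()):
                partial.remove_child(c)
                nd.add_child(c)
        return PhyloTree(new)

    def __repr__(self):
        kind = "ultrametric" if self.is_ultrametric else "non-ultrametric"
        return f"<PhyloTree n_tips={self.n_tips} depth={self.depth:.4g} {kind}>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)
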