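"""Phylogenetic beta-diversity metrics between pairs of communities.

Eight phylogenetic metrics are provided, plus the two classical species
metrics (Jaccard, Bray-Curtis):

``phylosor``
    Phylogenetic Sorensen similarity, 2*BL_shared / (BL_1 + BL_2), where a
    branch belongs to a community iff at least one of the community's tips
    descends through it and BL_k is the summed length of the community's
    branches.  In [0, 1]; 1 for identical communities.
``unifrac``
    Unique fraction of the phylogeny: length of branches belonging to
    exactly one community divided by the length of branches belonging to at
    least one.  In [0, 1]; 0 for identical communities.
``dnn`` / ``dnnw``
    Mean nearest phylogenetic neighbour distance between the two
    communities, presence-weighted (pooled over both communities,
    denominator n1 + n2) or abundance-weighted (the two f-weighted sums of
    nearest-neighbour distances, divided by 2).
``dpw`` / ``dpww``
    Mean pairwise phylogenetic distance across communities: the simple
    cross-pair mean, or the abundance-weighted double sum
    sum_i sum_j f_i f_j d_ij.
``raod``
    Between-community Rao quadratic entropy, half the abundance-weighted
    double sum — identically ``dpww / 2``.
``raoh``
    Rao's D standardised by alpha diversity:
    H = D12 - (D11 + D22) / 2, with D_kk the within-community half double
    sum over ordered pairs including self-pairs (d_ii = 0).

Nearest-neighbour and pairwise sums include species shared between the two
plots, which contribute distance 0.  Presence mode sets f_i = 1/n so every
presence metric is the equal-abundance special case of its weighted form.

On a star phylogeny every metric collapses to species-level information;
in particular PhyloSor equals the classical Sorensen similarity exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .communities import CommunityTable
from .trees import PairwiseMatrix, PhyloTree

__all__ = [
    "METRICS",
    "BetaCalculator",
    "phylosor",
    "unifrac",
    "dnn",
    "dpw",
    "rao_d",
    "rao_h",
    "jaccard",
    "bray_curtis",
    "all_pairs",
    "pairwise_matrix",
]

#: canonical metric names, in reporting order
METRICS = (
    "phylosor",
    "unifrac",
    "dnn",
    "dnnw",
    "dpw",
    "dpww",
    "raod",
    "raoh",
    "jaccard",
    "braycurtis",
)

#: metrics whose values are similarities (rest are dissimilarities/distances)
SIMILARITY_METRICS = frozenset({"phylosor"})

#: metrics that use the phylogeny (Jaccard/Bray-Curtis do not)
PHYLO_METRICS = frozenset(METRICS) - {"jaccard", "braycurtis"}


class BetaCalculator:
    """Precomputed structures for fast pairwise metric evaluation.

    Aligns a community table with a tree once (species must be a subset of
    the tips), building the branch-tip incidence matrix used by the
    branch-sharing metrics and the patristic matrix used by the
    distance-based ones.
    """

    def __init__(self, tree: PhyloTree, table: CommunityTable):
        table.check_against_tree(tree)
        self.tree = tree
        self.table = table
        tips = tree.tip_labels
        tip_idx = {t: i for i, t in enumerate(tips)}
        self._plot_idx = {p: i for i, p in enumerate(table.plots)}

        # abundance matrix aligned to tree tip order (plots x tips)
        A = np.zeros((len(table.plots), len(tips)))
        cols = [tip_idx[sp] for sp in table.species]
        A[:, cols] = table.df.values
        self.abund = A
        self.pres = A > 0

        # branch arrays: one entry per non-root node (branch attached below)
        dtree = tree._tree
        branches = [
            nd for nd in dtree.preorder_node_iter() if nd is not dtree.seed_node
        ]
        self.branch_lengths = np.array([nd.edge.length for nd in branches])
        incidence = np.zeros((len(branches), len(tips)), dtype=bool)
        below: dict = {}
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                below[nd] = [tip_idx[nd.taxon.label]]
            else:
                below[nd] = [i for c in nd.child_nodes() for i in below[c]]
        for b, nd in enumerate(branches):
            incidence[b, below[nd]] = True
        self.incidence = incidence

        # branch membership per plot: branch belongs to the plot iff >= 1
        # of the plot's tips descends through it
        self.plot_branches = (self.pres @ incidence.T.astype(float)) > 0

        self.D = tree.patristic_matrix().values

    # ------------------------------------------------------------- helpers

    def _pi(self, plot: str) -> int:
        try:
            return self._plot_idx[plot]
        except KeyError:
            raise KeyError(f"unknown plot: {plot!r}") from None

    def _freqs(self, i: int, mode: str) -> np.ndarray:
        """Relative abundances over tree tips (zero where absent)."""
        if mode == "presence":
            w = self.pres[i].astype(float)
        elif mode == "abundance":
            w = self.abund[i].copy()
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        return w / w.sum()

    # ------------------------------------------------------------- metrics

    def phylosor(self, p1: str, p2: str) -> float:
        b1 = self.plot_branches[self._pi(p1)]
        b2 = self.plot_branches[self._pi(p2)]
        L = self.branch_lengths
        bl1, bl2 = L[b1].sum(), L[b2].sum()
        shared = L[b1 & b2].sum()
        return float(2.0 * shared / (bl1 + bl2))

    def unifrac(self, p1: str, p2: str) -> float:
        b1 = self.plot_branches[self._pi(p1)]
        b2 = self.plot_branches[self._pi(p2)]
        L = self.branch_lengths
        union = L[b1 | b2].sum()
        unique = L[b1 ^ b2].sum()
        return float(unique / union)

    def dnn(self, p1: str, p2: str, mode: str = "presence") -> float:
        i, j = self._pi(p1), self._pi(p2)
        s1 = np.flatnonzero(self.pres[i])
        s2 = np.flatnonzero(self.pres[j])
        cross = self.D[np.ix_(s1, s2)]
        min1 = cross.min(axis=1)  # nearest neighbour in p2 for each sp of p1
        min2 = cross.min(axis=0)
        if mode == "presence":
            return float((min1.sum() + min2.sum()) / (len(s1) + len(s2)))
        if mode == "abundance":
            f1 = self._freqs(i, "abundance")[s1]
            f2 = self._freqs(j, "abundance")[s2]
            return float((f1 @ min1 + f2 @ min2) / 2.0)
        raise ValueError(f"unknown mode: {mode!r}")

    def dpw(self, p1: str, p2: str, mode: str = "presence") -> float:
        i, j = self._pi(p1), self._pi(p2)
        if mode == "presence":
            s1 = np.flatnonzero(self.pres[i])
            s2 = np.flatnonzero(self.pres[j])
            return float(self.D[np.ix_(s1, s2)].mean())
        if mode == "abundance":
            f1 = self._freqs(i, "abundance")
            f2 = self._freqs(j, "abundance")
            return float(f1 @ self.D @ f2)
        raise ValueError(f"unknown mode: {mode!r}")

    def rao_d(self, p1: str, p2: str, mode: str = "abundance") -> float:
        f1 = self._freqs(self._pi(p1), mode)
        f2 = self._freqs(self._pi(p2), mode)
        return float(0.5 * (f1 @ self.D @ f2))

    def _rao_within(self, i: int, mode: str) -> float:
        f = self._freqs(i, mode)
        return float(0.5 * (f @ self.D @ f))

    def rao_h(self, p1: str, p2: str, mode: str = "abundance") -> float:
        d12 = self.rao_d(p1, p2, mode)
        d11 = self._rao_within(self._pi(p1), mode)
        d22 = self._rao_within(self._pi(p2), mode)
        return float(d12 - 0.5 * (d11 + d22))

    def jaccard(self, p1: str, p2: str) -> float:
        a = self.pres[self._pi(p1)]
        b = self.pres[self._pi(p2)]
        union = (a | b).sum()
        if union == 0:
            raise ValueError("both plots are empty")
        return float(1.0 - (a & b).sum() / union)

    def bray_curtis(self, p1: str, p2: str) -> float:
        x = self.abund[self._pi(p1)]
        y = self.abund[self._pi(p2)]
        tot = (x + y).sum()
        if tot == 0:
            raise ValueError("both plots are empty")
        return float(np.abs(x - y).sum() / tot)

    # ---------------------------------------------------------------- bulk

    def value(self, metric: str, p1: str, p2: str, mode: str = "abundance") -> float:
        """Evaluate one named metric for a plot pair.

        ``mode`` selects the f-weighting of raod/raoh (dnnw/dpww are
        abundance-weighted by definition; dnn/dpw/phylosor/unifrac/jaccard
        are presence-based, braycurtis abundance-based).
        """
        if metric == "phylosor":
            return self.phylosor(p1, p2)
        if metric == "unifrac":
            return self.unifrac(p1, p2)
        if metric == "dnn":
            return self.dnn(p1, p2, "presence")
        if metric == "dnnw":
            return self.dnn(p1, p2, "abundance")
        if metric == "dpw":
            return self.dpw(p1, p2, "presence")
        if metric == "dpww":
            return self.dpw(p1, p2, "abundance")
        if metric == "raod":
            return self.rao_d(p1, p2, mode)
        if metric == "raoh":
            return self.rao_h(p1, p2, mode)
        if metric == "jaccard":
            return self.jaccard(p1, p2)
        if metric == "braycurtis":
            return self.bray_curtis(p1, p2)
        raise ValueError(f"unknown metric: {metric!r}")

    def all_pairs(self, metrics=PHYLO_METRICS, mode: str = "abundance") -> pd.DataFrame:
        """Long table with one row per unordered plot pair per metric.

        Pairs follow the table's plot order (i < j); metrics follow the
        order given (or canonical order for set-like inputs).
        """
        requested = list(metrics)
        unknown = [m for m in requested if m not in METRICS]
        if unknown:
            raise ValueError(f"unknown metric(s): {unknown}")
        if isinstance(metrics, (frozenset, set)):
            requested = [m for m in METRICS if m in metrics]
        metrics = requested
        plots = self.table.plots
        rows = []
        for a in range(len(plots)):
            for b in range(a + 1, len(plots)):
                p1, p2 = plots[a], plots[b]
                for m in metrics:
                    rows.append((p1, p2, m, mode, self.value(m, p1, p2, mode)))
        return pd.DataFrame(rows, columns=["plot1", "plot2", "metric", "mode", "value"])

    def pairwise_matrix(self, metric: str, mode: str = "abundance") -> PairwiseMatrix:
        """Plot x plot matrix of one metric."""
        plots = self.table.plots
        n = len(plots)
        M = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                M[a, b] = M[b, a] = self.value(metric, plots[a], plots[b], mode)
        orientation = "dissimilarity"
        if metric in SIMILARITY_METRICS:
            orientation = "similarity"
            np.fill_diagonal(M, 1.0)
        return PairwiseMatrix(plots, M, orientation=orientation, metric_name=metric)


# ------------------------------------------------------- module-level API


def phylosor(tree, table, plot1, plot2) -> float:
    """PhyloSor similarity between two plots (see module docstring)."""
    return BetaCalculator(tree, table).phylosor(plot1, plot2)


def unifrac(tree, table, plot1, plot2) -> float:
    """UniFrac dissimilarity between two plots."""
    return BetaCalculator(tree, table).unifrac(plot1, plot2)


def dnn(tree, table, plot1, plot2, mode="presence") -> float:
    """Mean nearest phylogenetic neighbour distance between two plots."""
    return BetaCalculator(tree, table).dnn(plot1, plot2, mode)


def dpw(tree, table, plot1, plot2, mode="presence") -> float:
    """Mean pairwise phylogenetic distance between two plots."""
    return BetaCalculator(tree, table).dpw(plot1, plot2, mode)


def rao_d(tree, table, plot1, plot2, mode="abundance") -> float:
    """Between-community Rao quadratic entropy (= dpww / 2)."""
    return BetaCalculator(tree, table).rao_d(plot1, plot2, mode)


def rao_h(tree, table, plot1, plot2, mode="abundance") -> float:
    """Rao's D standardised by the two within-community entropies."""
    return BetaCalculator(tree, table).rao_h(plot1, plot2, mode)


def jaccard(table, plot1, plot2) -> float:
    """Jaccard dissimilarity on presence sets."""
    a = set(table.presence(plot1))
    b = set(table.presence(plot2))
    if not a | b:
        raise ValueError("both plots are empty")
    return 1.0 - len(a & b) / len(a | b)


def bray_curtis(table, plot1, plot2) -> float:
    """Bray-Curtis dissimilarity on abundances."""
    x = table.abundances(plot1).astype(float)
    y = table.abundances(plot2).astype(float)
    tot = float((x + y).sum())
    if tot == 0:
        raise ValueError("both plots are empty")
    return float((x - y).abs().sum() / tot)


def all_pairs(tree, table, metrics=PHYLO_METRICS, mode="abundance") -> pd.DataFrame:
    """Evaluate metrics for every unordered plot pair; long DataFrame."""
    return BetaCalculator(tree, table).all_pairs(metrics, mode)


def pairwise_matrix(tree, table, metric, mode="abundance") -> PairwiseMatrix:
    """Plot x plot :class:`PairwiseMatrix` for one metric."""
    return BetaCalculator(tree, table).pairwise_matrix(metric, mode)
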