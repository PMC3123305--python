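"""Independent naive reference implementations used only by the tests.

Everything here works from explicit root paths and python dict/loop
arithmetic — deliberately avoiding the vectorised incidence-matrix and
postorder algorithms of the package — so agreement is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np


# --------------------------------------------------------- random trees


def random_tree_newick(rng: random.Random, n_tips: int, ultrametric: bool = False) -> str:
    """A random rooted binary tree as a newick string.

    Topology by recursive random splitting; branch lengths uniform in
    (0.1, 2.0), or set so all tips are equidistant from the root when
    ``ultrametric`` is requested.
    """
    labels = [f"x{i}" for i in range(n_tips)]
    rng.shuffle(labels)

    if not ultrametric:

        def build(tips):
            if len(tips) == 1:
                return f"{tips[0]}:{rng.uniform(0.1, 2.0):.6f}"
            k = rng.randint(1, len(tips) - 1)
            left, right = tips[:k], tips[k:]
            return f"({build(left)},{build(right)}):{rng.uniform(0.1, 2.0):.6f}"

        body = build(labels)
        # strip the root's branch length
        return body[: body.rfind(":")] + ";"

    def build_u(tips, height):
        # full-precision lengths so the result is ultrametric to 1e-9
        if len(tips) == 1:
            return f"{tips[0]}:{height!r}"
        k = rng.randint(1, len(tips) - 1)
        child_h = rng.uniform(0.05, 0.95) * height
        left = build_u(tips[:k], child_h)
        right = build_u(tips[k:], child_h)
        return f"({left},{right}):{height - child_h!r}"

    top = build_u(labels, 1.0)
    return top[: top.rfind(":")] + ";"


# ------------------------------------------------ root-path tree algebra


def index_tree(newick: str):
    """Parent map, branch lengths and tip labels from a newick string."""
    dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    nodes = list(dtree.preorder_node_iter())
    ids = {nd: i for i, nd in enumerate(nodes)}
    parent = {}
    length = {}
    for nd in nodes:
        i = ids[nd]
        if nd.parent_node is None:
            parent[i] = None
            length[i] = 0.0
        else:
            parent[i] = ids[nd.parent_node]
            length[i] = nd.edge.length if nd.edge.length is not None else 1.0
    tips = {nd.taxon.label: ids[nd] for nd in dtree.leaf_node_iter()}
    return parent, length, tips


def root_path(parent, node):
    """Set of branch ids (child-node ids) on the path from node to root."""
    path = set()
    while parent[node] is not None:
        path.add(node)
        node = parent[node]
    return path


def naive_patristic(newick: str):
    """Tip-to-tip distances by symmetric difference of root paths."""
    parent, length, tips = index_tree(newick)
    out = {}
    for a, na in tips.items():
        for b, nb in tips.items():
            sym = root_path(parent, na) ^ root_path(parent, nb)
            out[(a, b)] = sum(length[e] for e in sym)
    return out


def naive_mrca_patristic(newick: str):
    """Tip-to-tip distances by d = depth_i + depth_j - 2*depth(MRCA)."""
    parent, length, tips = index_tree(newick)

    def depth(node):
        d = 0.0
        while parent[node] is not None:
            d += length[node]
            node = parent[node]
        return d

    def ancestors(node):
        anc = [node]
        while parent[node] is not None:
            node = parent[node]
            anc.append(node)
        return anc

    out = {}
    for a, na in tips.items():
        for b, nb in tips.items():
            anc_a = ancestors(na)
            anc_b = set(ancestors(nb))
            mrca = next(x for x in anc_a if x in anc_b)
            out[(a, b)] = depth(na) + depth(nb) - 2.0 * depth(mrca)
    return out


# ------------------------------------------------------- naive metrics


def _community_branches(parent, tips, community):
    branches = set()
    for sp in community:
        branches |= root_path(parent, tips[sp])
    return branches


def naive_phylosor(newick, comm1, comm2):
    parent, length, tips = index_tree(newick)
    b1 = _community_branches(parent, tips, comm1)
    b2 = _community_branches(parent, tips, comm2)
    bl = lambda s: sum(length[e] for e in s)
    return 2.0 * bl(b1 & b2) / (bl(b1) + bl(b2))


def naive_unifrac(newick, comm1, comm2):
    parent, length, tips = index_tree(newick)
    b1 = _community_branches(parent, tips, comm1)
    b2 = _community_branches(parent, tips, comm2)
    bl = lambda s: sum(length[e] for e in s)
    return bl(b1 ^ b2) / bl(b1 | b2)


def _freqs(abund):
    tot = sum(abund.values())
    return {sp: a / tot for sp, a in abund.items()}


def naive_dnn(newick, comm1, comm2, abund1=None, abund2=None):
    """Presence mode when abundances are None, else the weighted form."""
    d = naive_patristic(newick)
    min1 = {i: min(d[(i, j)] for j in comm2) for i in comm1}
    min2 = {j: min(d[(i, j)] for i in comm1) for j in comm2}
    if abund1 is None:
        return (sum(min1.values()) + sum(min2.values())) / (len(comm1) + len(comm2))
    f1, f2 = _freqs(abund1), _freqs(abund2)
    return (
        sum(f1[i] * min1[i] for i in comm1) + sum(f2[j] * min2[j] for j in comm2)
    ) / 2.0


def naive_dpw(newick, comm1, comm2, abund1=None, abund2=None):
    d = naive_patristic(newick)
    if abund1 is None:
        return sum(d[(i, j)] for i in comm1 for j in comm2) / (len(comm1) * len(comm2))
    f1, f2 = _freqs(abund1), _freqs(abund2)
    return sum(f1[i] * f2[j] * d[(i, j)] for i in comm1 for j in comm2)


def naive_rao_d(newick, comm1, comm2, abund1, abund2):
    return 0.5 * naive_dpw(newick, comm1, comm2, abund1, abund2)


def naive_rao_h(newick, comm1, comm2, abund1, abund2):
    d12 = naive_rao_d(newick, comm1, comm2, abund1, abund2)
    d11 = naive_rao_d(newick, comm1, comm1, abund1, abund1)
    d22 = naive_rao_d(newick, comm2, comm2, abund2, abund2)
    return d12 - 0.5 * (d11 + d22)


# --------------------------------------------------------- naive UPGMA


def naive_upgma_cophenetic(values: dict):
    """Step-by-step UPGMA on |x_i - x_j|; returns cophenetic distances.

    O(n^3) agglomeration with explicit cluster lists; cophenetic distance
    between two leaves is the height of the merge that joins them.
    """
    clusters = [[k] for k in values]
    heights = {}
    dist = lambda a, b: abs(values[a] - values[b])

    def cluster_dist(c1, c2):
        return sum(dist(a, b) for a in c1 for b in c2) / (len(c1) * len(c2))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                heights[(a, b)] = heights[(b, a)] = d
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights
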