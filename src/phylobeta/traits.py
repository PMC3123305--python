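"""Trait evolution, phylogenetic signal and the functional-beta sweep.

Continuous traits are evolved along a phylogeny under an
Ornstein-Uhlenbeck (OU) process with selective constraint ``alpha``,
optimum ``theta`` and diffusion ``sigma`` (or under plain Brownian motion).
Phylogenetic signal is quantified with Blomberg's K: K near 1 is the
Brownian expectation, K > 1 indicates that relatives resemble each other
more than Brownian motion predicts, K < 1 less.

:func:`signal_sweep` ties the pieces together: it evolves many trait
datasets spanning a wide range of K, turns each into an ultrametric trait
dendrogram via hierarchical clustering, computes functional beta diversity
between all plot pairs on that dendrogram with the same metrics used for
the phylogeny, and records how well phylogenetic beta diversity predicts
functional beta diversity (the per-metric regression R^2) as a function
of K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist

from . import metrics as _metrics
from .communities import CommunityTable
from .trees import PhyloTree

__all__ = [
    "OUParams",
    "simulate_ou",
    "simulate_brownian",
    "blomberg_k",
    "trait_dendrogram",
    "signal_sweep",
    "SignalSweepResult",
]


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck simulation parameters.

    alpha : selective constraint (> 0), pull toward the optimum per unit
        branch length.
    theta : trait optimum (also the root state).
    sigma : diffusion standard deviation per unit sqrt(branch length).
    seed  : RNG seed; a fixed seed makes the simulation deterministic.
    """

    alpha: float
    theta: float = 0.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0 (use simulate_brownian for alpha=0)")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def _as_series(tree: PhyloTree, values: dict) -> pd.Series:
    return pd.Series({t: values[t] for t in tree.tip_labels}, name="trait")


def simulate_ou(tree: PhyloTree, params: OUParams) -> pd.Series:
    """Evolve one continuous trait along the tree under an OU process.

    The root starts at ``theta``.  Along a branch of length t the exact
    transition is applied:

        child = parent * e^(-alpha t) + theta (1 - e^(-alpha t)) + eps,
        eps ~ Normal(0, sigma^2 (1 - e^(-2 alpha t)) / (2 alpha)),

    so the simulation is exact for any branch length (no Euler stepping).
    Returns a Series of tip values indexed by tip label.
    """
    rng = np.random.default_rng(params.seed)
    a, th, s = params.alpha, params.theta, params.sigma
    dtree = tree._tree
    state = {dtree.seed_node: th}
    tips: dict[str, float] = {}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            x = state[nd]
        else:
            t = nd.edge.length
            decay = np.exp(-a * t)
            sd = s * np.sqrt((1.0 - np.exp(-2.0 * a * t)) / (2.0 * a))
            x = state[nd.parent_node] * decay + th * (1.0 - decay) + rng.normal(0.0, sd)
            state[nd] = x
        if nd.is_leaf():
            tips[nd.taxon.label] = x
    return _as_series(tree, tips)


def simulate_brownian(
    tree: PhyloTree, sigma: float = 1.0, root: float = 0.0, seed: int = 0
) -> pd.Series:
    """Evolve one trait under Brownian motion (variance sigma^2 per unit)."""
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    dtree = tree._tree
    state = {dtree.seed_node: root}
    tips: dict[str, float] = {}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            x = state[nd]
        else:
            x = state[nd.parent_node] + rng.normal(0.0, sigma * np.sqrt(nd.edge.length))
            state[nd] = x
        if nd.is_leaf():
            tips[nd.taxon.label] = x
    return _as_series(tree, tips)


def blomberg_k(tree: PhyloTree, traits: pd.Series) -> float:
    """Blomberg's K statistic of phylogenetic signal.

    With V the tip shared-branch-length (MRCA depth) matrix and a_hat the
    GLS (phylogenetic) mean,

        K = (MSE0 / MSE)_observed / [(tr V - n / sum(V^-1)) / (n - 1)],

    where MSE0 = (x - a_hat)'(x - a_hat)/(n-1) and
    MSE = (x - a_hat)' V^-1 (x - a_hat)/(n-1).  K = 1 exactly on a star
    phylogeny and in expectation (approximately) under Brownian motion.
    """
    if tree.n_tips < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if set(traits.index) != set(tree.tip_labels):
        raise ValueError("traits must cover every tip exactly once")
    x = traits.reindex(tree.tip_labels).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    V = tree.shared_depth_matrix().values
    n = len(x)
    try:
        chol = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance matrix: {exc}") from exc
    ones = np.ones(n)
    vi_ones = cho_solve(chol, ones)
    denom = ones @ vi_ones  # sum of all elements of V^-1
    ahat = (x @ vi_ones) / denom
    r = x - ahat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ cho_solve(chol, r)) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


_LINKAGES = {"upgma": "average", "complete": "complete", "single": "single"}


def trait_dendrogram(traits: pd.Series, linkage: str = "upgma") -> PhyloTree:
    """Ultrametric dendrogram of species from pairwise trait distances.

    Distances are absolute trait differences (Euclidean in one dimension),
    agglomerated with the chosen linkage (default UPGMA).  Tip depth is set
    to merge height / 2, so the cophenetic (patristic) distance between two
    tips equals the height at which they merge.  The result is a
    :class:`PhyloTree` usable by every beta-diversity metric.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    labels = [str(l) for l in traits.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in trait vector")
    if len(labels) < 2:
        raise ValueError("need at least 2 species")
    x = traits.to_numpy(dtype=float)[:, None]
    Z = hierarchy.linkage(pdist(x, metric="cityblock"), method=_LINKAGES[linkage])

    n = len(labels)
    heights = {i: 0.0 for i in range(n)}  # height of each cluster above tips

    def newick(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        h /= 2.0  # tip depth = merge height / 2
        left, right = int(a), int(b)
        bl_l = h - heights[left]
        bl_r = h - heights[right]
        heights[i] = h
        return f"({newick(left)}:{bl_l:.17g},{newick(right)}:{bl_r:.17g})"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        for i in range(n, 2 * n - 1):  # record heights bottom-up first
            heights[i] = Z[i - n, 2] / 2.0
        text = newick(2 * n - 2) + ";"
    finally:
        sys.setrecursionlimit(old)
    return PhyloTree.from_newick(text)


@dataclass
class SignalSweepResult:
    """Outcome of :func:`signal_sweep`.

    ``table`` has one row per retained trait dataset with its OU alpha,
    realised Blomberg K, and one ``r2_<metric>`` column per metric: the R^2
    of the regression of functional beta diversity (computed on the trait
    dendrogram) on phylogenetic beta diversity, over all plot pairs.
    """

    table: pd.DataFrame
    metrics: tuple = ()
    seed: int = 0

    @property
    def k_values(self) -> np.ndarray:
        return self.table["K"].to_numpy()

    def r2(self, metric: str) -> np.ndarray:
        return self.table[f"r2_{metric}"].to_numpy()


def signal_sweep(
    tree: PhyloTree,
    table: CommunityTable,
    alpha_grid=None,
    n_datasets: int = 60,
    metrics=("phylosor", "unifrac", "dnn", "dnnw", "dpw", "dpww", "raod", "raoh"),
    seed: int = 0,
    sigma: float = 0.1,
    theta: float = 0.0,
    oversample: int = 10,
    linkage: str = "upgma",
) -> SignalSweepResult:
    """Phylogenetic-signal sweep: how K controls the phylogeny's ability
    to predict functional beta diversity.

    ``oversample * n_datasets`` OU trait datasets are simulated with alpha
    cycling over ``alpha_grid`` (default: 12 values evenly spaced on
    [0.2, 0.99]); Blomberg's K is computed for each, and ``n_datasets``
    datasets are retained at evenly spaced ranks of K so the kept set spans
    the realised K range.  For each retained dataset a trait dendrogram is
    built, functional beta diversity is computed for every plot pair with
    every metric, and the R^2 of functional-on-phylogenetic regression is
    recorded per metric.  Fully deterministic for a given ``seed``.
    """
    n_pairs = len(table.plots) * (len(table.plots) - 1) // 2
    if n_pairs < 3:
        raise ValueError("need at least 3 plot pairs for the sweep regression")
    if alpha_grid is None:
        alpha_grid = np.linspace(0.2, 0.99, 12)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    metrics = list(metrics)

    rng = np.random.default_rng(seed)
    n_sim = int(oversample) * int(n_datasets)
    sims = []
    for i in range(n_sim):
        alpha = float(alpha_grid[i % len(alpha_grid)])
        sub = int(rng.integers(0, 2**31 - 1))
        tr = simulate_ou(tree, OUParams(alpha=alpha, theta=theta, sigma=sigma, seed=sub))
        sims.append((alpha, blomberg_k(tree, tr), tr))

    # retain n_datasets spanning the realised K range: evenly spaced order
    # statistics of K (one per quantile bin)
    order = np.argsort([s[1] for s in sims], kind="stable")
    keep_ranks = np.round(np.linspace(0, n_sim - 1, n_datasets)).astype(int)
    kept = [sims[order[r]] for r in keep_ranks]

    phylo = _metrics.BetaCalculator(tree, table).all_pairs(metrics, mode="abundance")
    phylo_wide = phylo.pivot_table(
        index=["plot1", "plot2"], columns="metric", values="value", sort=False
    )

    rows = []
    for alpha, K, tr in kept:
        dend = trait_dendrogram(tr, linkage=linkage)
        func = _metrics.BetaCalculator(dend, table).all_pairs(metrics, mode="abundance")
        func_wide = func.pivot_table(
            index=["plot1", "plot2"], columns="metric", values="value", sort=False
        )
        row = {"alpha": alpha, "K": K}
        for m in metrics:
            x = phylo_wide[m].to_numpy()
            y = func_wide[m].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                row[f"r2_{m}"] = np.nan
            else:
                row[f"r2_{m}"] = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("K", ignore_index=True)
    return SignalSweepResult(table=out, metrics=tuple(metrics), seed=seed)
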