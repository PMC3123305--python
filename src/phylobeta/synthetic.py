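"""Synthetic substrates: the worked-example fixture and a gradient
community simulator.

:func:`scenario_fixture` builds the 16-tip balanced, unit-branch-length
ultrametric tree together with four presence-absence community pairs that
exhibit, respectively, deep (basal) turnover between distant clades
(scenario A), basal turnover between sister clades (B), and terminal
turnover among cherry mates spread over the whole tree (C) or one half of
it (D).  Every pair has complete species turnover; the scenarios differ
only in where on the tree the turnover happens, which is exactly what the
branch-sharing versus distance-based metrics disagree about.

:func:`simulate_gradient` emulates a network of forest plots along a
rainfall gradient: an ultrametric birth-death phylogeny, species
precipitation optima evolved on it (Brownian for the niche-conserved mode,
tip-shuffled for the labile mode), plots on a latitude line with
monotonically increasing precipitation, and multinomial sampling of
individuals from Gaussian niche weights.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .communities import CommunityTable, EnvTable
from .traits import simulate_brownian
from .trees import PhyloTree

__all__ = [
    "ScenarioFixture",
    "scenario_fixture",
    "GradientConfig",
    "simulate_gradient",
]

# 16-tip balanced binary tree, all branch lengths 1 (depth 4); cherries
# (t1,t2)...(t15,t16), four-species clades Q1={t1..t4} ... Q4={t13..t16}
_FIXTURE_NEWICK = (
    "((((t1:1,t2:1):1,(t3:1,t4:1):1):1,((t5:1,t6:1):1,(t7:1,t8:1):1):1):1,"
    "(((t9:1,t10:1):1,(t11:1,t12:1):1):1,((t13:1,t14:1):1,(t15:1,t16:1):1):1):1);"
)

_SCENARIOS = {
    # deep turnover: opposite root halves
    "A": ({"t1", "t2", "t3", "t4"}, {"t9", "t10", "t11", "t12"}),
    # basal turnover between sister 4-clades
    "B": ({"t1", "t2", "t3", "t4"}, {"t5", "t6", "t7", "t8"}),
    # terminal turnover: cherry mates across the whole tree
    "C": ({"t1", "t3", "t9", "t11"}, {"t2", "t4", "t10", "t12"}),
    # terminal turnover confined to one root half
    "D": ({"t1", "t3", "t5", "t7"}, {"t2", "t4", "t6", "t8"}),
}


@dataclass(frozen=True)
class ScenarioFixture:
    """The worked-example tree and its four community pairs (A-D)."""

    tree: PhyloTree
    scenarios: dict

    def community_table(self) -> CommunityTable:
        """Presence-absence table with plots ``<scenario>_blue/orange``."""
        species = self.tree.tip_labels
        rows = {}
        for name, (blue, orange) in self.scenarios.items():
            rows[f"{name}_blue"] = [1 if s in blue else 0 for s in species]
            rows[f"{name}_orange"] = [1 if s in orange else 0 for s in species]
        return CommunityTable(
            pd.DataFrame.from_dict(rows, orient="index", columns=species)
        )

    def pair(self, scenario: str) -> tuple[str, str]:
        if scenario not in self.scenarios:
            raise KeyError(f"unknown scenario: {scenario!r}")
        return f"{scenario}_blue", f"{scenario}_orange"


def scenario_fixture() -> ScenarioFixture:
    """Build the deterministic 16-tip worked-example fixture."""
    return ScenarioFixture(
        tree=PhyloTree.from_newick(_FIXTURE_NEWICK),
        scenarios={k: (set(b), set(o)) for k, (b, o) in _SCENARIOS.items()},
    )


@dataclass(frozen=True)
class GradientConfig:
    """Configuration of the gradient community simulator.

    Defaults emulate a 96-plot tropical forest network: 446 species,
    ~61,965 individuals in total, latitude 13.2-15.2 deg at constant
    longitude, altitude 55-1060 m (drawn independently of assembly, so it
    acts as a negative control), annual precipitation 776-8340 mm.
    ``niche_breadth_mm`` is the s.d. of the Gaussian niche kernel linking a
    species' precipitation optimum to its sampling weight in a plot.
    ``tree_depth`` is the root-to-tip depth in arbitrary time units.
    """

    n_plots: int = 96
    n_species: int = 446
    precip_range: tuple = (776.0, 8340.0)
    alt_range: tuple = (55.0, 1060.0)
    lat_range: tuple = (13.2, 15.2)
    longitude: float = 75.0
    total_individuals: int = 61965
    mode: str = "conserved"
    niche_breadth_mm: float = 1250.0
    precip_ramp: float = 5.0
    tree_depth: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 2:
            raise ValueError("n_plots must be >= 2")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in ("precip_range", "alt_range", "lat_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")
        if min(self.precip_range) <= 0 or min(self.alt_range) <= 0:
            raise ValueError("precip_range and alt_range must be positive")
        if self.mode not in ("conserved", "labile"):
            raise ValueError("mode must be 'conserved' or 'labile'")
        if not self.niche_breadth_mm > 0:
            raise ValueError(
                "infeasible config: niche_breadth_mm must be > 0 "
                "(a zero-width niche kernel leaves plots empty)"
            )
        if self.precip_ramp < 0:
            raise ValueError("precip_ramp must be >= 0 (0 gives a linear gradient)")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be > 0")
        if self.total_individuals < self.n_plots:
            raise ValueError(
                "infeasible config: total_individuals must be >= n_plots "
                "(every plot needs at least one individual)"
            )


def _simulate_ultrametric_tree(n_species: int, depth: float, seed: int) -> PhyloTree:
    """Birth-death tree conditioned on tip count, rescaled to exact depth."""
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(
        [f"s{i + 1:04d}" for i in range(n_species)]
    )
    birth, death = 1.0, 0.25
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=rng,
    )
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry; run the clock one more exponential waiting time
    # so terminal branches stay positive (keeps the tree ultrametric)
    hold = rng.expovariate(n_species * (birth + death))
    for lf in dtree.leaf_node_iter():
        lf.edge.length += hold
    # rescale to the requested depth, then snap tips to exactly equal
    # depth (the simulator leaves ~1e-15 relative float scatter)
    tmp = PhyloTree(dtree)
    scale = depth / tmp.depth
    for nd in dtree.preorder_node_iter():
        if nd is not dtree.seed_node:
            nd.edge.length *= scale
    tmp = PhyloTree(dtree)
    depths = tmp.node_depths()
    for lf in dtree.leaf_node_iter():
        lf.edge.length += depth - depths[lf]
    return PhyloTree(dtree)


def simulate_gradient(
    config: GradientConfig | None = None, **overrides
) -> tuple[PhyloTree, CommunityTable, EnvTable]:
    """Simulate (tree, community table, environment table) along a gradient.

    Plots sit at evenly spaced latitudes on a constant longitude; annual
    precipitation increases monotonically (convexly) across the plot line,
    so environmental and geographic distance are correlated but not
    collinear.  Each species carries a precipitation optimum evolved on the
    tree by Brownian motion and rescaled to the precipitation range
    (``mode="conserved"``); ``mode="labile"`` shuffles the optima across
    tips, destroying phylogenetic niche structure while leaving the
    species-level gradient intact.  A plot's individuals are drawn
    multinomially with species weights from a Gaussian kernel of
    |plot precipitation - species optimum|.  Deterministic given the seed.
    """
    if config is None:
        config = GradientConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a GradientConfig or keyword overrides")
    config.validate()
    rng = np.random.default_rng(config.seed)

    tree = _simulate_ultrametric_tree(
        config.n_species, config.tree_depth, seed=int(rng.integers(0, 2**31 - 1))
    )
    species = tree.tip_labels

    # species precipitation optima
    bm = simulate_brownian(
        tree, sigma=1.0, root=0.0, seed=int(rng.integers(0, 2**31 - 1))
    )
    lo_p, hi_p = config.precip_range
    x = bm.to_numpy()
    span = x.max() - x.min()
    if span == 0:  # degenerate draw; spread optima uniformly instead
        optima = np.linspace(lo_p, hi_p, len(species))
    else:
        optima = lo_p + (x - x.min()) / span * (hi_p - lo_p)
    optima = pd.Series(optima, index=bm.index)
    if config.mode == "labile":
        optima = pd.Series(
            rng.permutation(optima.to_numpy()), index=optima.index
        )
    optima = optima.reindex(species)

    # plot environment
    u = np.linspace(0.0, 1.0, config.n_plots)
    lat = config.lat_range[0] + u * (config.lat_range[1] - config.lat_range[0])
    # orographic-style rainfall profile: monotone and convex in latitude,
    # so precipitation distance is correlated with but not collinear to
    # geographic distance (ramp 0 degenerates to a linear gradient)
    k = config.precip_ramp
    shape = u if k == 0 else np.expm1(k * u) / np.expm1(k)
    precip = lo_p + shape * (hi_p - lo_p)
    alt = rng.uniform(config.alt_range[0], config.alt_range[1], config.n_plots)
    plot_ids = [f"p{i + 1:03d}" for i in range(config.n_plots)]
    env = EnvTable(
        pd.DataFrame(
            {
                "lat": lat,
                "lon": config.longitude,
                "alt_m": alt,
                "precip_mm": precip,
            },
            index=plot_ids,
        )
    )

    # per-plot individual targets summing exactly to the total
    base = config.total_individuals // config.n_plots
    counts = np.full(config.n_plots, base, dtype=int)
    counts[: config.total_individuals - base * config.n_plots] += 1

    b = config.niche_breadth_mm
    weights = np.exp(
        -((precip[:, None] - optima.to_numpy()[None, :]) ** 2) / (2.0 * b * b)
    )
    row_sums = weights.sum(axis=1)
    if np.any(row_sums <= 0) or not np.all(np.isfinite(row_sums)):
        raise ValueError(
            "infeasible config: niche_breadth_mm too narrow for the gap "
            "between plot precipitation and the nearest species optimum"
        )
    abund = np.vstack(
        [
            rng.multinomial(counts[i], weights[i] / row_sums[i])
            for i in range(config.n_plots)
        ]
    )
    table = CommunityTable(pd.DataFrame(abund, index=plot_ids, columns=species))
    return tree, table, env
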