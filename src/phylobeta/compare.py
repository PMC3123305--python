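"""Statistical comparison machinery: Mantel tests, metric cross-correlation,
PCA of metric outputs, and confidence intervals over random polytomy
resolutions.

These implement the analysis layer that relates beta-diversity matrices to
environmental distance matrices (Mantel), asks which metrics are redundant
(Pearson correlation matrix, PCA of normalised metric outputs), and
propagates phylogenetic uncertainty from unresolved nodes (repeating the
Mantel analysis over many random resolutions and reporting percentile
intervals).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .communities import CommunityTable, EnvTable
from .trees import PairwiseMatrix, PhyloTree

__all__ = [
    "MantelResult",
    "mantel",
    "metric_correlations",
    "PcaResult",
    "pca_metrics",
    "resolution_ci",
]


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal (upper triangle)
    elements; ``p`` the permutation p-value with the +1 correction
    p = (1 + #{perm stat >= observed}) / (1 + n_perm), so the smallest
    attainable p is 1/(1 + n_perm).
    """

    r: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str


def _condensed_r(v1: np.ndarray, v2: np.ndarray) -> float:
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel(
    m1: PairwiseMatrix,
    m2: PairwiseMatrix,
    n_perm: int = 999,
    seed: int | None = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test of matrix correlation by row/column permutation.

    The null distribution is generated by simultaneously permuting rows and
    columns of ``m2`` (``n_perm`` times, seeded), or exhaustively over all
    non-identity label permutations when ``exact=True`` (only feasible for
    small matrices).  ``alternative`` is ``"greater"`` (default),
    ``"less"`` or ``"two-sided"``.
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share labels in identical order")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    n = m1.n
    if n < 3:
        raise ValueError("need at least 3 observations")
    iu = np.triu_indices(n, k=1)
    v1 = m1.values[iu]
    M2 = m2.values
    v2 = M2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero-variance matrix: Mantel r is undefined")
    r_obs = _condensed_r(v1, v2)

    # tolerance so permutations tied with the observed statistic count as
    # "at least as extreme" despite float round-off
    tol = 1e-12

    def stat(r):
        if alternative == "greater":
            return r >= r_obs - tol
        if alternative == "less":
            return r <= r_obs + tol
        return abs(r) >= abs(r_obs) - tol

    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            if perm == tuple(range(n)):
                continue
            p = np.asarray(perm)
            count += stat(_condensed_r(v1, M2[np.ix_(p, p)][iu]))
            total += 1
        return MantelResult(
            r=r_obs,
            p=(1 + count) / (1 + total),
            n_perm=total,
            seed=None,
            alternative=alternative,
        )

    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
    )
    V2 = M2[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
    v1c = v1 - v1.mean()
    V2c = V2 - V2.mean(axis=1, keepdims=True)
    r_perm = (V2c @ v1c) / (
        np.linalg.norm(v1c) * np.linalg.norm(V2c, axis=1)
    )
    count = int(np.sum(stat(r_perm)))
    return MantelResult(
        r=r_obs,
        p=(1 + count) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


def _wide(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long BetaResult table to (plot pair) x metric."""
    wide = results.pivot_table(
        index=["plot1", "plot2"], columns="metric", values="value", sort=False
    )
    if wide.isna().any().any():
        raise ValueError("all metrics must be computed on the identical pair set")
    return wide


def metric_correlations(results: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between metrics over plot pairs.

    ``results`` is the long table produced by
    :func:`phylobeta.metrics.all_pairs`; metrics must cover an identical
    set of plot pairs.
    """
    wide = _wide(results)
    if len(wide) < 3:
        raise ValueError("need at least 3 plot pairs")
    if (wide.std() == 0).any():
        bad = list(wide.columns[wide.std() == 0])
        raise ValueError(f"constant metric vector(s): {bad}")
    return wide.corr(method="pearson")


@dataclass
class PcaResult:
    """Loadings and explained variance of a PCA over metric outputs."""

    loadings: pd.DataFrame  # metrics x components
    explained: pd.Series  # proportion of variance per component
    cumulative: pd.Series


def pca_metrics(results: pd.DataFrame) -> PcaResult:
    """PCA of metric outputs across plot pairs (correlation matrix).

    Bounded similarities (PhyloSor) are first converted to dissimilarities
    as 1 - s; every metric vector is then z-scored, and the principal axes
    are the eigenvectors of the metric correlation matrix.  Because metric
    scales are incommensurate the correlation (not covariance) matrix is
    used.  Loading signs are arbitrary; the convention here makes the
    largest-magnitude loading of each component negative.
    """
    wide = _wide(results)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 metrics")
    if len(wide) < 3:
        raise ValueError("need at least 3 plot pairs")
    for m in wide.columns:
        if m in _metrics.SIMILARITY_METRICS:
            wide[m] = 1.0 - wide[m]
    if (wide.std() == 0).any():
        bad = list(wide.columns[wide.std() == 0])
        raise ValueError(f"constant metric vector(s): {bad}")
    corr = wide.corr().to_numpy()
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):  # sign convention
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] > 0:
            eigvec[:, j] *= -1.0
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    explained = pd.Series(eigval / eigval.sum(), index=comps, name="explained")
    return PcaResult(
        loadings=pd.DataFrame(eigvec, index=wide.columns, columns=comps),
        explained=explained,
        cumulative=explained.cumsum().rename("cumulative"),
    )


def _mantel_r_only(m1: PairwiseMatrix, m2: PairwiseMatrix) -> float:
    iu = np.triu_indices(m1.n, k=1)
    return _condensed_r(m1.values[iu], m2.values[iu])


def resolution_ci(
    tree: PhyloTree,
    table: CommunityTable,
    metrics,
    env: EnvTable,
    n_resolutions: int = 100,
    seed: int = 0,
    n_perm: int = 999,
) -> pd.DataFrame:
    """Mantel r point estimates with percentile CIs over random resolutions.

    The Mantel correlation of each metric with each environmental distance
    is computed on the input tree (point estimate, with a permutation p),
    then recomputed on ``n_resolutions`` random polytomy resolutions; the
    2.5 and 97.5 percentiles of the replicate r values are reported.  With
    zero-length resolution branches, patristic distances are unchanged, so
    only branch-sharing metrics (PhyloSor, UniFrac) can vary across
    replicates; a binary input tree yields zero-width intervals.
    """
    env_mats = env.env_distances()
    plots = table.plots
    metrics = list(metrics)
    rng = np.random.default_rng(seed)
    res_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_resolutions)]

    def metric_mats(t: PhyloTree) -> dict[str, PairwiseMatrix]:
        calc = _metrics.BetaCalculator(t, table)
        return {m: calc.pairwise_matrix(m) for m in metrics}

    point = metric_mats(tree)
    reps = [metric_mats(tree.resolve_polytomies(s)) for s in res_seeds]

    rows = []
    for m in metrics:
        for env_name, env_mat in env_mats.items():
            env_mat = env_mat.reordered(plots)
            res = mantel(point[m], env_mat, n_perm=n_perm, seed=seed)
            rs = np.array([_mantel_r_only(rep[m], env_mat) for rep in reps])
            rows.append(
                {
                    "metric": m,
                    "env": env_name,
                    "r": res.r,
                    "p": res.p,
                    "ci_low": float(np.percentile(rs, 2.5)),
                    "ci_high": float(np.percentile(rs, 97.5)),
                    "n_resolutions": n_resolutions,
                }
            )
    return pd.DataFrame(rows)
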