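import numpy as np
import pandas as pd
import pytest

from phylobeta import (
    BetaCalculator,
    CommunityTable,
    EnvTable,
    GradientConfig,
    PairwiseMatrix,
    all_pairs,
    mantel,
    metric_correlations,
    parse_newick,
    pca_metrics,
    resolution_ci,
    simulate_gradient,
)


def random_distance_matrix(rng, n, labels=None):
    M = rng.random((n, n))
    M = np.triu(M, 1)
    M = M + M.T
    labels = labels or [f"p{i}" for i in range(n)]
    return PairwiseMatrix(labels, M)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        m = random_distance_matrix(rng, 10)
        res = mantel(m, m, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_plus_one_correction_sets_minimum_p(self):
        rng = np.random.default_rng(1)
        m = random_distance_matrix(rng, 12)
        res = mantel(m, m, n_perm=99, seed=0)
        assert res.p >= 1 / 100

    def test_exhaustive_enumeration_matches_monte_carlo(self):
        """On a 4x4 matrix the 23 non-identity permutations are the exact
        null; the Monte-Carlo p must agree within sampling error."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            m1 = random_distance_matrix(rng, 4)
            m2 = random_distance_matrix(rng, 4)
            exact = mantel(m1, m2, exact=True)
            assert exact.n_perm == 23
            mc = mantel(m1, m2, n_perm=999, seed=trial)
            se = np.sqrt(exact.p * (1 - exact.p) / 999)
            assert abs(mc.p - exact.p) < max(2 * se, 0.02)

    def test_invariant_under_common_relabeling(self):
        rng = np.random.default_rng(7)
        m1 = random_distance_matrix(rng, 8)
        m2 = random_distance_matrix(rng, 8)
        perm = rng.permutation(8)
        labels = [m1.labels[i] for i in perm]
        r1 = mantel(m1, m2, n_perm=99, seed=0).r
        r2 = mantel(m1.reordered(labels), m2.reordered(labels), n_perm=99, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        m1 = random_distance_matrix(rng, 5)
        m2 = random_distance_matrix(rng, 5, labels=[f"q{i}" for i in range(5)])
        with pytest.raises(ValueError, match="labels"):
            mantel(m1, m2)

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(3)
        m1 = random_distance_matrix(rng, 5)
        flat = PairwiseMatrix(m1.labels, np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="variance"):
            mantel(m1, flat)

    def test_matches_skbio_reference(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(11)
        n = 12
        base = rng.random((n, 2))
        m1 = np.linalg.norm(base[:, None] - base[None, :], axis=-1)
        m2 = m1 + rng.random((n, n)) * 0.3
        m2 = 0.5 * (m2 + m2.T)
        np.fill_diagonal(m2, 0.0)
        labels = [f"p{i}" for i in range(n)]
        ours = mantel(
            PairwiseMatrix(labels, m1), PairwiseMatrix(labels, m2), n_perm=999, seed=0
        )
        ref_r, ref_p, _ = skbio_mantel(
            DistanceMatrix(m1, labels), DistanceMatrix(m2, labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(ref_r), abs=1e-12)
        assert ours.p == pytest.approx(float(ref_p), abs=0.05)


@pytest.fixture(scope="module")
def gradient_results():
    tree, table, env = simulate_gradient(
        GradientConfig(n_plots=12, n_species=40, total_individuals=2400, seed=6)
    )
    results = all_pairs(tree, table)
    return tree, table, env, results


class TestMetricCorrelations:
    def test_raod_equals_weighted_dpw(self, gradient_results):
        _, _, _, results = gradient_results
        corr = metric_correlations(results)
        assert corr.loc["raod", "dpww"] == pytest.approx(1.0)

    def test_diagonal_is_one(self, gradient_results):
        _, _, _, results = gradient_results
        corr = metric_correlations(results)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_phylosor_unifrac_anticorrelated(self, gradient_results):
        # similarity versus dissimilarity orientation
        _, _, _, results = gradient_results
        corr = metric_correlations(results)
        assert corr.loc["phylosor", "unifrac"] < 0

    def test_constant_metric_rejected(self):
        df = pd.DataFrame(
            {
                "plot1": ["a", "a", "b"],
                "plot2": ["b", "c", "c"],
                "metric": ["m1"] * 3,
                "mode": ["presence"] * 3,
                "value": [1.0, 1.0, 1.0],
            }
        )
        df2 = df.copy()
        df2["metric"] = "m2"
        df2["value"] = [0.1, 0.5, 0.9]
        with pytest.raises(ValueError, match="constant"):
            metric_correlations(pd.concat([df, df2]))


class TestPca:
    def test_perfectly_correlated_pair_loads_on_one_axis(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")]
        x = np.array([0.1, 0.5, 0.9, 0.3])
        rows = []
        for (p1, p2), v in zip(pairs, x):
            rows.append((p1, p2, "m1", "presence", v))
            rows.append((p1, p2, "m2", "presence", 3 * v + 1))
        res = pca_metrics(
            pd.DataFrame(rows, columns=["plot1", "plot2", "metric", "mode", "value"])
        )
        assert res.explained["PC1"] == pytest.approx(1.0)

    def test_variance_fractions_complete_and_loadings_orthonormal(self, gradient_results):
        _, _, _, results = gradient_results
        res = pca_metrics(results)
        assert res.cumulative.iloc[-1] == pytest.approx(1.0, abs=1e-9)
        L = res.loadings.values
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert res.explained.is_monotonic_decreasing

    def test_sign_convention_largest_loading_negative(self, gradient_results):
        _, _, _, results = gradient_results
        res = pca_metrics(results)
        for comp in res.loadings.columns:
            v = res.loadings[comp].values
            assert v[np.argmax(np.abs(v))] <= 0

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=20)
        rows = []
        pairs = [(f"p{i}", f"p{j}") for i in range(7) for j in range(i + 1, 7)][:20]
        vals = {
            "m1": base + rng.normal(scale=0.3, size=20),
            "m2": -base + rng.normal(scale=0.3, size=20),
            "m3": rng.normal(size=20),
        }
        for m, v in vals.items():
            for (p1, p2), x in zip(pairs, v):
                rows.append((p1, p2, m, "presence", x))
        res = pca_metrics(
            pd.DataFrame(rows, columns=["plot1", "plot2", "metric", "mode", "value"])
        )
        X = np.column_stack([vals[m] for m in ["m1", "m2", "m3"]])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        C = np.corrcoef(X, rowvar=False)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        np.testing.assert_allclose(
            np.sort(res.explained.values), np.sort(w[order] / w.sum()), atol=1e-9
        )
        for j in range(3):
            got = res.loadings.values[:, j]
            ref = v[:, order[j]]
            assert min(
                np.abs(got - ref).max(), np.abs(got + ref).max()
            ) == pytest.approx(0.0, abs=1e-8)

        # second independent route: sklearn PCA on the z-scored columns
        from sklearn.decomposition import PCA

        skl = PCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            res.explained.values, skl.explained_variance_ratio_, atol=1e-9
        )
        for j in range(3):
            got = res.loadings.values[:, j]
            ref = skl.components_[j]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8


@pytest.fixture(scope="module")
def polytomy_world():
    # a tree with two polytomies over 8 tips + matching plots/env
    tree = parse_newick("((a:1,b:1,c:1,d:1):1,(e:1,f:1,g:1,h:1):1);")
    rng = np.random.default_rng(8)
    plots = [f"p{i}" for i in range(6)]
    df = pd.DataFrame(
        rng.integers(0, 6, size=(6, 8)), index=plots, columns=tree.tip_labels
    )
    df.iloc[:, 0] += 1  # keep plots non-empty
    table = CommunityTable(df)
    env = EnvTable(
        pd.DataFrame(
            {
                "lat": np.linspace(13, 15, 6),
                "lon": 75.0,
                "alt_m": rng.uniform(50, 1000, 6),
                "precip_mm": np.linspace(800, 8000, 6),
            },
            index=plots,
        )
    )
    return tree, table, env


class TestResolutionCI:
    def test_binary_tree_has_zero_width_intervals(self, polytomy_world):
        _, table, env = polytomy_world
        tree = parse_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        )
        out = resolution_ci(tree, table, ["phylosor"], env, n_resolutions=10, seed=0, n_perm=99)
        assert np.allclose(out["ci_low"], out["ci_high"])
        assert np.allclose(out["ci_low"], out["r"])

    def test_replicate_count_and_layout(self, polytomy_world):
        tree, table, env = polytomy_world
        out = resolution_ci(
            tree, table, ["phylosor", "dpw"], env, n_resolutions=100, seed=1, n_perm=99
        )
        # one row per metric per environmental distance
        assert len(out) == 2 * 3
        assert (out["n_resolutions"] == 100).all()
        assert set(out["env"]) == {"geographic_km", "altitude_m", "precip_mm"}

    def test_distance_based_metrics_invariant_to_resolution(self, polytomy_world):
        """Zero-length insertions leave patristic distances, hence Dnn/Dpw/
        Rao Mantel correlations, identical across replicates."""
        tree, table, env = polytomy_world
        out = resolution_ci(
            tree, table, ["dnn", "dpw", "raod", "raoh"], env,
            n_resolutions=25, seed=3, n_perm=99,
        )
        assert np.allclose(out["ci_low"], out["ci_high"], atol=1e-12)
        assert np.allclose(out["ci_low"], out["r"], atol=1e-12)
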