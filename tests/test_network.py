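"""SparCC, network construction, node statistics, niche breadth, Mantel."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rumenrhythm.errors import (
    AlignmentError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from rumenrhythm.network import (
    CorrelationEstimate,
    bray_curtis,
    build_network,
    detect_modules,
    feature_rhythm_correlation,
    levins_niche_breadth,
    mantel,
    node_features,
    sparcc,
    sparcc_bootstrap,
    zi_pi,
)


def close(basis: np.ndarray) -> np.ndarray:
    return basis / basis.sum(axis=1, keepdims=True)


def sparcc_oracle(fractions: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Textbook one-pass SparCC written independently of the implementation:
    explicit loops over the log-ratio variances and a dense solve, no
    exclusion iterations."""
    x = fractions + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    d = logx.shape[1]
    T = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            T[i, j] = np.var(logx[:, i] - logx[:, j], ddof=1)
    M = np.ones((d, d))
    np.fill_diagonal(M, d - 1)
    omega = np.linalg.solve(M, T.sum(axis=1))
    r = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            r[i, j] = (omega[i] + omega[j] - T[i, j]) / (2 * np.sqrt(omega[i] * omega[j]))
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1, 1)


class TestSparcc:
    def test_unit_diagonal_and_symmetry(self, rng):
        frac = close(np.exp(rng.normal(0, 1, (50, 6))))
        r = sparcc(frac).r.to_numpy()
        np.testing.assert_array_equal(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T, atol=1e-9)

    def test_independent_basis_gives_near_zero_correlations(self):
        rng = np.random.default_rng(0)
        frac = close(np.exp(rng.normal(0, 1, (500, 5))))
        r = sparcc(frac).r.to_numpy()
        off = r[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_matches_textbook_oracle_before_exclusion(self):
        # Exclusion never triggers on a null matrix (all |r| below threshold),
        # so the implementation must agree with the independent step-by-step
        # oracle exactly.
        rng = np.random.default_rng(42)
        frac = close(np.exp(rng.normal(0, 1, (200, 6))))
        ours = sparcc(frac).r.to_numpy()
        oracle = sparcc_oracle(frac)
        if np.abs(oracle[~np.eye(6, dtype=bool)]).max() <= 0.1:
            np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_recovers_known_basis_pair(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, 500)
        x2 = 0.8 * z + np.sqrt(1 - 0.64) * rng.normal(0, 1, 500)
        frac = close(np.exp(np.column_stack([z, x2, rng.normal(0, 1, (500, 3))])))
        r = sparcc(frac).r.to_numpy()
        assert r[0, 1] == pytest.approx(0.8, abs=0.1)
        null = ~np.eye(5, dtype=bool)
        null[0, 1] = null[1, 0] = False
        assert np.abs(r[null]).max() < 0.15

    def test_beats_pearson_under_dominant_taxon_closure(self):
        rng = np.random.default_rng(1)
        basis = np.exp(rng.normal(0, 1, (500, 5)))
        basis[:, 0] *= np.exp(2)  # one dominant rhythm-free taxon drives closure
        frac = close(basis)
        sp = sparcc(frac).r.to_numpy()
        pe = np.corrcoef(frac.T)
        off = ~np.eye(5, dtype=bool)
        assert np.abs(sp[off]).mean() < np.abs(pe[off]).mean()

    def test_taxon_order_permutation_invariance(self, rng):
        frac = pd.DataFrame(close(np.exp(rng.normal(0, 1, (100, 6)))),
                            columns=[f"t{i}" for i in range(6)])
        r1 = sparcc(frac).r
        perm = ["t3", "t0", "t5", "t1", "t4", "t2"]
        r2 = sparcc(frac[perm]).r
        np.testing.assert_allclose(r1.loc[perm, perm].to_numpy(), r2.to_numpy(), atol=1e-9)

    def test_too_few_taxa_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            sparcc(close(np.exp(rng.normal(0, 1, (50, 4)))))

    def test_zero_variance_taxon_dropped(self, rng):
        frac = close(np.exp(rng.normal(0, 1, (50, 6))))
        frac[:, 2] = frac[:, 2].mean()  # constant column (pre-closure scaling)
        frac = pd.DataFrame(close(frac), columns=[f"t{i}" for i in range(6)])
        frac["t2"] = 0.1
        est = sparcc(frac)
        assert "t2" in est.dropped and "t2" not in est.taxa


class TestSparccBootstrap:
    def test_perfectly_coupled_pair_at_floor(self, rng):
        x = np.exp(rng.normal(0, 1, 500))
        frac = close(np.column_stack([x, 3 * x, np.exp(rng.normal(0, 1, (500, 3)))]))
        est = sparcc_bootstrap(frac, n_boot=100, rng=np.random.default_rng(5))
        assert est.p.iloc[0, 1] == pytest.approx(1 / 101)

    def test_p_bounds(self, rng):
        frac = close(np.exp(rng.normal(0, 1, (40, 5))))
        est = sparcc_bootstrap(frac, n_boot=50, rng=rng)
        p = est.p.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(p >= 1 / 51) and np.all(p <= 1.0)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(12):
            frac = close(np.exp(rng.normal(0, 1, (500, 5))))
            est = sparcc_bootstrap(frac, n_boot=100, rng=rng)
            ps.extend(est.p.to_numpy()[np.triu_indices(5, 1)])
        ks = stats.kstest(np.array(ps), "uniform").statistic
        assert ks < 0.15


def est_from_pairs(taxa, pairs):
    """Build a CorrelationEstimate from explicit (i, j, r, p) tuples."""
    r = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
    p = pd.DataFrame(np.ones((len(taxa), len(taxa))), index=taxa, columns=taxa)
    np.fill_diagonal(p.values, 0.0)
    for a, b, rv, pv in pairs:
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return CorrelationEstimate(taxa=list(taxa), r=r, p=p, n_bootstrap=100)


class TestBuildNetwork:
    def test_threshold_filtering(self):
        est = est_from_pairs(
            list("abcde"),
            [("a", "b", 0.5, 0.01), ("a", "c", 0.25, 0.001), ("b", "c", -0.4, 0.2)],
        )
        net = build_network(est)
        assert net.graph.number_of_edges() == 1
        assert net.graph.has_edge("a", "b")
        assert net.graph.number_of_nodes() == 5  # isolated nodes retained

    def test_boundary_r_excluded(self):
        est = est_from_pairs(list("abcde"), [("a", "b", 0.3, 0.001)])
        assert build_network(est).graph.number_of_edges() == 0

    def test_permissive_thresholds_keep_everything(self):
        est = est_from_pairs(list("abcde"), [("a", "b", 0.05, 0.9), ("c", "d", -0.01, 0.99)])
        net = build_network(est, r_threshold=0.0, p_threshold=1.01)
        assert net.graph.number_of_edges() == 2


class TestNodeFeatures:
    def test_path_graph(self):
        est = est_from_pairs(list("abc") + ["d", "e"], [("a", "b", 0.5, 0.01), ("b", "c", 0.5, 0.01)])
        net = build_network(est)
        f = node_features(net)
        assert f.loc["b", "degree"] == 2
        assert f.loc["b", "betweenness"] == pytest.approx(1.0)
        assert f.loc["b", "closeness"] == pytest.approx(1.0)
        assert f.loc["a", "closeness"] == pytest.approx(2 / 3)
        assert f.loc["d", "closeness"] == 0.0 and f.loc["d", "degree"] == 0

    def test_triangle_has_zero_betweenness(self):
        est = est_from_pairs(
            list("abcde"),
            [("a", "b", 0.5, 0.01), ("b", "c", 0.5, 0.01), ("a", "c", 0.5, 0.01)],
        )
        f = node_features(build_network(est))
        assert (f.loc[["a", "b", "c"], "betweenness"] == 0).all()

    def test_disjoint_edges_component_restricted_closeness(self):
        est = est_from_pairs(
            list("abcde"), [("a", "b", 0.5, 0.01), ("c", "d", 0.5, 0.01)]
        )
        f = node_features(build_network(est))
        assert (f.loc[["a", "b", "c", "d"], "closeness"] == 1.0).all()

    def test_weighted_degree_sums_abs_r(self):
        est = est_from_pairs(
            list("abcde"), [("a", "b", 0.5, 0.01), ("a", "c", -0.4, 0.01)]
        )
        f = node_features(build_network(est))
        assert f.loc["a", "weighted_degree"] == pytest.approx(0.9)


class TestModulesAndRoles:
    def _two_cliques(self):
        g = nx.Graph()
        left, right = list("abcd"), list("wxyz")
        for grp in (left, right):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    g.add_edge(u, v, r=0.5, weight=0.5)
        g.add_edge("a", "w", r=0.5, weight=0.5)
        from rumenrhythm.network import MicrobialNetwork

        return MicrobialNetwork(graph=g, r_threshold=0.3, p_threshold=0.05), left, right

    def test_two_cliques_recovered(self):
        net, left, right = self._two_cliques()
        modules, q = detect_modules(net)
        assert len({modules[n] for n in left}) == 1
        assert len({modules[n] for n in right}) == 1
        assert modules["a"] != modules["w"]
        assert q > 0.3

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.5, "weight")
        from rumenrhythm.network import MicrobialNetwork

        net = MicrobialNetwork(graph=g, r_threshold=0.3, p_threshold=0.05)
        modules, q = detect_modules(net)
        assert len(set(modules.values())) == 1 and q == pytest.approx(0.0)

    def test_deterministic(self):
        net1, *_ = self._two_cliques()
        net2, *_ = self._two_cliques()
        assert detect_modules(net1) == detect_modules(net2)

    def test_edgeless_network(self):
        from rumenrhythm.network import MicrobialNetwork

        g = nx.empty_graph(4)
        net = MicrobialNetwork(graph=g, r_threshold=0.3, p_threshold=0.05)
        modules, q = detect_modules(net)
        assert len(set(modules.values())) == 4 and q == 0.0

    def test_zi_pi_values_and_roles(self):
        net, left, right = self._two_cliques()
        modules, _ = detect_modules(net)
        table = zi_pi(net, modules)
        # 'b' has all 3 edges inside its module -> Pi = 0.
        assert table.loc["b", "pi"] == pytest.approx(0.0)
        # Bridge endpoints have 3 within + 1 across of 4 edges: Pi = 1 - (9+1)/16.
        assert table.loc["a", "pi"] == pytest.approx(1 - (3 / 4) ** 2 - (1 / 4) ** 2)
        assert (table["pi"] <= 1 - 1 / len(set(modules.values())) + 1e-9).all()
        assert set(table["role"]) <= {"peripheral", "connector", "module_hub", "network_hub"}

    def test_half_split_pi(self):
        g = nx.Graph()
        g.add_edges_from([("n", "a1"), ("n", "a2"), ("n", "b1"), ("n", "b2")])
        nx.set_edge_attributes(g, 1.0, "weight")
        from rumenrhythm.network import MicrobialNetwork

        net = MicrobialNetwork(graph=g, r_threshold=0, p_threshold=1)
        modules = {"n": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        table = zi_pi(net, modules)
        assert table.loc["n", "pi"] == pytest.approx(0.5)

    def test_equal_within_degree_gives_zero_zi_peripheral(self):
        g = nx.cycle_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        from rumenrhythm.network import MicrobialNetwork

        net = MicrobialNetwork(graph=g, r_threshold=0, p_threshold=1)
        modules = {n: 0 for n in g.nodes}
        table = zi_pi(net, modules)
        assert (table["zi"] == 0).all()
        assert (table["role"] == "peripheral").all()


class TestNicheBreadth:
    def test_uniform_taxon_has_breadth_n(self):
        table = pd.DataFrame({"t": [0.2] * 4, "u": [0.8] * 4}, index=list("abcd"))
        comm = pd.Series(list("abcd"), index=list("abcd"))
        out = {nb.taxon_id: nb for nb in levins_niche_breadth(table, comm)}
        assert out["t"].b == pytest.approx(4.0)
        assert out["t"].n_communities == 4

    def test_single_community_taxon_has_breadth_one(self):
        table = pd.DataFrame({"t": [1.0, 0.0, 0.0]}, index=list("abc"))
        comm = pd.Series(list("abc"), index=list("abc"))
        assert levins_niche_breadth(table, comm)[0].b == pytest.approx(1.0)

    def test_even_split_between_two_communities(self):
        table = pd.DataFrame({"t": [0.3, 0.3]}, index=["s1", "s2"])
        comm = pd.Series(["c1", "c2"], index=["s1", "s2"])
        assert levins_niche_breadth(table, comm)[0].b == pytest.approx(2.0)

    def test_bounds(self, rng):
        table = pd.DataFrame(rng.random((12, 6)) + 0.01, index=[f"s{i}" for i in range(12)])
        comm = pd.Series(np.repeat(["c1", "c2", "c3", "c4"], 3), index=table.index)
        for nb in levins_niche_breadth(table, comm):
            assert 1.0 - 1e-9 <= nb.b <= 4.0 + 1e-9

    def test_all_zero_taxon_rejected(self):
        table = pd.DataFrame({"t": [0.0, 0.0]}, index=["s1", "s2"])
        comm = pd.Series(["c1", "c2"], index=["s1", "s2"])
        with pytest.raises(UndefinedStatisticError):
            levins_niche_breadth(table, comm)


class TestBrayCurtisMantel:
    def test_bray_curtis_extremes(self):
        table = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]], index=list("abc"))
        d = bray_curtis(table)
        assert d.loc["a", "b"] == pytest.approx(1.0)
        assert d.loc["a", "c"] == pytest.approx(0.0)

    def test_mantel_identical_matrices_at_floor(self, rng):
        d = bray_curtis(pd.DataFrame(rng.random((10, 6)), index=[f"s{i}" for i in range(10)]))
        r, p = mantel(d, d.copy(), permutations=999, rng=np.random.default_rng(2))
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_mantel_agrees_with_skbio(self, rng):
        """Cross-check r and permutation p against scikit-bio's Mantel."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        ids = [f"s{i}" for i in range(10)]
        d1 = bray_curtis(pd.DataFrame(rng.random((10, 5)), index=ids))
        d2 = bray_curtis(pd.DataFrame(rng.random((10, 5)), index=ids))
        r_ours, p_ours = mantel(d1, d2, permutations=999, rng=np.random.default_rng(0))
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(d1.to_numpy(), ids),
            DistanceMatrix(d2.to_numpy(), ids),
            method="spearman",
            permutations=999,
            alternative="two-sided",
        )
        assert r_ours == pytest.approx(float(r_ref), abs=1e-9)
        assert p_ours == pytest.approx(float(p_ref), abs=0.05)

    def test_mantel_null_calibration(self):
        rng = np.random.default_rng(7)
        nonsig = 0
        for _ in range(100):
            ids = [f"s{i}" for i in range(12)]
            d1 = bray_curtis(pd.DataFrame(rng.random((12, 8)), index=ids))
            d2 = bray_curtis(pd.DataFrame(rng.random((12, 8)), index=ids))
            _, p = mantel(d1, d2, permutations=199, rng=rng)
            nonsig += p > 0.05
        assert nonsig >= 90

    def test_mismatched_samples_rejected(self, rng):
        d1 = bray_curtis(pd.DataFrame(rng.random((5, 3)), index=list("abcde")))
        d2 = bray_curtis(pd.DataFrame(rng.random((5, 3)), index=list("fghij")))
        with pytest.raises(AlignmentError):
            mantel(d1, d2)


class TestFeatureRhythmCorrelation:
    def test_identical_and_reversed(self):
        idx = [f"t{i}" for i in range(6)]
        feats = pd.DataFrame({"degree": [1, 2, 3, 4, 5, 6]}, index=idx)
        params = pd.DataFrame(
            {"amplitude": [1, 2, 3, 4, 5, 6], "mesor": [6, 5, 4, 3, 2, 1]}, index=idx
        )
        out = feature_rhythm_correlation(feats, params).set_index("parameter")
        assert out.loc["amplitude", "rho"] == pytest.approx(1.0)
        assert out.loc["mesor", "rho"] == pytest.approx(-1.0)

    def test_constant_feature_flagged(self):
        idx = list("abc")
        feats = pd.DataFrame({"degree": [2, 2, 2]}, index=idx)
        params = pd.DataFrame({"amplitude": [1, 2, 3]}, index=idx)
        out = feature_rhythm_correlation(feats, params)
        assert out["undefined"].all() and out["rho"].isna().all()

    def test_too_few_shared_taxa(self):
        feats = pd.DataFrame({"degree": [1, 2]}, index=["a", "b"])
        params = pd.DataFrame({"amp": [1, 2]}, index=["a", "b"])
        with pytest.raises(InsufficientDataError):
            feature_rhythm_correlation(feats, params)
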