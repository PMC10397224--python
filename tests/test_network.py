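import numpy as np
import pandas as pd
import pytest

import craniodev as cd
from craniodev import network as net


def block_tom(sizes, within=0.8, between=0.05, rng=None):
    """Synthetic TOM with planted diagonal blocks."""
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start : start + s, start : start + s] = within
        start += s
    if rng is not None:
        noise = rng.normal(0, 0.01, size=(n, n))
        t = t + (noise + noise.T) / 2
    np.fill_diagonal(t, 1.0)
    genes = [f"g{i:04d}" for i in range(n)]
    return pd.DataFrame(t, index=genes, columns=genes)


class TestAdjacency:
    def test_closed_forms(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        expr = pd.DataFrame(
            [base, base, -base, rng.normal(size=6)],
            index=["a", "b", "c", "d"],
        )
        adj = net.signed_adjacency(expr, beta=18)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_value(self):
        assert ((1 + 0) / 2) ** 18 == pytest.approx(3.8147e-6, rel=1e-4)

    def test_constant_genes_dropped(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 3.0], "s3": [1.0, 4.0]}, index=["flat", "ok"]
        )
        adj = net.signed_adjacency(expr, beta=2)
        assert list(adj.index) == ["ok"]

    def test_symmetry_and_range_random(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 10)))
        adj = net.signed_adjacency(expr, beta=6).to_numpy()
        assert np.allclose(adj, adj.T)
        assert adj.min() >= 0 and adj.max() <= 1.0 + 1e-12


class TestScaleFree:
    def test_power_law_degrees_fit_well(self):
        # exact power law: ten distinct degree values, one per bin, with
        # frequencies n(k) proportional to k^-2 -> log-log collinear
        ks = 50.0 * np.arange(1, 11)
        counts = np.round(1e6 * ks**-2.0).astype(int)
        k = np.repeat(ks, counts)
        a = np.outer(k, k) / k.sum()
        np.fill_diagonal(a, 0.0)
        r2 = net.scale_free_fit(pd.DataFrame(a), n_bins=10)
        assert r2 >= 0.99

    def test_constant_degrees_missing(self):
        adj = pd.DataFrame(np.full((5, 5), 0.3))
        assert np.isnan(net.scale_free_fit(adj))

    def test_bin_doubling_stability(self):
        i = np.arange(1, 1001)
        k = 100.0 * i ** (-0.7)
        adj = pd.DataFrame(np.outer(k, k) / k.sum())
        r10 = net.scale_free_fit(adj, n_bins=10)
        r20 = net.scale_free_fit(adj, n_bins=20)
        assert abs(r10 - r20) <= 0.05


class TestTom:
    def test_two_gene_closed_form(self):
        for x in (0.2, 0.5, 0.9):
            adj = pd.DataFrame([[1.0, x], [x, 1.0]], index=["a", "b"], columns=["a", "b"])
            tom = net.topological_overlap(adj)
            assert tom.loc["a", "b"] == pytest.approx(x)

    def test_three_gene_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = net.topological_overlap(pd.DataFrame(a))
        assert tom.iloc[0, 1] == pytest.approx(0.5)

    def test_identity_adjacency_gives_zero_overlap(self):
        tom = net.topological_overlap(pd.DataFrame(np.eye(4)))
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_symmetry_range_and_unit_diagonal(self, rng):
        r = rng.uniform(-1, 1, size=(20, 20))
        r = (r + r.T) / 2
        a = ((1 + r) / 2) ** 6
        np.fill_diagonal(a, 1.0)
        tom = net.topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0 and tom.max() <= 1.0 + 1e-9


class TestDetectAndMerge:
    def test_two_planted_blocks_recovered(self, rng):
        tom = block_tom([60, 40], rng=rng)
        labels = net.detect_modules(tom, net.NetworkParams(min_module_size=20))
        assert set(labels) == {1, 2}
        assert labels.iloc[:60].nunique() == 1 and labels.iloc[60:].nunique() == 1

    def test_min_size_larger_than_network_unassigns_all(self):
        tom = block_tom([10, 10])
        labels = net.detect_modules(tom, net.NetworkParams(min_module_size=100))
        assert (labels == 0).all()

    def test_merge_rule_on_eigengene_correlation(self, rng):
        t = np.linspace(0, 1, 12)
        u = np.sin(2 * np.pi * t)
        genes, profiles = [], []
        for i in range(10):
            genes.append(f"a{i}")
            profiles.append(u + rng.normal(0, 0.05, 12))
        for i in range(10):
            genes.append(f"b{i}")
            profiles.append(0.97 * u + rng.normal(0, 0.05, 12))  # cor ~ 0.9+
        expr = pd.DataFrame(profiles, index=genes)
        labels = pd.Series([1] * 10 + [2] * 10, index=genes)
        merged = net.merge_modules(expr, labels, merge_height=0.18)
        assert merged.nunique() == 1

        v = rng.normal(size=12)  # unrelated profile -> low eigengene cor
        profiles2 = profiles[:10] + [v + rng.normal(0, 0.05, 12) for _ in range(10)]
        expr2 = pd.DataFrame(profiles2, index=genes)
        merged2 = net.merge_modules(expr2, labels, merge_height=0.18)
        assert merged2.nunique() == 2

    def test_merge_is_idempotent(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 10)), index=[f"g{i}" for i in range(30)])
        labels = pd.Series([1] * 10 + [2] * 10 + [3] * 10, index=expr.index)
        once = net.merge_modules(expr, labels, 0.18)
        twice = net.merge_modules(expr, once, 0.18)
        assert once.equals(twice)

    def test_merged_configuration_satisfies_height(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 15)), index=[f"g{i}" for i in range(60)])
        labels = pd.Series(np.repeat([1, 2, 3, 4, 5, 6], 10), index=expr.index)
        merged = net.merge_modules(expr, labels, 0.3)
        eig = net.module_eigengene(expr, merged)
        if len(eig) >= 2:
            c = np.corrcoef(eig.to_numpy())
            np.fill_diagonal(c, -1)
            assert 1 - c.max() >= 0.3


class TestEigengene:
    def test_identical_profiles_give_common_profile(self):
        t = np.linspace(0, 1, 8)
        u = np.sin(2 * np.pi * t) + 3
        expr = pd.DataFrame([u, u, u], index=["a", "b", "c"])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig = net.module_eigengene(expr, labels).loc[1].to_numpy()
        z = (u - u.mean()) / u.std()
        cor = np.corrcoef(eig, z)[0, 1]
        assert cor == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_variance_explained_beats_any_member(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 9)), index=[f"g{i}" for i in range(12)])
        labels = pd.Series([1] * 12, index=expr.index)
        eig = net.module_eigengene(expr, labels).loc[1].to_numpy()
        x = expr.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        var_eig = ((z @ eig) ** 2).sum()
        for i in range(12):
            d = z[i] / np.linalg.norm(z[i])
            assert var_eig >= ((z @ d) ** 2).sum() - 1e-9

    def test_sign_aligned_with_mean_profile(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            expr = pd.DataFrame(r.normal(size=(8, 10)), index=[f"g{i}" for i in range(8)])
            labels = pd.Series([1] * 8, index=expr.index)
            eig = net.module_eigengene(expr, labels).loc[1].to_numpy()
            x = expr.to_numpy()
            z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
            assert np.dot(eig, z.mean(axis=0)) >= 0


class TestConnectivityAndHubs:
    def test_hand_summed_kwithin(self):
        a = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        adj = pd.DataFrame(a, index=["a", "b", "c"], columns=["a", "b", "c"])
        labels = pd.Series([1, 1, 1], index=adj.index)
        conn = net.intramodular_connectivity(adj, labels)
        assert list(conn["kWithin"]) == pytest.approx([0.6, 0.8, 1.0])
        assert list(conn["kTotal"]) == pytest.approx([0.6, 0.8, 1.0])

    def test_unassigned_gene_has_zero_kwithin(self):
        adj = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("abc"))
        labels = pd.Series([1, 1, 0], index=adj.index)
        conn = net.intramodular_connectivity(adj, labels)
        assert conn.loc["c", "kWithin"] == 0
        assert conn.loc["c", "kTotal"] == pytest.approx(1.0)
        assert (conn["kWithin"] <= conn["kTotal"] + 1e-12).all()

    def test_hub_count_ceiling_rule(self, rng):
        conn = pd.DataFrame(
            {"module": 1, "kTotal": rng.random(26626), "kWithin": rng.random(26626)},
            index=[f"g{i:05d}" for i in range(26626)],
        )
        assert len(net.select_hubs(conn, 0.10)) == 2663
        small = conn.iloc[:10]
        assert len(net.select_hubs(small, 0.10)) == 1

    def test_all_equal_connectivity_deterministic(self):
        conn = pd.DataFrame(
            {"module": 1, "kTotal": 1.0, "kWithin": 1.0}, index=["g3", "g1", "g2", "g4"]
        )
        assert net.select_hubs(conn, 0.5) == {"g1", "g2"}


class TestModuleGraph:
    def test_inclusive_positive_threshold(self, rng):
        t = np.linspace(0, 2 * np.pi, 20)
        z1 = np.sin(t)
        e2 = 0.5 * z1 + rng.normal(0, 0.5, 20)
        eig = pd.DataFrame([z1, e2, -z1], index=[1, 2, 3])
        c12 = np.corrcoef(eig.to_numpy())[0, 1]
        assert c12 > 0
        # threshold equal to the correlation itself: edge kept (>= inclusive)
        edges = net.module_graph(eig, min_cor=c12)
        pairs = set(map(tuple, edges[["module_a", "module_b"]].to_numpy()))
        assert (1, 2) in pairs
        assert (1, 3) not in pairs  # strongly negative correlation excluded
        # nudging the threshold above the correlation removes the edge
        edges2 = net.module_graph(eig, min_cor=c12 + 1e-12)
        pairs2 = set(map(tuple, edges2[["module_a", "module_b"]].to_numpy()))
        assert (1, 2) not in pairs2

    def test_single_module_empty(self):
        eig = pd.DataFrame([np.sin(np.linspace(0, 6, 10))], index=[1])
        assert len(net.module_graph(eig)) == 0


class TestPipelineRecovery:
    def test_planted_module_recovery_ari(self):
        """Planted modules recovered with ARI >= 0.8 over 20 seeds at the
        generator's default signal-to-noise ratio."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            params = cd.SimParams(seed=seed, n_genes=600, n_modules=4)
            tc, truth = cd.simulate_module_expression(params)
            expr = cd.log_transform(tc)
            labels, _, _, _, _ = net.build_network(expr, net.NetworkParams(min_module_size=50))
            true = pd.Series(truth.module_labels_true).loc[labels.index]
            aris.append(adjusted_rand_score(true, labels))
        assert np.mean(aris) >= 0.8

    def test_recovery_degrades_with_noise(self):
        from sklearn.metrics import adjusted_rand_score

        means = []
        for snr in (4.0, 1.0, 0.25):
            aris = []
            for seed in range(5):
                params = cd.SimParams(seed=seed, n_genes=400, n_modules=4, module_snr=snr)
                tc, truth = cd.simulate_module_expression(params)
                labels, _, _, _, _ = net.build_network(
                    cd.log_transform(tc), net.NetworkParams(min_module_size=30)
                )
                true = pd.Series(truth.module_labels_true).loc[labels.index]
                aris.append(adjusted_rand_score(true, labels))
            means.append(np.mean(aris))
        assert means[0] >= means[1] >= means[2]

    def test_pipeline_determinism(self):
        params = cd.SimParams(seed=5, n_genes=300, n_modules=3)
        tc, _ = cd.simulate_module_expression(params)
        expr = cd.log_transform(tc)
        l1, e1, c1, h1, _ = net.build_network(expr, net.NetworkParams(min_module_size=30))
        l2, e2, c2, h2, _ = net.build_network(expr, net.NetworkParams(min_module_size=30))
        assert l1.equals(l2) and h1 == h2
        pd.testing.assert_frame_equal(e1, e2)
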