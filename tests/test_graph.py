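import itertools

import numpy as np
import pytest

from dynconn.graph import (
    SparsityRamp,
    auc_over_ramp,
    global_metrics,
    nodal_metrics,
    small_world,
    temporal_variability,
    threshold_by_sparsity,
)


# --- independent brute-force oracle (exhaustive, small graphs only) ---------

def brute_distances(adj):
    """Floyd-Warshall by hand."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def brute_metrics(adj):
    n = adj.shape[0]
    d = brute_distances(adj)
    eg = sum(
        1.0 / d[i, j]
        for i, j in itertools.permutations(range(n), 2)
        if np.isfinite(d[i, j])
    ) / (n * (n - 1))
    finite = [d[i, j] for i, j in itertools.permutations(range(n), 2)
              if np.isfinite(d[i, j])]
    cp = float(np.mean(finite)) if finite else 0.0
    cc_terms = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            cc_terms.append(0.0)
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
        cc_terms.append(2.0 * links / (k * (k - 1)))
    eloc_terms = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            eloc_terms.append(0.0)
            continue
        sub = adj[np.ix_(nb, nb)]
        ds = brute_distances(sub)
        m = len(nb)
        eloc_terms.append(
            sum(1.0 / ds[a, b] for a, b in itertools.permutations(range(m), 2)
                if np.isfinite(ds[a, b])) / (m * (m - 1))
        )
    return dict(Eg=eg, Cp_path=cp, Ccoef=float(np.mean(cc_terms)),
                Eloc=float(np.mean(eloc_terms)))


def random_adj(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return a


# ----------------------------------------------------------------------------


class TestThresholdBySparsity:
    def test_edge_count_27_nodes(self, rng):
        """27 nodes at 5% sparsity keep round(0.05*351) = 18 edges."""
        z = rng.standard_normal((27, 27))
        z = (z + z.T) / 2
        adj = threshold_by_sparsity(z, 0.05)
        assert adj.sum() // 2 == 18

    def test_separation_case(self):
        n = 27
        z = np.full((n, n), -100.0)
        iu = np.triu_indices(n, 1)
        pos = [(iu[0][i], iu[1][i]) for i in range(18)]
        for i, j in pos:
            z[i, j] = z[j, i] = 1.0
        np.fill_diagonal(z, 0.0)
        adj = threshold_by_sparsity(z, 0.05, use_abs=False)
        assert {(i, j) for i, j in zip(*np.nonzero(np.triu(adj, 1)))} == set(pos)

    def test_near_unit_sparsity_gives_complete_graph(self, rng):
        z = rng.standard_normal((8, 8))
        z = (z + z.T) / 2
        adj = threshold_by_sparsity(z, 0.999)
        assert adj.sum() == 8 * 7  # all off-diagonal pairs

    def test_sparsity_bounds(self, rng):
        z = np.eye(5)
        for s in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                threshold_by_sparsity(z, s)

    def test_efficiency_monotone_in_sparsity(self, rng):
        """Nested edge sets: Eg never decreases as the graph densifies."""
        z = rng.standard_normal((20, 20))
        z = (z + z.T) / 2
        prev = -1.0
        for s in SparsityRamp().values():
            eg = global_metrics(threshold_by_sparsity(z, s))["Eg"]
            assert eg >= prev - 1e-12
            prev = eg


class TestGlobalMetrics:
    def test_path_graph(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        m = global_metrics(adj)
        assert m["Eg"] == pytest.approx(5 / 6)
        assert m["Cp_path"] == pytest.approx(4 / 3)
        assert m["Ccoef"] == 0.0

    def test_triangle(self):
        adj = ~np.eye(3, dtype=bool)
        m = global_metrics(adj)
        assert m["Eg"] == 1.0 and m["Cp_path"] == 1.0 and m["Ccoef"] == 1.0

    def test_two_disjoint_edges(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        m = global_metrics(adj)
        assert m["Eg"] == pytest.approx(1 / 3)  # 4 reachable ordered pairs at d=1
        assert m["Cp_path"] == 1.0
        assert not m["connected"]

    def test_empty_graph(self):
        m = global_metrics(np.zeros((5, 5), dtype=bool))
        assert m["Eg"] == 0 and m["Ccoef"] == 0 and not m["connected"]

    def test_matches_brute_force_on_small_graphs(self, rng):
        """Spot-check against exhaustive Floyd-Warshall / triangle counting."""
        for _ in range(150):
            n = rng.integers(3, 8)
            adj = random_adj(rng, n, rng.uniform(0.2, 0.9))
            got = global_metrics(adj)
            want = brute_metrics(adj)
            for key in ("Eg", "Cp_path", "Ccoef", "Eloc"):
                assert got[key] == pytest.approx(want[key], abs=1e-12), key


class TestSmallWorld:
    def test_self_null_gives_unity(self, rng):
        adj = random_adj(rng, 12, 0.4)
        sw = small_world(adj, n_null=20, seed=0, rewire=False)
        assert sw["gamma"] == pytest.approx(1.0)
        assert sw["lambda"] == pytest.approx(1.0)
        assert sw["sigma"] == pytest.approx(1.0)

    def test_random_graph_sigma_near_one(self, rng):
        adj = random_adj(rng, 24, 0.3)
        sw = small_world(adj, n_null=30, seed=1)
        assert sw["sigma"] == pytest.approx(1.0, abs=0.25)

    def test_ring_lattice_is_clustered(self):
        """A ring lattice has gamma > 1 against degree-preserving nulls."""
        import networkx as nx

        G = nx.watts_strogatz_graph(24, 6, p=0.0, seed=0)
        adj = nx.to_numpy_array(G, dtype=bool)
        sw = small_world(adj, n_null=20, seed=0)
        assert sw["gamma"] > 1.0

    def test_null_preserves_degrees(self, rng):
        import networkx as nx

        from dynconn.graph import _rewired_null

        adj = random_adj(rng, 15, 0.35)
        G = nx.from_numpy_array(adj.astype(int))
        H = _rewired_null(G, np.random.default_rng(0))
        assert sorted(d for _, d in H.degree()) == sorted(d for _, d in G.degree())
        for node in G.nodes:
            assert H.degree(node) == G.degree(node)


class TestAucAndVariability:
    def test_constant_metric_auc(self):
        ramp = SparsityRamp()
        assert len(ramp.values()) == 36
        assert auc_over_ramp(np.ones(36), ramp) == pytest.approx(0.35)

    def test_linear_ramp_auc(self):
        ramp = SparsityRamp()
        y = np.linspace(0, 1, 36)
        assert auc_over_ramp(y, ramp) == pytest.approx(0.175)

    def test_single_point_ramp_errors(self):
        with pytest.raises(ValueError):
            auc_over_ramp([1.0], np.array([0.05]))

    def test_missing_value_errors(self):
        ramp = SparsityRamp()
        y = np.ones(36)
        y[5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            auc_over_ramp(y, ramp)

    def test_constant_series_zero_variance(self):
        assert temporal_variability(np.full(10, 3.3)) == pytest.approx(0.0, abs=1e-20)

    def test_alternating_series_closed_form(self):
        a, n_w = 0.2, 8
        series = a * (-1.0) ** np.arange(n_w)
        expected = a**2 * n_w / (n_w - 1)
        assert temporal_variability(series) == pytest.approx(expected)
        assert temporal_variability(series, use_sd=True) == pytest.approx(
            np.sqrt(expected)
        )

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            temporal_variability(np.array([1.0]))


def test_nodal_metrics_star_graph():
    """Star: hub degree n-1, leaves 1; hub carries all betweenness."""
    n = 6
    adj = np.zeros((n, n), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    nm = nodal_metrics(adj)
    assert nm.loc[0, "degree"] == n - 1
    assert nm.loc[0, "betweenness"] == pytest.approx(1.0)
    assert nm.loc[1, "nodal_efficiency"] == pytest.approx((1 + 0.5 * (n - 2)) / (n - 1))


def test_group_topology_gap_raises_eg_variance(gt):
    """Bigger between-state topology contrast yields larger Eg variance."""
    import dynconn
    from dynconn.graph import subject_dynamic_graph
    from dynconn.synthetic import GroundTruth, _nearest_pd_correlation
    from dynconn.windows import WindowParams, window_connectivity

    sticky = {"patient": np.array([[0.98, 0.02], [0.02, 0.98]])}
    base = gt.state_covariances[1] - np.diag(np.diag(gt.state_covariances[1]))
    base = base / np.abs(base).max() * 0.55  # off-diagonal pattern, unit-free

    def make(scales):
        covs = [_nearest_pd_correlation(np.eye(27) + s * base) for s in scales]
        return GroundTruth(2, covs, sticky, np.zeros(27), 0.25, 0, atlas=gt.atlas)

    variances = []
    for scales in [(0.9, 1.1), (0.2, 1.6)]:  # small vs large state gap
        gt_s = make(scales)
        vs = []
        for seed in range(3):
            ts, _ = dynconn.simulate_subject(gt_s, "patient", T=230, seed=seed)
            wfc = window_connectivity(ts, WindowParams())
            _, summary = subject_dynamic_graph(wfc, small_world_mean=False)
            vs.append(summary["Eg_variance"])
        variances.append(np.mean(vs))
    assert variances[1] > variances[0]
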