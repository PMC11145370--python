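import numpy as np
import pytest
from scipy import stats

from dynconn.nbs import (
    build_design,
    edge_glm_t,
    extract_components,
    permutation_test,
)
from dynconn.windows import vector_to_matrix


def _stack(rng, n, nodes=10):
    """Random symmetric matrices, zero diagonal."""
    E = nodes * (nodes - 1) // 2
    return np.array([vector_to_matrix(rng.standard_normal(E), nodes)
                     for _ in range(n)])


class TestEdgeGlmT:
    def test_equals_two_sample_t_without_covariates(self, rng):
        """Group-coefficient t == pooled-variance two-sample t, to 1e-10."""
        stack = _stack(rng, 30)
        group = np.array(["a"] * 14 + ["b"] * 16)
        t_mat, p_mat = edge_glm_t(stack, group)
        iu = np.triu_indices(10, 1)
        for i, j in list(zip(*iu))[:20]:
            y = stack[:, i, j]
            t_ref, p_ref = stats.ttest_ind(y[group == "b"], y[group == "a"],
                                           equal_var=True)
            assert t_mat[i, j] == pytest.approx(t_ref, abs=1e-10)
            assert p_mat[i, j] == pytest.approx(p_ref, abs=1e-10)

    def test_orthogonal_covariate_barely_moves_t(self, rng):
        stack = _stack(rng, 200)
        group = np.array(["a"] * 100 + ["b"] * 100)
        g = (group == "b").astype(float)
        cov = rng.standard_normal(200)
        cov -= cov.mean()
        cov -= g * (g - g.mean()) @ cov / ((g - g.mean()) @ (g - g.mean())) * 0
        cov = cov - (g - g.mean()) * ((g - g.mean()) @ cov) / ((g - g.mean()) @ (g - g.mean()))
        t0, _ = edge_glm_t(stack, group)
        t1, _ = edge_glm_t(stack, group, covariates={"c": cov})
        iu = np.triu_indices(10, 1)
        np.testing.assert_allclose(t1[iu], t0[iu], rtol=0.05, atol=0.05)

    def test_identical_groups_give_zero_t(self, rng):
        half = _stack(rng, 12)
        stack = np.concatenate([half, half])
        group = ["a"] * 12 + ["b"] * 12
        t_mat, _ = edge_glm_t(stack, group)
        np.testing.assert_allclose(t_mat, 0.0, atol=1e-10)

    def test_collinear_design_names_column(self, rng):
        stack = _stack(rng, 20)
        group = np.array(["a"] * 10 + ["b"] * 10)
        g = (group == "b").astype(float)
        with pytest.raises(ValueError, match="dup"):
            edge_glm_t(stack, group, covariates={"dup": g})


class TestExtractComponents:
    def _p_from_edges(self, edges, n=6):
        p = np.ones((n, n))
        for i, j in edges:
            p[i, j] = p[j, i] = 1e-6
        return p

    def test_hand_enumerated_components(self):
        p = self._p_from_edges([(1, 2), (2, 3), (4, 5)])
        comps = extract_components(p, 1e-4, direction=+1)
        sizes = sorted(c.size for c in comps)
        assert sizes == [1, 2]
        big = next(c for c in comps if c.size == 2)
        assert big.edges == [(1, 2), (2, 3)]
        assert big.nodes == [1, 2, 3]

    def test_empty_result(self):
        comps = extract_components(np.ones((5, 5)), 1e-4, +1)
        assert comps == []

    def test_complete_suprathreshold_graph(self):
        p = np.full((5, 5), 1e-6)
        np.fill_diagonal(p, 1.0)
        comps = extract_components(p, 1e-4, +1)
        assert len(comps) == 1 and comps[0].size == 10

    def test_direction_filtering(self):
        p = self._p_from_edges([(0, 1), (2, 3)])
        t = np.zeros((6, 6))
        t[0, 1] = t[1, 0] = 3.0
        t[2, 3] = t[3, 2] = -3.0
        pos = extract_components(p, 1e-4, +1, edge_t=t)
        neg = extract_components(p, 1e-4, -1, edge_t=t)
        assert [c.edges for c in pos] == [[(0, 1)]]
        assert [c.edges for c in neg] == [[(2, 3)]]

    def test_node_relabel_invariance(self, rng):
        n = 8
        p = self._p_from_edges([(0, 1), (1, 2), (5, 6)], n=n)
        perm = rng.permutation(n)
        p_perm = p[np.ix_(perm, perm)]
        sizes = sorted(c.size for c in extract_components(p, 1e-4, +1))
        sizes_perm = sorted(c.size for c in extract_components(p_perm, 1e-4, +1))
        assert sizes == sizes_perm


class TestPermutationTest:
    def test_min_nperm_enforced(self, rng):
        stack = _stack(rng, 20)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(stack, ["a"] * 10 + ["b"] * 10, n_perm=50)

    def test_p_floor_add_one_convention(self, rng):
        stack = _stack(rng, 24)
        stack[12:, 0, 1] += 5.0
        stack[12:, 1, 0] += 5.0
        res = permutation_test(stack, ["a"] * 12 + ["b"] * 12,
                               primary_p=0.001, n_perm=150, seed=0)
        for c in res.components:
            assert c.p_fwe >= 1.0 / (res.n_perm + 1)

    def test_exhaustive_fallback_small_n(self, rng):
        """With 4+4 subjects only C(8,4)=70 label splits exist: all are used."""
        stack = _stack(rng, 8)
        res = permutation_test(stack, ["a"] * 4 + ["b"] * 4,
                               primary_p=0.01, n_perm=100, seed=0)
        assert res.n_perm == 70

    def test_freedman_lane_reduces_to_label_shuffle(self, rng):
        """Without covariates the permuted stat equals a plain label shuffle."""
        stack = _stack(rng, 16, nodes=5)
        group = np.array(["a"] * 8 + ["b"] * 8)
        res = permutation_test(stack, group, primary_p=0.5, n_perm=120, seed=7)
        # oracle: same rng protocol, shuffle rows of the data directly
        from dynconn.windows import upper_triangle

        rng2 = np.random.default_rng(7)
        null_max = np.zeros(120)
        for r in range(120):
            perm = rng2.permutation(16)
            t_m, p_m = edge_glm_t(stack[perm], group)
            comps = (extract_components(p_m, 0.5, +1, edge_t=t_m)
                     + extract_components(p_m, 0.5, -1, edge_t=t_m))
            null_max[r] = max((c.size for c in comps), default=0)
        got = np.maximum(res.null_max_sizes[+1], res.null_max_sizes[-1])
        np.testing.assert_array_equal(got, null_max)

    def test_planted_subnetwork_detected(self, rng):
        """A dense 6-edge effect at d=1.5 with 30/30 subjects is found."""
        nodes = 27
        stack = _stack(rng, 60, nodes=nodes)
        quad = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for i, j in quad:
            stack[30:, i, j] += 1.5
            stack[30:, j, i] += 1.5
        res = permutation_test(stack, ["a"] * 30 + ["b"] * 30,
                               n_perm=200, seed=3)
        sig = [c for c in res.components if c.p_fwe < 0.05 and c.direction == 1]
        assert sig and max(c.size for c in sig) >= 5

    def test_covariate_shift_absorbed(self, rng):
        """A pure covariate effect does not create spurious components."""
        stack = _stack(rng, 40, nodes=8)
        age = rng.uniform(20, 60, 40)
        stack += 0.05 * (age[:, None, None] - 40)  # age effect on every edge
        res = permutation_test(
            stack, ["a"] * 20 + ["b"] * 20, covariates={"age": age},
            primary_p=1e-3, n_perm=100, seed=1,
        )
        assert all(c.p_fwe > 0.05 for c in res.components)


def test_build_design_levels_and_names():
    X, coef, names = build_design(["control"] * 3 + ["patient"] * 3,
                                  {"age": [30, 40, 50, 35, 45, 55]})
    assert names == ["intercept", "group[patient]", "age"]
    np.testing.assert_array_equal(X[:, coef], [0, 0, 0, 1, 1, 1])
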