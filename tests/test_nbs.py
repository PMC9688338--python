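"""Network-based statistic: paired t matrix, components, permutation p."""

import numpy as np
import pytest

from gswnet.nbs import (
    NBSResult,
    WeightedNetwork,
    apply_adjacency_weights,
    nbs_paired,
    paired_t_matrix,
    significant_adjacency,
)


def _sym_tensor(rng, subjects, n):
    x = rng.normal(size=(subjects, n, n))
    x = (x + np.swapaxes(x, 1, 2)) / 2
    for s in range(subjects):
        np.fill_diagonal(x[s], 0.0)
    return x


class TestPairedTMatrix:
    def test_identical_tensors_all_zero(self, rng):
        a = _sym_tensor(rng, 5, 4)
        with pytest.warns(UserWarning, match="zero-variance"):
            t = paired_t_matrix(a, a.copy())
        assert np.allclose(t, 0.0)

    def test_hand_computed_value(self):
        """Differences [1, 2, 3] give t = mean/(sd/sqrt(n)) = 2*sqrt(3)."""
        n = 3
        base = np.zeros((3, 2, 2))
        a = base.copy()
        for s, d in enumerate([1.0, 2.0, 3.0]):
            a[s, 0, 1] = a[s, 1, 0] = d
        t = paired_t_matrix(a, base)
        assert t[0, 1] == pytest.approx(2 * np.sqrt(3))

    def test_sign_antisymmetry(self, rng):
        a = _sym_tensor(rng, 6, 5)
        b = _sym_tensor(rng, 6, 5)
        assert np.allclose(paired_t_matrix(a, b), -paired_t_matrix(b, a))

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            paired_t_matrix(_sym_tensor(rng, 4, 3), _sym_tensor(rng, 5, 3))


class TestNbsPaired:
    def test_null_difference_gives_no_components(self, rng):
        a = _sym_tensor(rng, 6, 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = nbs_paired(a, a.copy(), threshold=1.0, n_perm=50, seed=0)
        assert res.components == []

    def test_minimum_achievable_p(self, rng):
        """With n_perm permutations the smallest possible p is
        1/(1+n_perm) — below 0.001 at 5000 permutations."""
        assert 1 / (1 + 5000) < 0.001
        a = _sym_tensor(rng, 8, 4)
        b = a + 2.0 * (1 - np.eye(4))
        res = nbs_paired(a + 5 * (1 - np.eye(4)), _sym_tensor(rng, 8, 4),
                         threshold=1.0, n_perm=100, seed=1)
        assert np.all(res.component_p >= 1 / (1 + 100))

    def test_planted_component_recovered(self):
        """A 3-edge chain shifted by 1.5 within-subject SD reaches p<=0.05
        in at least 90% of generator seeds (intensity statistic — a strong
        homogeneous shift keeps its edges correlated under sign flips, which
        floors extent-based p-values near 0.1)."""
        hits = 0
        planted = [(0, 1), (1, 2), (2, 3)]
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            b = _sym_tensor(rng, 23, 6)
            noise = rng.normal(size=(23, 6, 6))
            a = b + 0.5 * (noise + np.swapaxes(noise, 1, 2)) / 2
            sd_diff = 0.5 / np.sqrt(2)  # SD of the difference by construction
            for i, j in planted:
                a[:, i, j] += 1.5 * sd_diff
                a[:, j, i] += 1.5 * sd_diff
            res = nbs_paired(a, b, threshold=1.0, n_perm=500, seed=seed,
                             stat="intensity")
            for comp, p in zip(res.components, res.component_p):
                edges = {tuple(sorted(e)) for e in comp}
                if p <= 0.05 and len(edges & set(planted)) >= 2:
                    hits += 1
                    break
        assert hits >= 18

    def test_threshold_monotonicity(self, rng):
        a = _sym_tensor(rng, 10, 6)
        b = _sym_tensor(rng, 10, 6)
        r1 = nbs_paired(a, b, threshold=1.0, n_perm=20, seed=3)
        r35 = nbs_paired(a, b, threshold=3.5, n_perm=20, seed=3)
        edges1 = {e for c in r1.components for e in c}
        edges35 = {e for c in r35.components for e in c}
        assert edges35 <= edges1

    def test_seed_reproducibility(self, rng):
        a = _sym_tensor(rng, 8, 5)
        b = _sym_tensor(rng, 8, 5)
        r1 = nbs_paired(a, b, n_perm=100, seed=7)
        r2 = nbs_paired(a, b, n_perm=100, seed=7)
        assert np.array_equal(r1.component_p, r2.component_p)
        assert r1.components == r2.components


class TestAdjacencyAndWeights:
    def _result_with(self, n, comps, ps):
        return NBSResult(np.zeros((n, n)), 1.0, comps, np.array(ps), 100, 0)

    def test_no_significant_component_zero_matrix(self):
        res = self._result_with(4, [[(0, 1)]], [0.5])
        assert np.count_nonzero(significant_adjacency(res, 0.05)) == 0

    def test_edge_count_doubles_by_symmetry(self):
        res = self._result_with(5, [[(0, 1), (1, 2), (2, 3)]], [0.01])
        adj = significant_adjacency(res, 0.05)
        assert np.count_nonzero(adj) == 6
        assert np.array_equal(adj, adj.T)

    def test_alpha_one_includes_all_suprathreshold(self):
        res = self._result_with(4, [[(0, 1)], [(2, 3)]], [0.9, 0.6])
        adj = significant_adjacency(res, alpha=1.0)
        assert adj[0, 1] == 1 and adj[2, 3] == 1

    def test_masking_identity_and_idempotence(self, rng):
        conn = np.abs(_sym_tensor(rng, 1, 5)[0]) / 10
        adj = (np.ones((5, 5)) - np.eye(5)).astype(int)
        w = apply_adjacency_weights(adj, conn)
        assert np.allclose(w.weights, np.abs(conn))
        w2 = apply_adjacency_weights(adj, w.weights)
        assert np.allclose(w.weights, w2.weights)

    def test_empty_adjacency_empty_network(self, rng):
        conn = np.abs(_sym_tensor(rng, 1, 4)[0])
        w = apply_adjacency_weights(np.zeros((4, 4), dtype=int), conn)
        assert np.count_nonzero(w.weights) == 0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_adjacency_weights(np.zeros((3, 3)), np.zeros((4, 4)))


def test_weighted_network_validation():
    with pytest.raises(ValueError):
        WeightedNetwork(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    with pytest.raises(ValueError):
        WeightedNetwork(np.array([[0.0, 1.0], [2.0, 0.0]]))
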