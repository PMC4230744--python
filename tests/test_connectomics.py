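"""NMI estimation, weighted graph metrics vs brute-force oracles, nulls,
and the max-statistic permutation test."""

import itertools

import numpy as np
import pytest

from dopasim.connectomics import (entropy, local_efficiency, nmi, nmi_matrix,
                                  nodal_degree, nodal_strength,
                                  normalized_metrics, null_ensemble,
                                  paired_permutation_test,
                                  weighted_clustering, NmiNetwork)
from dopasim.params import ParameterError


# ---------------------------------------------------------------------------
# brute-force oracles (triple loops / explicit all-pairs shortest paths)

def onnela_oracle(w):
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    mx = w.max()
    if mx == 0:
        return np.zeros(n)
    s = (w / mx) ** (1.0 / 3.0)
    out = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                acc += s[i, j] * s[i, h] * s[j, h]
        out[i] = acc / (k * (k - 1))
    return out


def floyd_warshall_oracle(lengths):
    d = lengths.copy()
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def latora_oracle(w):
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), np.inf)
        d = floyd_warshall_oracle(lengths)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]):
                    acc += 1.0 / d[a, b]
        out[i] = acc / (k * (k - 1))
    return out


def random_weighted_graph(n, density, rng):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = np.where(rng.random(iu[0].size) < density, rng.random(iu[0].size),
                    0.0)
    w[iu] = vals
    return w + w.T


# ---------------------------------------------------------------------------

class TestEntropy:
    def test_constant_series_zero_bits(self):
        assert entropy(np.full(100, 3.7), bins=8) == 0.0

    def test_uniform_maximum(self):
        x = np.repeat(np.arange(8), 16)  # exactly equal occupancy of 8 bins
        assert entropy(x, bins=8) == pytest.approx(3.0)

    def test_fair_two_bin_split(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert entropy(x, bins=2) == pytest.approx(1.0)

    def test_upper_bound_and_errors(self, rng):
        x = rng.normal(size=500)
        assert 0.0 <= entropy(x, bins=16) <= 4.0
        with pytest.raises(ParameterError):
            entropy(np.array([]), bins=4)
        with pytest.raises(ParameterError):
            entropy(x, bins=1)


class TestNmi:
    def test_self_information_is_one(self, rng):
        x = rng.normal(size=2000)
        assert nmi(x, x, bins=16) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert nmi(x, y, bins=16) < 0.05

    def test_symmetry(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=(2, 500))
            assert nmi(x, y, bins=10) == pytest.approx(nmi(y, x, bins=10))

    def test_constant_series_zero_with_warning(self, rng):
        with pytest.warns(UserWarning, match="zero entropy"):
            assert nmi(np.ones(100), rng.normal(size=100)) == 0.0

    def test_length_mismatch(self, rng):
        with pytest.raises(ParameterError):
            nmi(np.ones(10), np.ones(11))


class TestNmiMatrix:
    def test_contract_on_random_panel(self, rng):
        panel = rng.normal(size=(400, 6))
        panel[:, 3] = panel[:, 0]  # duplicated region
        net = nmi_matrix(panel, bins=12)
        m = net.matrix
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.all((m >= 0) & (m <= 1))
        assert m[0, 3] == pytest.approx(1.0)
        # entries equal elementwise nmi calls
        assert m[1, 2] == pytest.approx(
            nmi(panel[:, 1], panel[:, 2], bins=12))

    def test_independent_panel_near_zero_offdiagonal(self):
        rng = np.random.default_rng(11)
        panel = rng.normal(size=(10_000, 4))
        m = nmi_matrix(panel, bins=16).matrix
        off = m[~np.eye(4, dtype=bool)]
        assert np.all(off < 0.05)


class TestGraphMetrics:
    def test_strength_hand_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.8
        np.testing.assert_allclose(nodal_strength(w), [0.6, 1.0, 1.2])
        np.testing.assert_array_equal(nodal_degree(w), [2, 2, 2])
        np.testing.assert_array_equal(nodal_strength(np.zeros((4, 4))), 0.0)

    def test_degree_loses_one_per_removed_edge(self, rng):
        w = random_weighted_graph(8, 1.0, rng)
        k0 = nodal_degree(w)
        w2 = w.copy()
        w2[2, 5] = w2[5, 2] = 0.0
        k1 = nodal_degree(w2)
        assert k0[2] - k1[2] == 1 and k0[5] - k1[5] == 1
        assert np.all(k0[[0, 1, 3, 4, 6, 7]] == k1[[0, 1, 3, 4, 6, 7]])

    def test_uniform_complete_graph_is_exchangeable(self):
        w = np.full((7, 7), 0.3)
        np.fill_diagonal(w, 0.0)
        np.testing.assert_allclose(weighted_clustering(w), 1.0)
        s = nodal_strength(w)
        assert np.ptp(s) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_clustering_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(8, 0.6, rng)
        np.testing.assert_allclose(weighted_clustering(w), onnela_oracle(w),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_efficiency_matches_shortest_path_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        w = random_weighted_graph(8, 0.5, rng)
        np.testing.assert_allclose(local_efficiency(w), latora_oracle(w),
                                   atol=1e-12)

    def test_efficiency_matches_networkx_oracle(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(4)
        w = random_weighted_graph(9, 0.7, rng)
        mine = local_efficiency(w)
        for i in range(9):
            nbrs = np.flatnonzero(w[i] > 0)
            if nbrs.size < 2:
                assert mine[i] == 0.0
                continue
            g = nx.Graph()
            for a_, b_ in itertools.combinations(range(nbrs.size), 2):
                ww = w[nbrs[a_], nbrs[b_]]
                if ww > 0:
                    g.add_edge(a_, b_, length=1.0 / ww)
            g.add_nodes_from(range(nbrs.size))
            d = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
            acc = sum(1.0 / d[a_][b_] for a_ in d for b_ in d[a_] if a_ != b_)
            want = acc / (nbrs.size * (nbrs.size - 1))
            assert mine[i] == pytest.approx(want, abs=1e-12)

    def test_low_degree_nodes_score_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5  # nodes 0,1 have 1 neighbor; 2,3 isolated
        assert np.all(weighted_clustering(w)[[0, 1, 2, 3]] == 0.0)
        assert np.all(local_efficiency(w) == 0.0)

    def test_fully_connected_direct_edge_is_shortest(self, rng):
        """In a complete NMI-like graph the one-hop path is shortest for
        every neighbor pair whenever no two-hop detour has lower total
        inverse-weight length; verify per instance."""
        w = random_weighted_graph(7, 1.0, rng) * 0.5 + 0.5
        np.fill_diagonal(w, 0.0)
        lengths = 1.0 / np.where(w > 0, w, np.inf)
        d = floyd_warshall_oracle(lengths.copy())
        off = ~np.eye(7, dtype=bool)
        assert np.all(d[off] <= lengths[off] + 1e-12)
        # with weights in [0.5, 1] a detour of two edges is never shorter
        assert np.allclose(d[off], lengths[off])


class TestNullModel:
    def test_weight_multiset_and_density_preserved(self, rng):
        w = random_weighted_graph(9, 0.5, rng)
        ens = null_ensemble(w, n=20, seed=3)
        iu = np.triu_indices(9, k=1)
        for surr in ens:
            np.testing.assert_array_equal(surr, surr.T)
            np.testing.assert_allclose(np.sort(surr[iu]), np.sort(w[iu]))
        assert np.mean([nodal_strength(s).sum() for s in ens]) == \
            pytest.approx(nodal_strength(w).sum())

    def test_seeding(self, rng):
        w = random_weighted_graph(8, 0.5, rng)
        a = null_ensemble(w, n=5, seed=1)
        b = null_ensemble(w, n=5, seed=1)
        c = null_ensemble(w, n=5, seed=2)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_normalization_against_ensemble_of_copies(self, rng):
        w = random_weighted_graph(8, 0.8, rng)
        ens = np.stack([w, w, w])
        c_hat, e_hat = normalized_metrics(w, ens)
        np.testing.assert_allclose(c_hat, 1.0)
        np.testing.assert_allclose(e_hat, 1.0)

    def test_self_normalization_near_unity(self):
        """A network drawn from the null family itself normalizes to ~1."""
        rng = np.random.default_rng(8)
        w = random_weighted_graph(12, 1.0, rng)
        ens = null_ensemble(w, n=50, seed=5)
        c_hat, e_hat = normalized_metrics(w, ens)
        assert np.nanmean(c_hat) == pytest.approx(1.0, abs=0.1)
        assert np.nanmean(e_hat) == pytest.approx(1.0, abs=0.1)

    def test_clustering_scale_invariance(self, rng):
        w = random_weighted_graph(8, 0.7, rng)
        np.testing.assert_allclose(weighted_clustering(w),
                                   weighted_clustering(3.7 * w), atol=1e-12)


class TestPermutationTest:
    def test_equal_inputs_give_p_one(self, rng):
        a = rng.normal(size=20)
        res = paired_permutation_test(a, a.copy(), n_perm=200, seed=0)
        np.testing.assert_array_equal(res.p_fwe, 1.0)

    def test_p_values_in_range_and_null_length(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        res = paired_permutation_test(a, b, n_perm=500, seed=1)
        assert res.null_max.shape == (500,)
        assert np.all(res.p_fwe > 0) and np.all(res.p_fwe <= 1)
        assert res.p_fwe.min() >= 1.0 / res.n_perm

    def test_matches_full_enumeration_on_tiny_input(self, rng):
        """Monte-Carlo with many permutations agrees with the exact
        exhaustive test on n <= 10 nodes."""
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        exact = paired_permutation_test(a, b, n_perm=100, seed=0,
                                        exhaustive=True)
        assert exact.n_perm == 64
        # manual enumeration oracle with explicit studentization
        d = a - b

        def zstat(e):
            e = np.asarray(e, dtype=float)
            return (e - e.mean()) / e.std()

        ms = [zstat([s * d[k] for k, s in enumerate(signs)]).max()
              for signs in itertools.product((1, -1), repeat=6)]
        z_obs = zstat(d)
        for i in range(6):
            want = np.mean([m >= z_obs[i] for m in ms])
            assert exact.p_fwe[i] == pytest.approx(want)

    def test_fwe_calibration_under_null(self):
        """Rejection rate of min-p at alpha=0.05 over simulated paired
        nulls stays at the nominal level (quick version; the full-size
        calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 400
        for r in range(n_rep):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            res = paired_permutation_test(a, b, n_perm=200, seed=r)
            rejections += res.p_fwe.min() <= 0.05
        rate = rejections / n_rep
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_input_validation(self, rng):
        with pytest.raises(ParameterError):
            paired_permutation_test(np.ones(5), np.ones(6))
        with pytest.raises(ParameterError):
            paired_permutation_test(np.ones(5), np.ones(5), n_perm=10)


class TestNmiNetworkType:
    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            NmiNetwork(matrix=np.array([[1.0, 0.5], [0.4, 1.0]]), bins=4)
        with pytest.raises(ParameterError):
            NmiNetwork(matrix=np.array([[1.0, 1.5], [1.5, 1.0]]), bins=4)
        with pytest.raises(ParameterError):
            NmiNetwork(matrix=np.array([[0.5, 0.1], [0.1, 0.5]]), bins=4)
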