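"""Cluster-randomisation test: t maps, cluster formation, permutation null."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from frnkit.cluster import (Cluster, ClusterConfig, ContrastWave,
                            form_clusters, permutation_null, run_cluster_test,
                            samplewise_t)
import frnkit.cluster as C


def wave_from(data):
    data = np.asarray(data, float)
    return ContrastWave(data, "test",
                        tuple(f"c{i}" for i in range(data.shape[1])),
                        np.arange(data.shape[2], dtype=float))


def chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestSamplewiseT:
    def test_matches_published_group_statistic(self):
        """Samples whose mean/sd/N equal the published behavioural summary
        produce the published t."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(44)
        x = (x - x.mean()) / x.std(ddof=1) * 23.04 + 20.73
        t = samplewise_t(wave_from(x[:, None, None]))
        assert round(float(t[0, 0]), 2) == 5.97

    def test_antisymmetry(self, rng):
        data = rng.standard_normal((12, 3, 7))
        assert np.allclose(samplewise_t(wave_from(-data)),
                           -samplewise_t(wave_from(data)))

    def test_zero_variance_handling(self):
        data = np.ones((6, 1, 3))
        data[:, 0, 1] = 0.0
        data[:, 0, 2] = -2.0
        t = samplewise_t(wave_from(data))
        assert t[0, 0] == np.inf and t[0, 1] == 0.0 and t[0, 2] == -np.inf

    def test_agrees_with_scipy(self, rng):
        data = rng.standard_normal((15, 2, 4)) + 0.3
        t = samplewise_t(wave_from(data))
        ref = sps.ttest_1samp(data, 0.0, axis=0).statistic
        assert np.allclose(t, ref)


def flood_fill_oracle(t_map, adjacency, t_crit, min_size):
    """Independent BFS clustering over same-sign significant samples."""
    n_ch, n_t = t_map.shape
    sig = np.abs(t_map) > t_crit
    seen = np.zeros_like(sig)
    out = []
    for c0, t0 in product(range(n_ch), range(n_t)):
        if not sig[c0, t0] or seen[c0, t0]:
            continue
        sign = np.sign(t_map[c0, t0])
        queue, members = [(c0, t0)], set()
        seen[c0, t0] = True
        while queue:
            c, t = queue.pop()
            members.add((c, t))
            nbrs = [(c, t - 1), (c, t + 1)] + [
                (c2, t) for c2 in range(n_ch) if adjacency[c, c2]
            ]
            for c2, t2 in nbrs:
                if (0 <= t2 < n_t and sig[c2, t2] and not seen[c2, t2]
                        and np.sign(t_map[c2, t2]) == sign):
                    seen[c2, t2] = True
                    queue.append((c2, t2))
        if len(members) >= min_size:
            out.append(frozenset(members))
    return set(out)


class TestFormClusters:
    def test_isolated_sample_below_min_size_discarded(self):
        t_map = np.zeros((3, 10))
        t_map[1, 4] = 8.0
        clusters = form_clusters(t_map, chain_adjacency(3), 0.05, 20, 25)
        assert clusters == []

    def test_rectangular_block_counted(self):
        t_map = np.zeros((5, 6))
        t_map[:, :] = 9.0
        clusters = form_clusters(t_map, chain_adjacency(5), 0.05, 30, 25)
        assert len(clusters) == 1
        assert clusters[0].size == 30
        assert clusters[0].sign == 1
        assert clusters[0].mass == pytest.approx(9.0 * 30)

    def test_sign_splits_components(self):
        t_map = np.zeros((1, 9))
        t_map[0, :4] = 5.0
        t_map[0, 4:] = -5.0
        clusters = form_clusters(t_map, np.zeros((1, 1), bool), 0.05, 20, 2)
        assert sorted(c.sign for c in clusters) == [-1, 1]

    @pytest.mark.parametrize("min_size", [1, 3, 6])
    def test_random_maps_match_flood_fill_oracle(self, rng, min_size):
        adjacency = np.zeros((4, 4), dtype=bool)
        adjacency[0, 1] = adjacency[1, 0] = True
        adjacency[1, 2] = adjacency[2, 1] = True
        adjacency[0, 3] = adjacency[3, 0] = True
        df = 19
        t_crit = sps.t.ppf(0.975, df)
        for _ in range(30):
            t_map = rng.standard_normal((4, 10)) * 2.0
            mine = {
                frozenset(c.members)
                for c in form_clusters(t_map, adjacency, 0.05, df, min_size)
            }
            assert mine == flood_fill_oracle(t_map, adjacency, t_crit, min_size)

    def test_peak_is_max_abs_t(self, rng):
        t_map = np.abs(rng.standard_normal((2, 8))) + 3.0
        clusters = form_clusters(t_map, np.ones((2, 2), bool) ^ np.eye(2, dtype=bool),
                                 0.05, 20, 1)
        c = max(clusters, key=lambda c: c.size)
        ch, tt = c.peak
        assert t_map[ch, tt] == max(t_map[m] for m in c.members)


class TestPermutationNull:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Sign-flip MC p agrees with full 2^N enumeration."""
        rng = np.random.default_rng(3)
        n = 8
        data = rng.normal(1.2, 1.0, (n, 1, 8))
        wave = wave_from(data)
        adj = np.zeros((1, 1), bool)
        cfg = ClusterConfig(n_perm=5000, min_size=2, seed=11)
        res = run_cluster_test(wave, adj, cfg)
        assert res
        signs = np.array(list(product([-1.0, 1.0], repeat=n)))
        null = C._null_from_signs(wave, adj, cfg, signs)
        for c in res:
            exact = (null >= abs(c.mass)).mean()
            se = np.sqrt(max(exact * (1 - exact), 1e-9) / cfg.n_perm)
            assert abs(c.mc_p - exact) <= 3 * se + 1.0 / cfg.n_perm

    def test_all_zero_data_produces_no_clusters(self):
        wave = wave_from(np.zeros((6, 2, 10)))
        res = run_cluster_test(wave, chain_adjacency(2),
                               ClusterConfig(n_perm=200, min_size=1))
        assert res == []

    def test_scale_invariance(self, rng):
        data = rng.normal(0.8, 1.0, (10, 2, 12))
        adj = chain_adjacency(2)
        cfg = ClusterConfig(n_perm=500, min_size=2, seed=4)
        a = run_cluster_test(wave_from(data), adj, cfg)
        b = run_cluster_test(wave_from(data * 2.0), adj, cfg)
        assert [c.mc_p for c in a] == [c.mc_p for c in b]
        assert [c.members for c in a] == [c.members for c in b]

    def test_invariant_to_participant_order(self, rng):
        # under the exhaustive sign set the null is exactly order-invariant
        data = rng.normal(0.6, 1.0, (8, 2, 10))
        adj = chain_adjacency(2)
        cfg = ClusterConfig(n_perm=400, min_size=2, seed=9)
        signs = np.array(list(product([-1.0, 1.0], repeat=8)))
        a = C._null_from_signs(wave_from(data), adj, cfg, signs)
        b = C._null_from_signs(wave_from(data[::-1]), adj, cfg, signs)
        assert np.allclose(np.sort(a), np.sort(b))

    def test_too_few_permutations_rejected(self, rng):
        wave = wave_from(rng.standard_normal((5, 1, 5)))
        with pytest.raises(ValueError):
            permutation_null(wave, np.zeros((1, 1), bool),
                             ClusterConfig(n_perm=50))


class TestRunClusterTest:
    def test_p_values_in_unit_interval_and_sorted(self, rng):
        data = rng.normal(0.7, 1.0, (14, 3, 12))
        res = run_cluster_test(wave_from(data), chain_adjacency(3),
                               ClusterConfig(n_perm=300, min_size=2, seed=0))
        ps = [c.corrected_p for c in res]
        assert all(0 < c.mc_p <= 1 for c in res)
        assert ps == sorted(ps)

    def test_bonferroni_multiplies_by_initial_cluster_count(self, rng):
        data = rng.normal(0.0, 1.0, (20, 4, 30))
        data[:, 1, 5:15] += 1.5
        data[:, 3, 20:28] -= 1.5
        res = run_cluster_test(wave_from(data), chain_adjacency(4),
                               ClusterConfig(n_perm=300, min_size=3, seed=1))
        n_initial = len(res)
        for c in res:
            assert c.corrected_p == pytest.approx(
                min(1.0, c.mc_p * n_initial)
            )

    def test_larger_effect_never_increases_p(self):
        rng = np.random.default_rng(8)
        noise = rng.standard_normal((12, 2, 10))
        adj = chain_adjacency(2)
        cfg = ClusterConfig(n_perm=400, min_size=2, seed=2)
        ps = []
        for amp in (0.8, 1.6, 3.2):
            data = noise.copy()
            data[:, 0, 2:8] += amp
            res = run_cluster_test(wave_from(data), adj, cfg)
            ps.append(min(c.mc_p for c in res))
        assert ps[0] >= ps[1] >= ps[2]

    def test_plain_estimator_can_reach_zero(self, rng):
        data = rng.normal(3.0, 0.5, (15, 1, 10))
        res = run_cluster_test(
            wave_from(data), np.zeros((1, 1), bool),
            ClusterConfig(n_perm=200, min_size=2, seed=0,
                          p_estimator="plain"),
        )
        assert res[0].mc_p >= 0.0
        res2 = run_cluster_test(
            wave_from(data), np.zeros((1, 1), bool),
            ClusterConfig(n_perm=200, min_size=2, seed=0),
        )
        assert res2[0].mc_p >= 1.0 / 201
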