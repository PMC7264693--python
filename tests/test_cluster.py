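"""Cluster formation, permutation nulls and family-wise validity."""

import numpy as np
import pytest
from scipy import stats

from olferp.cluster import (cluster_test, find_clusters, paired_tmap,
                            permutation_null)


def brute_force_clusters(t, threshold, adjacency):
    """Independent exhaustive BFS oracle over the channel x time grid."""
    n_ch, n_t = t.shape
    out = []
    for sign in (1, -1):
        cells = {(c, k) for c in range(n_ch) for k in range(n_t)
                 if sign * t[c, k] > threshold}
        seen = set()
        for cell in sorted(cells):
            if cell in seen:
                continue
            comp, frontier = set(), [cell]
            while frontier:
                c, k = frontier.pop()
                if (c, k) in comp:
                    continue
                comp.add((c, k))
                for nb in [(c, k - 1), (c, k + 1)] + [
                        (c2, k) for c2 in range(n_ch) if adjacency[c, c2]]:
                    if nb in cells and nb not in comp:
                        frontier.append(nb)
            seen |= comp
            out.append((frozenset(comp), sum(t[c, k] for c, k in comp)))
    return out


def chain_adjacency(n):
    adj = np.zeros((n, n), bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestTMap:
    def test_equal_conditions_give_zero(self):
        a = np.random.default_rng(0).normal(size=(6, 3, 4))
        tm = paired_tmap(a, a.copy())
        assert np.allclose(tm.values, 0.0)
        assert tm.df == 5

    def test_matches_textbook_paired_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(10, 2, 3)), rng.normal(size=(10, 2, 3))
        tm = paired_tmap(a, b)
        ref = stats.ttest_rel(a[:, 1, 2], b[:, 1, 2]).statistic
        assert tm.values[1, 2] == pytest.approx(ref)

    def test_zero_variance_location_gets_sentinel(self):
        a = np.zeros((4, 1, 2))
        b = np.zeros((4, 1, 2))
        a[:, 0, 0] = 1.0                      # constant difference
        a[:, 0, 1] = [0.1, -0.2, 0.3, 0.0]    # ordinary variability
        tm = paired_tmap(a, b)
        assert tm.degenerate[0, 0] and not tm.degenerate[0, 1]
        assert tm.values[0, 0] >= 1e6
        assert np.isfinite(tm.values[0, 1]) and abs(tm.values[0, 1]) < 1e6


class TestFindClusters:
    def test_subthreshold_map_is_empty(self):
        t = np.full((3, 4), 1.5)
        assert find_clusters(t, 2.0, chain_adjacency(3)) == []

    def test_single_point_cluster(self):
        t = np.zeros((3, 4))
        t[1, 2] = 3.0
        (c,) = find_clusters(t, 2.0, chain_adjacency(3))
        assert c.polarity == "positive"
        assert c.mass == pytest.approx(3.0)
        assert c.members == [(1, 2)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(0, 1.8, size=(5, 8))
        adj = chain_adjacency(5)
        ours = {(frozenset(c.members), round(c.mass, 9))
                for c in find_clusters(t, 2.0, adj)}
        oracle = {(m, round(mass, 9))
                  for m, mass in brute_force_clusters(t, 2.0, adj)}
        assert ours == oracle

    def test_label_invariance_under_channel_permutation(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0, 1.8, size=(6, 10))
        adj = chain_adjacency(6)
        perm = rng.permutation(6)
        t2 = t[perm]
        adj2 = adj[np.ix_(perm, perm)]
        orig = {(frozenset((int(perm[c]), k) for c, k in cl.members),
                 round(cl.mass, 9))
                for cl in find_clusters(t2, 2.0, adj2)}
        ref = {(frozenset(cl.members), round(cl.mass, 9))
               for cl in find_clusters(t, 2.0, adj)}
        assert orig == ref


class TestPermutationNull:
    def test_exact_enumeration_size(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(5, 3, 4)), rng.normal(size=(5, 3, 4))
        null = permutation_null(a, b, 2.0, chain_adjacency(3), seed=0)
        assert null.n_permutations == 32 and null.exact

    def test_identical_conditions_give_degenerate_null(self):
        a = np.random.default_rng(4).normal(size=(6, 3, 4))
        null = permutation_null(a, a.copy(), 2.0, chain_adjacency(3), seed=0)
        assert np.all(null.max_mass == 0) and np.all(null.min_mass == 0)

    def test_monte_carlo_p_close_to_exhaustive(self):
        """At n=8 the Monte-Carlo p of the largest cluster is within 0.02
        of the exhaustive-enumeration p."""
        rng = np.random.default_rng(6)
        a = rng.normal(size=(8, 4, 10)) + 0.9
        b = rng.normal(size=(8, 4, 10))
        adj = chain_adjacency(4)
        exact = cluster_test(a, b, adj, n_permutations=256, seed=1)
        assert exact.null.exact
        d = a - b
        signs = np.random.default_rng(2).choice([-1.0, 1.0], size=(2000, 8))
        mc_extreme = []
        from olferp.cluster import (_adjacent_pairs, _adjacency_lists,
                                    _extreme_masses, _flip_tmaps)
        t_all = _flip_tmaps(d.reshape(8, -1), signs)
        pairs, al = _adjacent_pairs(adj), _adjacency_lists(adj)
        for row in t_all:
            hi, lo = _extreme_masses(row.reshape(4, 10), 2.0, pairs, al)
            mc_extreme.append(max(hi, -lo))
        mc_extreme = np.array(mc_extreme)
        top = max((c for c in exact.clusters if c.polarity == "positive"),
                  key=lambda c: c.mass)
        p_mc = (1 + (mc_extreme >= top.mass).sum()) / (1 + len(mc_extreme))
        assert abs(p_mc - top.p_value) < 0.02


class TestClusterTest:
    def test_alpha_one_flags_every_cluster(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(8, 3, 6))
        b = rng.normal(size=(8, 3, 6))
        res = cluster_test(a, b, chain_adjacency(3), alpha=1.0,
                           n_permutations=200, seed=2)
        assert len(res.significant) == len(res.clusters)

    def test_p_values_valid_and_monotone_in_mass(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(10, 4, 12)) + 0.6
        b = rng.normal(size=(10, 4, 12))
        res = cluster_test(a, b, chain_adjacency(4), n_permutations=300,
                           seed=3)
        pos = [c for c in res.clusters if c.polarity == "positive"]
        assert all(0 < c.p_value <= 1 for c in res.clusters)
        pos.sort(key=lambda c: -c.mass)
        ps = [c.p_value for c in pos]
        assert ps == sorted(ps)

    def test_matches_mne_cluster_permutation(self, layout):
        """Independent cross-check: identical clusters and masses from
        MNE's sign-flip spatio-temporal cluster test."""
        from mne.stats import permutation_cluster_1samp_test
        from scipy import sparse

        rng = np.random.default_rng(12)
        n, n_ch, n_t = 10, 16, 20
        adj = layout.adjacency()[:n_ch, :n_ch]
        d = rng.normal(size=(n, n_ch, n_t))
        d[:, 3:6, 5:12] += 0.8
        ours = find_clusters(paired_tmap(d, np.zeros_like(d)), 2.0, adj)
        t_obs, clusters, _, _ = permutation_cluster_1samp_test(
            d.transpose(0, 2, 1), threshold=2.0, n_permutations=50,
            adjacency=sparse.coo_matrix(adj), out_type="indices",
            tail=0, seed=1, verbose="error")
        theirs = set()
        for comp in clusters:
            tt, cc = comp
            members = frozenset(zip(cc.tolist(), tt.tolist()))
            theirs.add((members, round(float(t_obs.T[cc, tt].sum()), 6)))
        mine = {(frozenset(c.members), round(c.mass, 6)) for c in ours}
        assert mine == theirs

    def test_injected_effect_found_in_roi_window(self, layout):
        """A strong congruence bump injected by the generator yields a
        significant positive cluster overlapping the CF ROI/window."""
        import dataclasses

        from olferp.erp import subject_condition_averages
        from olferp.layout import CF_ROI
        from olferp.simulate import (default_config, generate_behavior,
                                     generate_epochs)

        cfg = dataclasses.replace(default_config(n_participants=10, seed=55),
                                  noise_sd_uV=6.0)
        beh = generate_behavior(cfg)
        eps = generate_epochs(cfg, beh, layout)
        avgs = subject_condition_averages(eps, ["congruence"])
        res = cluster_test(avgs[("incongruent",)], avgs[("congruent",)],
                           layout, n_permutations=500, seed=5,
                           times=eps.times)
        assert res.significant
        cf = set(layout.index(CF_ROI))
        win = {i for i, t in enumerate(eps.times) if 0.32 <= t < 0.58}
        target = {(c, k) for c in cf for k in win}
        overlaps = [
            len(target & set(c.members)) / min(len(target), len(c.members))
            for c in res.significant if c.polarity == "positive"]
        assert max(overlaps) >= 0.5
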