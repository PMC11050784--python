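"""Adjacency, cluster formation and the ERP permutation test, with oracles."""

import numpy as np
import pytest
from scipy import stats

from jolreact import (ClusterPermutationTest, Montage, build_adjacency,
                      form_clusters, pointwise_paired_t)
from .conftest import toy_evoked_group


class TestAdjacency:
    def test_distance_threshold_is_inclusive_boundary(self):
        m44 = Montage(("A", "B"), np.array([[0, 0, 0], [44, 0, 0]], float))
        m46 = Montage(("A", "B"), np.array([[0, 0, 0], [46, 0, 0]], float))
        assert build_adjacency(m44).neighbors[0] == {1}
        assert build_adjacency(m46).neighbors[0] == frozenset()

    def test_zero_distance_gives_empty_graph(self, montage40):
        adj = build_adjacency(montage40, 0.0)
        assert all(len(s) == 0 for s in adj.neighbors)

    def test_symmetric_and_irreflexive(self, montage40):
        adj = build_adjacency(montage40)
        for i, s in enumerate(adj.neighbors):
            assert i not in s
            for j in s:
                assert i in adj.neighbors[j]

    def test_shipped_montage_mean_degree_near_reference(self, montage40):
        # the 45 mm rule on the shipped coordinates averages ~5 neighbors
        assert build_adjacency(montage40, 45.0).mean_degree == pytest.approx(
            5.15, abs=0.6)


class TestPointwiseT:
    def test_hand_computed_three_subject_dataset(self, small_montage):
        # subject differences at one electrode, two samples
        diffs = np.zeros((3, 4, 2))
        diffs[:, 1, 0] = [1.0, 2.0, 3.0]     # mean 2, sd 1, t = 2*sqrt(3)
        diffs[:, 1, 1] = [-1.0, 1.0, 0.0]    # mean 0, t = 0
        grp = toy_evoked_group(diffs, small_montage, t_start=0.0)
        t, p = pointwise_paired_t(grp, (0.0, 2.0), tail="greater")
        assert t.shape == (4, 2)
        assert t[1, 0] == pytest.approx(2 * np.sqrt(3))
        assert t[1, 1] == pytest.approx(0.0)
        assert p[1, 0] == pytest.approx(stats.t.sf(2 * np.sqrt(3), 2))

    def test_identical_conditions_give_zero_t_everywhere(self, small_montage):
        grp = toy_evoked_group(np.zeros((4, 4, 10)), small_montage)
        t, p = pointwise_paired_t(grp, (0.0, 18.0))
        assert np.all(t == 0.0)
        assert np.all(p == 1.0)  # zero-variance points are flagged out

    def test_map_dimensions_follow_window(self, montage40, rng):
        from jolreact.epochs import EvokedSet, TimeAxis
        data = rng.standard_normal((5, 2, 40, 1500))
        ev = EvokedSet([f"S{i}" for i in range(5)], data,
                       TimeAxis(500.0, -1000.0, 1500), montage40)
        t, p = pointwise_paired_t(ev, (0.0, 300.0))
        assert t.shape == (40, 151)


def _flood_fill_oracle(supra, adj_sets):
    """Brute-force BFS clustering; connectivity = time OR electrode adjacency."""
    seen = np.zeros_like(supra, dtype=bool)
    comps = []
    n_ch, n_sp = supra.shape
    for i in range(n_ch):
        for k in range(n_sp):
            if not supra[i, k] or seen[i, k]:
                continue
            comp = []
            stack = [(i, k)]
            seen[i, k] = True
            while stack:
                ci, ck = stack.pop()
                comp.append((ci, ck))
                cands = [(ci, ck - 1), (ci, ck + 1)] + [
                    (j, ck) for j in adj_sets[ci]]
                for ni, nk in cands:
                    if 0 <= nk < n_sp and supra[ni, nk] and not seen[ni, nk]:
                        seen[ni, nk] = True
                        stack.append((ni, nk))
            comps.append(frozenset(comp))
    return set(comps)


class TestClusterFormation:
    def _adjacency(self, montage):
        return build_adjacency(montage, 45.0)

    def test_single_supra_point(self, small_montage):
        t = np.zeros((4, 5))
        t[2, 3] = 4.0
        p = np.ones_like(t)
        p[2, 3] = 0.01
        cs = form_clusters(t, p, self._adjacency(small_montage))
        assert len(cs) == 1
        assert cs[0].t_sum == pytest.approx(4.0)
        assert set(map(tuple, cs[0].points)) == {(2, 3)}

    def test_non_neighboring_electrodes_stay_separate(self, small_montage):
        t = np.zeros((4, 5))
        t[0, 2] = t[3, 2] = 4.0  # electrodes A and D are 90 mm apart
        p = np.where(t > 0, 0.01, 1.0)
        cs = form_clusters(t, p, self._adjacency(small_montage))
        assert len(cs) == 2

    def test_matches_flood_fill_oracle_on_random_grids(self, small_montage, rng):
        adj = self._adjacency(small_montage)
        adj_sets = [set(s) for s in adj.neighbors]
        for _ in range(25):
            t = rng.standard_normal((4, 20))
            p = np.where(t > 0.8, 0.01, 1.0)
            cs = form_clusters(t, p, adj, cluster_alpha=0.05)
            got = {frozenset(map(tuple, c.points)) for c in cs}
            expected = _flood_fill_oracle((p < 0.05) & (t > 0), adj_sets)
            assert got == expected
            for c in cs:
                members = np.array(list(map(tuple, c.points)))
                assert c.t_sum == pytest.approx(t[members[:, 0], members[:, 1]].sum())


def _exhaustive_sign_flip_p(diffs, adj, threshold_alpha, observed_sum):
    """Enumerate all 2^n sign patterns; independent max-cluster-sum null."""
    n = diffs.shape[0]
    df = n - 1
    t_thr = stats.t.ppf(1 - threshold_alpha, df)
    maxima = []
    adj_sets = [set(s) for s in adj.neighbors]
    for bits in range(2 ** n):
        signs = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(n)])
        d = diffs * signs[:, None, None]
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
        supra = t > t_thr
        comps = _flood_fill_oracle(supra, adj_sets)
        sums = [sum(t[i, k] for i, k in comp) for comp in comps]
        maxima.append(max(sums) if sums else 0.0)
    maxima = np.asarray(maxima)
    return np.mean(maxima >= observed_sum)


class TestPermutationTest:
    def test_p_matches_exhaustive_enumeration_for_n5(self, small_montage, rng):
        diffs = rng.standard_normal((5, 4, 8)) + 0.9
        grp = toy_evoked_group(diffs, small_montage, t_start=0.0)
        test = ClusterPermutationTest(grp, (0.0, 14.0),
                                      build_adjacency(small_montage))
        res = test.fit(n_permutations=3000, seed=21)
        assert res.clusters, "expected at least one observed cluster"
        c = res.clusters[0]
        p_exact = _exhaustive_sign_flip_p(diffs, test.adjacency, 0.05, c.t_sum)
        assert c.p_rand == pytest.approx(p_exact, abs=0.02)

    def test_subject_relabeling_changes_p_only_within_mc_error(self, small_montage, rng):
        diffs = rng.standard_normal((8, 4, 10)) + 0.6
        grp1 = toy_evoked_group(diffs, small_montage, t_start=0.0)
        grp2 = toy_evoked_group(diffs[::-1], small_montage, t_start=0.0)
        p1 = ClusterPermutationTest(grp1, (0.0, 18.0)).fit(2000, seed=5).clusters[0].p_rand
        p2 = ClusterPermutationTest(grp2, (0.0, 18.0)).fit(2000, seed=6).clusters[0].p_rand
        assert abs(p1 - p2) < 0.04

    def test_larger_effects_never_raise_cluster_p(self, small_montage, rng):
        template = np.zeros((4, 30))
        template[1:3, 10:20] = 1.0
        med_p = []
        for amp in (0.3, 0.9):
            ps = []
            for rep in range(10):
                noise = rng.standard_normal((8, 4, 30))
                grp = toy_evoked_group(noise + amp * template, small_montage,
                                       t_start=0.0)
                res = ClusterPermutationTest(grp, (0.0, 58.0)).fit(300, seed=rep)
                ps.append(res.clusters[0].p_rand if res.clusters else 1.0)
            med_p.append(np.median(ps))
        assert med_p[1] <= med_p[0]

    def test_cluster_membership_matches_mne(self, small_montage, rng):
        mne = pytest.importorskip("mne")
        from scipy import sparse

        diffs = rng.standard_normal((9, 4, 25)) + 0.45
        grp = toy_evoked_group(diffs, small_montage, t_start=0.0)
        test = ClusterPermutationTest(grp, (0.0, 48.0))
        res = test.fit(500, seed=3)
        n = diffs.shape[0]
        thr = stats.t.ppf(1 - 0.05, n - 1)
        adj_mat = sparse.lil_matrix((4, 4))
        for i, s in enumerate(test.adjacency.neighbors):
            for j in s:
                adj_mat[i, j] = 1
        X = np.transpose(diffs, (0, 2, 1))  # mne wants obs x time x space
        t_obs, clusters, _, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            X, threshold=thr, adjacency=adj_mat.tocsr(), tail=1,
            n_permutations=100, seed=1, out_type="indices", verbose="error")
        mne_sets = set()
        for time_idx, ch_idx in clusters:
            mne_sets.add(frozenset(zip(ch_idx, time_idx)))
        ours = {frozenset(map(tuple, c.points)) for c in res.clusters}
        assert ours == mne_sets

    def test_pure_noise_type_one_error_near_alpha(self, small_montage, rng):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            diffs = rng.standard_normal((8, 4, 15))
            grp = toy_evoked_group(diffs, small_montage, t_start=0.0)
            res = ClusterPermutationTest(grp, (0.0, 28.0)).fit(200, seed=rep)
            if res.clusters and res.clusters[0].p_rand < 0.05:
                hits += 1
        assert 0.0 <= hits / n_rep <= 0.12
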