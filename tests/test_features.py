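"""Feature families: bin means, seeds, idiosyncrasy, graph measures."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fcmethods as fc
from fcmethods.atlas import BinScheme, HomotopicPairing, make_strength_bins
from fcmethods.connectivity import ConnectivityMatrix
from fcmethods.features import (ConnectivityFeatureExtractor,
                                ReferenceProfile, distance_bin_features,
                                global_efficiency, homotopic_features,
                                idiosyncrasy, modularity_score,
                                network_features, normalize_timeseries,
                                seed_cortical_features,
                                strength_bin_features)


def _profile(mean_conn, centroid_dist=None, path_lengths=None):
    r = mean_conn.shape[0]
    if centroid_dist is None:
        centroid_dist = np.abs(np.subtract.outer(np.arange(r),
                                                 np.arange(r))) * 10.0
    if path_lengths is None:
        path_lengths = pd.DataFrame(
            columns=["region_a", "region_b", "length_mm"])
    return ReferenceProfile(mean_conn=mean_conn, path_lengths=path_lengths,
                            centroid_dist=centroid_dist)


def _sym(r, off):
    m = np.full((r, r), off, dtype=float)
    np.fill_diagonal(m, 1.0)
    return m


class TestBinFeatures:
    def test_subject_equal_to_profile_recovers_bin_means(self, rng):
        r = 6
        mean_conn = _sym(r, 0.0)
        iu = np.triu_indices(r, 1)
        vals = rng.uniform(-0.15, 0.55, iu[0].size)
        mean_conn[iu] = vals
        mean_conn[(iu[1], iu[0])] = vals
        profile = _profile(mean_conn)
        scheme = make_strength_bins(profile)
        feats = strength_bin_features(
            ConnectivityMatrix(mean_conn), profile, scheme)
        idx = scheme.assign(vals)
        for b in scheme.retained_bins:
            assert feats[b] == pytest.approx(vals[idx == b].mean())

    def test_enumeration_oracle_on_4_region_toy(self):
        # hand-assigned bins: pairs (0,1),(0,2) in bin of 0.10-0.12;
        # (0,3),(1,2) near 0.30; (1,3),(2,3) near 0.50
        mean = _sym(4, 0.0)
        pairs = {(0, 1): 0.10, (0, 2): 0.11, (0, 3): 0.30, (1, 2): 0.31,
                 (1, 3): 0.50, (2, 3): 0.51}
        subj = _sym(4, 0.0)
        subj_vals = {(0, 1): 0.2, (0, 2): 0.4, (0, 3): -0.1, (1, 2): 0.3,
                     (1, 3): 0.0, (2, 3): 0.8}
        for (i, j), v in pairs.items():
            mean[i, j] = mean[j, i] = v
        for (i, j), v in subj_vals.items():
            subj[i, j] = subj[j, i] = v
        profile = _profile(mean)
        scheme = make_strength_bins(profile)
        feats = strength_bin_features(ConnectivityMatrix(subj), profile,
                                      scheme)
        expect = {15: (0.2 + 0.4) / 2, 25: (-0.1 + 0.3) / 2,
                  35: (0.0 + 0.8) / 2}
        assert {b: pytest.approx(v) for b, v in feats.items()} == expect

    def test_at_most_40_strength_columns(self, small_profile):
        scheme = make_strength_bins(small_profile)
        assert len(scheme.retained_bins) <= 40

    def test_path_features_use_only_connected_pairs(self):
        mean = _sym(5, 0.2)
        subj_mat = _sym(5, 0.0)
        subj_mat[0, 1] = subj_mat[1, 0] = 0.9
        subj_mat[2, 3] = subj_mat[3, 2] = -0.5
        subj_mat[0, 4] = subj_mat[4, 0] = 0.7   # not structurally connected
        paths = pd.DataFrame({"region_a": [0, 2], "region_b": [1, 3],
                              "length_mm": [20.0, 320.0]})
        profile = _profile(mean, path_lengths=paths)
        scheme = fc.make_distance_bins(profile, "path_length")
        feats = distance_bin_features(ConnectivityMatrix(subj_mat),
                                      profile, scheme)
        assert feats.to_dict() == {0: pytest.approx(0.9),
                                   6: pytest.approx(-0.5)}

    def test_single_bin_equals_mean_offdiagonal(self, rng):
        r = 5
        mean = _sym(r, 0.3)
        subj_mat = _sym(r, 0.0)
        iu = np.triu_indices(r, 1)
        vals = rng.uniform(-1, 1, iu[0].size)
        subj_mat[iu] = vals
        subj_mat[(iu[1], iu[0])] = vals
        profile = _profile(mean)
        scheme = make_strength_bins(profile)
        feats = strength_bin_features(ConnectivityMatrix(subj_mat),
                                      profile, scheme)
        assert len(feats) == 1
        assert feats.iloc[0] == pytest.approx(vals.mean())


class TestHomotopicAndSeeds:
    def test_single_pair_value(self):
        conn = ConnectivityMatrix(np.array([[1.0, 0.7], [0.7, 1.0]]))
        pairing = HomotopicPairing(pairs=[(0, 1)], excluded=[])
        vals, mean = homotopic_features(conn, pairing)
        assert vals.tolist() == [0.7] and mean == 0.7

    def test_count_and_mean(self, small_cohort, rng):
        atlas = small_cohort.atlas
        pairing = fc.find_homotopic_pairs(atlas)
        r = atlas.n_regions
        m = rng.uniform(-0.5, 0.5, (r, r))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        vals, mean = homotopic_features(ConnectivityMatrix(m), pairing)
        assert len(vals) == len(pairing.pairs)
        assert mean == pytest.approx(vals.mean())

    def test_seed_targets_are_ipsilateral_lookups(self, small_cohort, rng):
        atlas = small_cohort.atlas
        r = atlas.n_regions
        m = rng.uniform(-0.5, 0.5, (r, r))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        conn = ConnectivityMatrix(m)
        for hemi in ("left", "right"):
            feats = seed_cortical_features(conn, atlas, "thalamus", hemi)
            targets = atlas.indices(hemisphere=hemi, compartment="cortical")
            assert len(feats) == len(targets)
            si = fc.synth.seed_indices(atlas, "thalamus", hemi)
            for t in targets:
                assert feats[atlas.regions[t].name] == m[si, t]

    def test_seed_feature_counts_match_hemisphere_counts(self, paper_atlas,
                                                         rng):
        m = np.eye(361)
        conn = ConnectivityMatrix(m)
        left = seed_cortical_features(conn, paper_atlas, "caudate", "left")
        right = seed_cortical_features(conn, paper_atlas, "caudate",
                                       "right")
        assert (len(left), len(right)) == (161, 172)


class TestIdiosyncrasy:
    def test_zero_iff_equal(self, small_profile):
        conn = ConnectivityMatrix(small_profile.mean_conn)
        assert idiosyncrasy(conn, small_profile) == 0.0

    def test_two_region_closed_form(self):
        profile = _profile(_sym(2, 0.3))
        conn = ConnectivityMatrix(_sym(2, 0.5))
        # brute-force elementwise sum over the full 2x2 matrix
        brute = sum((np.asarray(conn.values) - profile.mean_conn
                     ).ravel() ** 2) / (4 - 1)
        assert idiosyncrasy(conn, profile) == pytest.approx(0.08 / 3)
        assert idiosyncrasy(conn, profile) == pytest.approx(brute)

    def test_quadratic_scaling(self, small_profile, rng):
        base = small_profile.mean_conn
        dev = rng.uniform(-0.05, 0.05, base.shape)
        dev = (dev + dev.T) / 2
        np.fill_diagonal(dev, 0.0)
        s1 = idiosyncrasy(ConnectivityMatrix(base + dev), small_profile)
        s2 = idiosyncrasy(ConnectivityMatrix(base + 2 * dev),
                          small_profile)
        assert s2 == pytest.approx(4 * s1, rel=1e-10)
        assert s1 > 0

    def test_mismatched_sizes_rejected(self, small_profile):
        with pytest.raises(ValueError):
            idiosyncrasy(ConnectivityMatrix(np.eye(3)), small_profile)


def exhaustive_modularity(w):
    """Best Q over all partitions of an n-node weighted graph."""
    import networkx as nx
    g = nx.from_numpy_array(w)
    n = w.shape[0]
    best = -np.inf

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1:]
            yield part + [{first}]

    for part in partitions(list(range(n))):
        q = nx.community.modularity(g, part, weight="weight")
        best = max(best, q)
    return best


class TestModularity:
    def test_two_cliques_match_exhaustive_search(self):
        w = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(grp, 2):
                w[i, j] = w[j, i] = 1.0
        q, part = modularity_score(w)
        assert q == pytest.approx(exhaustive_modularity(w), abs=1e-9)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]

    def test_uniform_complete_graph_has_zero_q(self):
        w = np.ones((5, 5))
        q, _ = modularity_score(w)
        assert q == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_8_node_graphs_reach_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        q, _ = modularity_score(w)
        assert q >= exhaustive_modularity(w) - 1e-9

    def test_negative_weights_zeroed_and_diagonal_ignored(self):
        w = np.array([[1.0, 0.9, -0.8], [0.9, 1.0, -0.7],
                      [-0.8, -0.7, 1.0]])
        q, part = modularity_score(w)
        pos = np.array([[0, 0.9, 0], [0.9, 0, 0], [0, 0, 0]])
        assert q == pytest.approx(exhaustive_modularity(pos), abs=1e-9)

    def test_all_zero_graph_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            q, part = modularity_score(-np.ones((4, 4)))
        assert q == 0.0 and len(part) == 4


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        assert global_efficiency(np.ones((6, 6))) == pytest.approx(1.0)

    def test_path_graph_closed_form(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert global_efficiency(w) == pytest.approx(5 / 6)

    def test_edgeless_graph(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_matches_floyd_warshall_oracle(self, rng):
        n = 7
        w = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        # dense Floyd-Warshall on reciprocal lengths
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(n):
            d = np.minimum(d, d[:, [k]] + d[[k], :])
        inv = np.where(np.isfinite(d), 1.0 / np.where(d > 0, d, np.inf),
                       0.0)
        np.fill_diagonal(inv, 0.0)
        expect = inv.sum() / (n * (n - 1))
        assert global_efficiency(w) == pytest.approx(expect, abs=1e-12)

    def test_range_for_unit_interval_weights(self, rng):
        w = rng.uniform(0, 1, (9, 9))
        w = (w + w.T) / 2
        e = global_efficiency(w)
        assert 0.0 <= e <= 1.0

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.ones((1, 1)))


class TestNetworkFeatures:
    def test_pair_counts_match_arithmetic(self, paper_atlas):
        conn = ConnectivityMatrix(np.eye(361))
        dmn, _ = network_features(conn, paper_atlas, "default")
        assert len(dmn) == 41 * 40 // 2 == 820
        between, _ = network_features(
            conn, paper_atlas, "default",
            ("salience", "dorsal_attention"))
        assert len(between) == 41 * 36 == 1476

    def test_constant_matrix_gives_constant_summaries(self, paper_atlas):
        m = _sym(361, 0.25)
        conn = ConnectivityMatrix(m)
        _, mean_w = network_features(conn, paper_atlas, "default")
        _, mean_b = network_features(conn, paper_atlas, "default",
                                     ("salience", "dorsal_attention"))
        assert mean_w == pytest.approx(0.25)
        assert mean_b == pytest.approx(0.25)


def test_normalization_preserves_correlation(rng):
    ts = rng.standard_normal((60, 5)) * rng.uniform(0.5, 3, 5) + 2
    norm = normalize_timeseries(ts)
    assert norm.min() >= -1 - 1e-12 and norm.max() <= 1 + 1e-12
    assert np.allclose(np.corrcoef(ts, rowvar=False),
                       np.corrcoef(norm, rowvar=False))


@pytest.fixture(scope="module")
def fitted(small_cohort, small_profile):
    ext = ConnectivityFeatureExtractor(
        atlas=small_cohort.atlas, profile=small_profile,
        n_modularity_restarts=3)
    return ext.fit()


@pytest.fixture(scope="module")
def table(fitted, small_cohort):
    with pytest.warns(UserWarning):
        return fitted.transform(small_cohort.subjects[:4])


class TestExtractor:
    def test_definition_bookkeeping(self, fitted, table):
        assert table.values.shape == (4, fitted.n_features_out_)
        ids = [d.feature_id for d in fitted.definitions_]
        assert len(set(ids)) == len(ids)
        assert list(table.values.columns) == ids

    def test_scalar_families_present_once(self, table):
        methods = table.methods
        for scalar in ("idiosyncrasy", "modularity", "global_efficiency"):
            assert (methods == scalar).sum() == 1

    def test_matches_direct_family_functions(self, fitted, table,
                                             small_cohort, small_profile):
        subj = small_cohort.subjects[0]
        mask = fc.censor_volumes(subj.fd_trace)
        conn = fc.connectivity_matrix(subj.timeseries, mask)
        row = table.values.iloc[0]
        s2 = idiosyncrasy(conn, small_profile)
        assert row["idiosyncrasy:value"] == pytest.approx(s2)
        direct = strength_bin_features(conn, small_profile,
                                       fitted.strength_scheme_)
        for b, v in direct.items():
            assert row[f"strength_bin:bin{b:02d}"] == pytest.approx(v)
        vals, mean = homotopic_features(conn, fitted.pairing_)
        hom = row[[c for c in table.values.columns
                   if c.startswith("homotopic:")]]
        assert hom.iloc[-1] == pytest.approx(mean)
        assert np.allclose(hom.iloc[:-1].to_numpy(), vals.to_numpy())

    def test_permutation_equivariance(self, small_cohort, small_profile,
                                      rng):
        """Permuting region order leaves feature values unchanged."""
        atlas = small_cohort.atlas
        subj = small_cohort.subjects[0]
        perm = rng.permutation(atlas.n_regions)
        regions = [atlas.regions[i] for i in perm]
        perm_atlas = fc.RegionAtlas([
            fc.Region(region_id=r.region_id, name=r.name,
                      hemisphere=r.hemisphere, compartment=r.compartment,
                      network=r.network, centroid=r.centroid)
            for r in regions])
        perm_profile = ReferenceProfile(
            mean_conn=small_profile.mean_conn[np.ix_(perm, perm)],
            path_lengths=_permute_paths(small_profile.path_lengths, perm),
            centroid_dist=small_profile.centroid_dist[np.ix_(perm, perm)])
        base = ConnectivityFeatureExtractor(
            atlas=atlas, profile=small_profile,
            methods=("strength_bin", "homotopic", "thalamocortical",
                     "idiosyncrasy"), include_summary_means=False).fit()
        permuted = ConnectivityFeatureExtractor(
            atlas=perm_atlas, profile=perm_profile,
            methods=("strength_bin", "homotopic", "thalamocortical",
                     "idiosyncrasy"), include_summary_means=False).fit()
        import dataclasses
        subj_perm = dataclasses.replace(
            subj, timeseries=subj.timeseries[:, perm])
        t0 = base.transform([subj]).values.iloc[0]
        t1 = permuted.transform([subj_perm]).values.iloc[0]
        assert sorted(t0.index) == sorted(t1.index)
        pd.testing.assert_series_equal(t0.sort_index(), t1.sort_index(),
                                       atol=1e-10, rtol=0)


def _permute_paths(paths, perm):
    inv = np.argsort(perm)
    out = paths.copy()
    out["region_a"] = inv[paths["region_a"].to_numpy()]
    out["region_b"] = inv[paths["region_b"].to_numpy()]
    return out
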