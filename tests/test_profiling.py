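import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from dsrt import screen_sim as ss
from dsrt.profiling import (cluster_profiles, define_responder_groups,
                            euclidean_distance_matrix, export_cluster_files,
                            marker_ttest, read_cdt, read_tree_file,
                            spearman_distance_matrix)


def brute_force_complete_linkage(dist):
    """Independent oracle: enumerate agglomerative merges directly.

    Returns the sorted merge heights and, per merge, the partition of
    leaf indices after that merge.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[min(a, b)] = merged
        heights.append(d)
        partitions.append(frozenset(clusters.values()))
    return heights, partitions


def partitions_from_linkage(z, heights):
    out = []
    for h in heights:
        labels = fcluster(z, t=h + 1e-9, criterion="distance")
        groups = {}
        for idx, lab in enumerate(labels):
            groups.setdefault(lab, set()).add(idx)
        out.append(frozenset(frozenset(g) for g in groups.values()))
    return out


#: Seeds giving all-distinct pairwise Spearman distances at 15 columns
#: (tied distances make the complete-linkage dendrogram ambiguous, so the
#: oracle comparison is only meaningful on tie-free inputs).
TIE_FREE_SEEDS = {3: 3000, 4: 4000, 5: 5000, 6: 6001}


def tie_free_matrix(n):
    rng = np.random.default_rng(TIE_FREE_SEEDS[n])
    return pd.DataFrame(rng.normal(size=(n, 15)),
                        index=[f"d{i}" for i in range(n)])


def assert_matches_brute_force(matrix, metric):
    dist = (spearman_distance_matrix(matrix) if metric == "spearman"
            else euclidean_distance_matrix(matrix))
    vals = dist[np.triu_indices_from(dist, k=1)]
    assert len(set(np.round(vals, 12))) == len(vals), "tied distances"
    heights, partitions = brute_force_complete_linkage(dist)
    result = cluster_profiles(matrix, row_metric=metric)
    z_heights = result.row_linkage[:, 2]
    np.testing.assert_allclose(np.sort(z_heights), np.sort(heights),
                               atol=1e-9)
    assert partitions_from_linkage(result.row_linkage, heights) == partitions


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0],
                          [9.0, 1.0, 5.0]], index=list("abc"))
        # rows a and b are rank-identical -> Spearman distance 0
        result = cluster_profiles(m)
        assert result.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {result.row_labels[int(result.row_linkage[0, 0])],
                 result.row_labels[int(result.row_linkage[0, 1])]}
        assert first == {"a", "b"}

    def test_anticorrelated_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        d = spearman_distance_matrix(m)
        assert d[0, 1] == pytest.approx(2.0)

    def test_zero_variance_profile_max_distance(self, caplog):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [3.0, 2.0, 1.0]],
                         index=["flat", "slope"])
        with caplog.at_level("WARNING", logger="dsrt.profiling"):
            d = spearman_distance_matrix(m)
        assert d[0, 1] == pytest.approx(2.0)
        assert any("flat" in r.message for r in caplog.records)

    @pytest.mark.parametrize("metric", ["spearman", "euclidean"])
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_brute_force_oracle(self, metric, n):
        assert_matches_brute_force(tie_free_matrix(n), metric)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(6, 5)),
                         index=[f"d{i}" for i in range(6)],
                         columns=[f"c{i}" for i in range(5)])
        r1 = cluster_profiles(m)
        perm = m.iloc[[3, 1, 5, 0, 4, 2], [2, 0, 4, 1, 3]]
        r2 = cluster_profiles(perm)
        np.testing.assert_allclose(np.sort(r1.row_linkage[:, 2]),
                                   np.sort(r2.row_linkage[:, 2]), atol=1e-9)
        heights = r1.row_linkage[:, 2]
        p1 = partitions_from_linkage(r1.row_linkage, heights)
        # map partitions through labels for comparison
        lab1 = [frozenset(frozenset(r1.row_labels[i] for i in g) for g in p)
                for p in p1]
        p2 = partitions_from_linkage(r2.row_linkage, heights)
        labels2 = list(perm.index)
        lab2 = [frozenset(frozenset(labels2[i] for i in g) for g in p)
                for p in p2]
        assert lab1 == lab2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(5, 6)))
        d1 = spearman_distance_matrix(m)
        d2 = spearman_distance_matrix(np.exp(m * 3.0) + 7.0)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1.0, 2.0]]))

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(8, 6)))
        result = cluster_profiles(m)
        assert np.all(np.diff(result.row_linkage[:, 2]) >= -1e-12)


class TestExport:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(8)
        return pd.DataFrame(rng.normal(size=(5, 4)),
                            index=[f"drug{i}" for i in range(5)],
                            columns=[f"line{i}" for i in range(4)])

    def test_two_by_two(self, tmp_path):
        m = pd.DataFrame([[1.0, 2.0], [4.0, 3.0]], index=["a", "b"],
                         columns=["x", "y"])
        result = cluster_profiles(m)
        paths = export_cluster_files(m, result, tmp_path / "out")
        cdt = (tmp_path / "out.cdt").read_text().splitlines()
        assert len(cdt) == 5  # header + AID + EWEIGHT + 2 data rows
        assert len(read_tree_file(paths["gtr"])) == 1

    def test_cdt_round_trip_exact(self, matrix, tmp_path):
        result = cluster_profiles(matrix)
        paths = export_cluster_files(matrix, result, tmp_path / "out")
        loaded = read_cdt(paths["cdt"])
        reordered = matrix.loc[result.row_order, result.col_order]
        pd.testing.assert_frame_equal(
            loaded, reordered, check_names=False, atol=1e-9)

    def test_leaf_order_matches_result(self, matrix, tmp_path):
        result = cluster_profiles(matrix)
        paths = export_cluster_files(matrix, result, tmp_path / "out")
        loaded = read_cdt(paths["cdt"])
        assert list(loaded.index) == list(result.row_order)
        assert list(loaded.columns) == [str(c) for c in result.col_order]

    def test_gtr_heights_round_trip(self, matrix, tmp_path):
        result = cluster_profiles(matrix)
        paths = export_cluster_files(matrix, result, tmp_path / "out")
        rows = read_tree_file(paths["gtr"])
        np.testing.assert_allclose([r[3] for r in rows],
                                   result.row_linkage[:, 2], atol=1e-9)


class TestResponderGroups:
    def records(self):
        return pd.DataFrame({
            "cell_line": ["L1", "L1", "L2", "L2"],
            "compound_id": ["mit1", "mit2", "mit1", "mit2"],
            "readout": "tox_fluor",
            "dss": [22.0, 18.0, 1.5, 0.5],
            "drug_class": "taxane",
        })

    def test_two_line_split(self):
        sens, insens, means = define_responder_groups(
            self.records(), "taxane", "tox_fluor", threshold=5.0)
        assert sens == {"L1"} and insens == {"L2"}
        assert means["L1"] == pytest.approx(20.0)

    def test_all_below_threshold_warns(self, caplog):
        with caplog.at_level("WARNING", logger="dsrt.profiling"):
            sens, insens, _ = define_responder_groups(
                self.records(), "taxane", "tox_fluor", threshold=50.0)
        assert sens == set() and insens == {"L1", "L2"}
        assert caplog.records

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="proteasome"):
            define_responder_groups(self.records(), "proteasome",
                                    "tox_fluor", 5.0)

    def test_planted_subset_recovered_zero_noise(self, cell_lines):
        from dsrt import plates, scoring
        lib = ss.make_library(10, {"proteasome": 1.0}, seed=21)
        truth = ss.make_truth(cell_lines, lib, seed=21)
        noise = ss.NoiseModel(cv_mult=0.0, sd_add=0.0, seed=0)
        screen = ss.simulate_screen(cell_lines, lib, truth, noise)
        norm, _ = plates.normalize_screen(screen)
        records = scoring.score_screen(norm)
        sens, _, _ = define_responder_groups(
            records, "proteasome", "tox_fluor", threshold=5.0,
            class_map=truth.compound_class)
        assert sens == set(truth.sensitive_lines["proteasome"])


class TestMarkerTtest:
    def test_identical_groups_t_zero_p_one(self):
        table = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["m"],
                             columns=["a", "b", "c", "d"])
        res = marker_ttest(table, (["a", "b"], ["c", "d"]))
        assert res[0].t == 0.0 and res[0].p == 1.0

    def test_matches_hand_computed_welch(self):
        a = np.array([3.1, 2.9, 3.4, 3.0])
        b = np.array([1.2, 1.5, 1.1, 1.6])
        table = pd.DataFrame([np.concatenate([a, b])], index=["m"],
                             columns=list("abcdefgh"))
        res = marker_ttest(table, (list("abcd"), list("efgh")))
        # Welch statistic computed from first principles
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
        from scipy.stats import t as t_dist
        p_hand = 2 * t_dist.sf(abs(t_hand), df_hand)
        assert res[0].t == pytest.approx(t_hand, abs=1e-12)
        assert res[0].p == pytest.approx(p_hand, abs=1e-12)

    def test_group_too_small_raises(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="group B"):
            marker_ttest(table, (["a", "b"], ["c"]))

    def test_power_on_planted_markers(self):
        hits = 0
        for seed in range(25):
            table, truth = ss.simulate_marker_table(
                [f"s{i}" for i in range(4)], [f"r{i}" for i in range(4)],
                n_markers=70, n_informative=9, effect_size=3.0, seed=seed)
            res = marker_ttest(table, (truth["group_a"], truth["group_b"]))
            found = {r.marker for r in res if r.significant}
            hits += len(found & set(truth["informative"])) >= 7
        assert hits >= 20  # >=80% of seeds

    def test_bh_adjustment_more_conservative(self):
        table, truth = ss.simulate_marker_table(
            ["a", "b", "c", "d"], ["e", "f", "g", "h"],
            n_markers=50, n_informative=5, effect_size=1.0, seed=3)
        raw = marker_ttest(table, (truth["group_a"], truth["group_b"]))
        adj = marker_ttest(table, (truth["group_a"], truth["group_b"]),
                           adjust="bh")
        n_raw = sum(r.significant for r in raw)
        n_adj = sum(r.significant for r in adj)
        assert n_adj <= n_raw
        assert all(r.p_adjusted >= r.p - 1e-12 for r in adj)
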