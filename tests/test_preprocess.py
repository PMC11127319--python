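import math

import numpy as np
import pandas as pd
import pytest

from dmscore.data import screen_from_frame
from dmscore.preprocess import (
    assign_mean_groups,
    assign_positions,
    filter_variants,
    impute_counts,
    integrate_replicates,
    normalize,
    preprocess_screen,
)
from tests.conftest import make_screen


class TestFilter:
    def base_counts(self):
        # V=4, T=3, R=1; variant 1 missing 2/4, variant 2 missing 3/4
        c = np.arange(16, dtype=float).reshape(4, 4, 1) + 1
        c[1, :2, 0] = np.nan
        c[2, :3, 0] = np.nan
        return c

    def test_exactly_at_threshold_retained_strictly_more_removed(self):
        sc = make_screen(self.base_counts())
        out = filter_variants(sc, max_missing_frac=0.5)
        kept = set(out.annotations["variant_id"])
        assert "v1" in kept  # 2/4 missing == 0.5: "more than" is strict
        assert "v2" not in kept  # 3/4 missing > 0.5
        assert "v0" in kept and "v3" in kept

    def test_per_replicate_filtering_keeps_other_replicates(self):
        c = np.ones((3, 4, 2))
        c[1, :3, 0] = np.nan  # dropped in replicate 1 only
        sc = make_screen(c)
        out = filter_variants(sc)
        assert np.isnan(out.counts[1, :, 0]).all()
        assert not np.isnan(out.counts[1, :, 1]).any()


class TestImpute:
    def test_zero_fill(self):
        c = np.ones((3, 4, 1)) * 5
        c[0, 2, 0] = np.nan
        out = impute_counts(make_screen(c), method="zero")
        assert out.counts[0, 2, 0] == 0

    def test_knn_with_exact_duplicate_neighbor(self):
        c = np.tile(np.array([4.0, 8.0, 16.0, 32.0]), (6, 1))[:, :, None]
        c[0, 2, 0] = np.nan
        out = impute_counts(make_screen(c), method="knn", k=1)
        assert out.counts[0, 2, 0] == pytest.approx(16.0, abs=1e-9)

    def test_knn_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        V, Tp1 = 30, 4
        counts = rng.integers(1, 500, size=(V, Tp1, 1)).astype(float)
        missing = [(0, 1), (7, 3), (12, 0)]
        for v, t in missing:
            counts[v, t, 0] = np.nan
        k = 4
        out = impute_counts(make_screen(counts), method="knn", k=k)
        X = np.log(counts[:, :, 0] + 0.5)
        for v, t in missing:
            dists = []
            for u in range(V):
                if u == v or np.isnan(X[u, t]):
                    continue
                mutual = ~np.isnan(X[v]) & ~np.isnan(X[u])
                d = math.sqrt(
                    Tp1 / mutual.sum() * np.sum((X[v][mutual] - X[u][mutual]) ** 2)
                )
                dists.append((d, u))
            nbrs = [u for _, u in sorted(dists)[:k]]
            expected = math.exp(np.mean(X[nbrs, t])) - 0.5
            assert out.counts[v, t, 0] == pytest.approx(expected, rel=1e-9)


class TestNormalize:
    def test_variant_tracking_wildtype_scores_zero(self):
        # variant and wild-type both 3 -> 7: log-ratios cancel
        c = np.array([[[3.0], [7.0]], [[3.0], [7.0]]])
        sc = make_screen(c, mutation_types=["synonymous", "missense"])
        sc.annotations.loc[0, "is_wildtype_reference"] = True
        ns = normalize(sc, method="wt")
        assert ns.m[1, 1, 0] == pytest.approx(0.0)

    def test_hand_computed_log_ratio(self):
        c = np.array([[[7.0], [7.0]], [[7.0], [15.0]]])
        sc = make_screen(c, mutation_types=["synonymous", "missense"])
        sc.annotations.loc[0, "is_wildtype_reference"] = True
        ns = normalize(sc)
        assert ns.m[1, 1, 0] == pytest.approx(math.log(15.5 / 7.5), abs=1e-10)

    def test_t0_always_zero(self, sim_default):
        ns = normalize(impute_counts(filter_variants(sim_default.screen), "zero"))
        np.testing.assert_allclose(ns.m[:, 0, :], 0.0)

    def test_wildtype_series_itself_is_identically_zero(self):
        rng = np.random.default_rng(0)
        c = rng.integers(10, 100, size=(5, 3, 2)).astype(float)
        sc = make_screen(c)
        sc.annotations.loc[0, "is_wildtype_reference"] = True
        ns = normalize(sc)
        np.testing.assert_allclose(ns.m[0], 0.0, atol=1e-12)


class TestIntegrate:
    def test_missing_replicate_gets_mean_of_others(self):
        c = np.ones((12, 3, 3)) * 10
        c[1, :, 2] = np.nan
        c[1, :, 0] = [10, 20, 40]
        c[1, :, 1] = [10, 30, 50]
        sc = make_screen(c)
        ns = integrate_replicates(normalize(sc, method="total"))
        expected = 0.5 * (ns.m[1, :, 0] + ns.m[1, :, 1])
        np.testing.assert_allclose(ns.m[1, :, 2], expected)

    def test_complete_variant_unchanged_and_r1_identity(self):
        c = np.abs(np.random.default_rng(1).integers(5, 50, size=(4, 3, 1))).astype(float)
        ns = normalize(make_screen(c), method="total")
        out = integrate_replicates(ns)
        np.testing.assert_array_equal(out.m, ns.m)


class TestPositions:
    def build(self, n_pos, per_pos, n_syn):
        V = n_pos * per_pos + n_syn
        types = ["missense"] * (n_pos * per_pos) + ["synonymous"] * n_syn
        positions = [p for p in range(1, n_pos + 1) for _ in range(per_pos)] + [1] * n_syn
        ann = pd.DataFrame(
            {
                "variant_id": [f"x{i}" for i in range(V)],
                "position": positions,
                "mutant": [f"m{i}" for i in range(V)],
                "mutation_type": types,
            }
        )
        counts = np.full((V, 2, 1), 10.0)
        sc = screen_from_frame(ann, counts, 1, 1)
        return normalize(sc, method="total")

    def test_control_positions_sized_by_max_nonsyn(self):
        ns = assign_positions(self.build(n_pos=5, per_pos=20, n_syn=60))
        syn = ns.annotations["mutation_type"] == "synonymous"
        labels, sizes = np.unique(ns.position_label[syn.to_numpy()], return_counts=True)
        assert len(labels) == 3 and (sizes == 20).all()
        # control labels live above the real residue range
        assert labels.min() > 5

    def test_control_sizes_sum_to_synonymous_count(self):
        ns = assign_positions(self.build(n_pos=4, per_pos=12, n_syn=31))
        syn = (ns.annotations["mutation_type"] == "synonymous").to_numpy()
        assert (ns.position_label[syn] > 4).all()
        assert syn.sum() == 31

    def test_dense_positions_unchanged(self):
        ns = assign_positions(self.build(n_pos=4, per_pos=19, n_syn=19), min_variants=10)
        nonsyn = (ns.annotations["mutation_type"] == "missense").to_numpy()
        np.testing.assert_array_equal(
            ns.position_label[nonsyn], ns.annotations["position"].to_numpy()[nonsyn]
        )

    def test_sparse_adjacent_positions_merged_left_to_right(self):
        ns = assign_positions(self.build(n_pos=6, per_pos=4, n_syn=12), min_variants=10)
        nonsyn = (ns.annotations["mutation_type"] == "missense").to_numpy()
        labels = ns.position_label[nonsyn]
        # 4 variants/position: blocks {1,2,3} and {4,5,6} -> labels 1 and 4
        assert set(labels) == {1, 4}
        sizes = pd.Series(labels).value_counts()
        assert (sizes >= 10).all()

    def test_indel_labeled_at_leftmost_residue(self):
        ns = self.build(n_pos=2, per_pos=15, n_syn=15)
        ns.annotations.loc[0, "mutation_type"] = "deletion"
        ns.annotations.loc[0, "position"] = 1  # deletion of 1..10 annotated at 1
        out = assign_positions(ns)
        assert out.position_label[0] == 1


class TestMeanGroups:
    def make(self, V):
        counts = np.arange(V, dtype=float)[:, None, None] * np.ones((V, 2, 1)) + 1
        sc = make_screen(counts)
        return normalize(sc, method="total"), sc

    def test_even_split(self):
        ns, sc = self.make(50)
        out = assign_mean_groups(ns, sc, group_size=25)
        sizes = np.bincount(out.mean_group)
        assert list(sizes) == [25, 25]

    def test_small_remainder_merged_into_predecessor(self):
        ns, sc = self.make(60)
        out = assign_mean_groups(ns, sc, group_size=25)
        sizes = np.bincount(out.mean_group)
        assert sorted(sizes) == [25, 35]

    def test_groups_ordered_by_mean_count(self):
        ns, sc = self.make(50)
        out = assign_mean_groups(ns, sc, group_size=25)
        mean = sc.counts.mean(axis=(1, 2))
        assert mean[out.mean_group == 0].max() <= mean[out.mean_group == 1].min()


class TestPipeline:
    def test_full_pipeline_output_clean(self, sim_default):
        ns = preprocess_screen(sim_default.screen)
        assert np.isfinite(ns.m).all()
        np.testing.assert_allclose(ns.m[:, 0, :], 0.0)
        assert ns.position_label is not None and ns.mean_group is not None
        sizes = pd.Series(ns.position_label).value_counts()
        assert (sizes >= 10).all()

    def test_filter_impute_idempotent_on_complete_data(self, sim_default):
        once = impute_counts(filter_variants(sim_default.screen), "knn")
        twice = impute_counts(filter_variants(once), "knn")
        np.testing.assert_array_equal(once.counts, twice.counts)
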