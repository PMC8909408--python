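"""Generic filters and correlation/RT clustering."""

import numpy as np
import pytest

from peakrate.errors import ValidationError
from peakrate.model import Attribution, SampleInfo, SampleRole
from peakrate.prefilter import (
    FilterConfig,
    apply_clusters,
    blank_filter,
    cluster_features,
    normalize_internal_standard,
    rsd_filter,
)

from conftest import build_table


def _bio(n):
    return [SampleInfo(f"S{i}", SampleRole.BIOLOGICAL, f"c{i}") for i in range(1, n + 1)]


class TestNormalizeInternalStandard:
    def test_hand_arithmetic(self):
        table = build_table(
            [
                ("f", 200.0, 1.0, {"S1": 100.0, "S2": 200.0}),
                ("IS", 309.1, 5.0, {"S1": 10.0, "S2": 20.0}),
            ]
        )
        out = normalize_internal_standard(table, "IS")
        # IS median over biological samples is 15 -> f becomes 150 in both
        assert out.feature("f").heights == {"S1": 150.0, "S2": 150.0}

    def test_constant_is_only_removes_is_row(self):
        table = build_table(
            [
                ("f", 200.0, 1.0, {"S1": 100.0, "S2": 200.0}),
                ("IS", 309.1, 5.0, {"S1": 10.0, "S2": 10.0}),
            ]
        )
        out = normalize_internal_standard(table, "IS")
        assert out.feature("f").heights == {"S1": 100.0, "S2": 200.0}
        assert len(out) == 1

    def test_missing_is_errors(self):
        table = build_table([("f", 200.0, 1.0, {"S1": 100.0})])
        with pytest.raises(ValidationError):
            normalize_internal_standard(table, "IS")

    def test_is_without_signal_lists_samples(self):
        table = build_table(
            [
                ("f", 200.0, 1.0, {"S1": 1.0, "S2": 1.0}),
                ("IS", 309.1, 5.0, {"S1": 10.0, "S2": 0.0}),
            ]
        )
        with pytest.raises(ValidationError, match="S2"):
            normalize_internal_standard(table, "IS")


class TestBlankFilter:
    def _table(self, bio_heights, blank_height):
        samples = [
            SampleInfo("S1", SampleRole.BIOLOGICAL, "a"),
            SampleInfo("S2", SampleRole.BIOLOGICAL, "a"),
            SampleInfo("B", SampleRole.BLANK, "blank"),
        ]
        heights = {"S1": bio_heights[0], "S2": bio_heights[1], "B": blank_height}
        return build_table([("f", 100.0, 1.0, heights)], samples=samples)

    def test_blank_dominated_feature_removed(self):
        out = blank_filter(self._table([500.0, 300.0], 1000.0), FilterConfig(min_blank_ratio=0.8))
        assert out.feature("f").attribution == Attribution.INTERFERENCE

    def test_feature_absent_from_blank_retained(self):
        out = blank_filter(self._table([5.0, 3.0], 0.0), FilterConfig(min_blank_ratio=100.0))
        assert out.feature("f").attribution == Attribution.UNRATED

    def test_ratio_zero_disables_filter(self):
        out = blank_filter(self._table([0.0, 0.0], 1e6), FilterConfig(min_blank_ratio=0.0))
        assert out.feature("f").attribution == Attribution.UNRATED

    def test_no_blanks_is_noop_with_log(self):
        table = build_table([("f", 100.0, 1.0, {"S1": 1.0})])
        out = blank_filter(table, FilterConfig())
        assert out.feature("f").attribution == Attribution.UNRATED
        assert any("skipped" in line for line in out.provenance)

    def test_removal_is_attribution_not_deletion(self):
        out = blank_filter(self._table([1.0, 1.0], 1e6), FilterConfig())
        assert len(out) == 1  # conservation: row kept, attributed interference


class TestRsdFilter:
    def _samples(self):
        return [
            SampleInfo("A_1", SampleRole.BIOLOGICAL, "A"),
            SampleInfo("A_2", SampleRole.BIOLOGICAL, "A"),
            SampleInfo("A_3", SampleRole.BIOLOGICAL, "A"),
            SampleInfo("B_1", SampleRole.BIOLOGICAL, "B"),
            SampleInfo("B_2", SampleRole.BIOLOGICAL, "B"),
        ]

    def test_identical_heights_always_retained(self):
        table = build_table(
            [("f", 100.0, 1.0, {"A_1": 7.0, "A_2": 7.0, "A_3": 7.0, "B_1": 7.0, "B_2": 7.0})],
            samples=self._samples(),
        )
        out = rsd_filter(table, FilterConfig(max_class_rsd=1e-9))
        assert out.feature("f").attribution == Attribution.UNRATED

    def test_best_class_rsd_decides(self):
        # class A is perfectly stable, class B wildly unstable -> retained
        table = build_table(
            [("f", 100.0, 1.0, {"A_1": 10.0, "A_2": 10.0, "A_3": 10.0, "B_1": 1.0, "B_2": 100.0})],
            samples=self._samples(),
        )
        out = rsd_filter(table, FilterConfig(max_class_rsd=0.3))
        assert out.feature("f").attribution == Attribution.UNRATED

    def test_unstable_in_every_class_removed(self):
        table = build_table(
            [("f", 100.0, 1.0, {"A_1": 1.0, "A_2": 100.0, "A_3": 1.0, "B_1": 1.0, "B_2": 100.0})],
            samples=self._samples(),
        )
        out = rsd_filter(table, FilterConfig(max_class_rsd=0.3))
        assert out.feature("f").attribution == Attribution.INTERFERENCE

    def test_all_singleton_classes_is_noop(self):
        samples = [SampleInfo(f"S{i}", SampleRole.BIOLOGICAL, f"c{i}") for i in range(3)]
        table = build_table(
            [("f", 100.0, 1.0, {"S0": 1.0, "S1": 100.0, "S2": 1.0})], samples=samples
        )
        out = rsd_filter(table, FilterConfig(max_class_rsd=0.01))
        assert out.feature("f").attribution == Attribution.UNRATED


class TestClusterFeatures:
    def _samples(self):
        return [SampleInfo(f"S{i}", SampleRole.BIOLOGICAL, "c") for i in range(1, 5)]

    def test_correlated_coeluting_pair_clusters(self):
        h = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "S4": 4.0}
        table = build_table(
            [("a", 100.0, 2.00, h), ("b", 120.0, 2.01, {k: 2 * v for k, v in h.items()})],
            samples=self._samples(),
        )
        clusters = cluster_features(table, FilterConfig())
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_rt_gap_splits_despite_perfect_correlation(self):
        h = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "S4": 4.0}
        table = build_table(
            [("a", 100.0, 2.0, h), ("b", 120.0, 2.5, h)], samples=self._samples()
        )
        clusters = cluster_features(table, FilterConfig(cluster_rt_tol=0.03))
        assert len(clusters) == 2

    def test_transitive_closure_merges_chain(self):
        # deviation vectors at 30/30/60 degrees: r(a,b)=r(b,c)=0.866, r(a,c)=0.5
        a = {"S1": 5.707, "S2": 4.293, "S3": 5.0, "S4": 5.0}
        b = {"S1": 5.612, "S2": 4.388, "S3": 5.354, "S4": 4.646}
        c = {"S1": 5.354, "S2": 4.646, "S3": 5.612, "S4": 4.388}
        table = build_table(
            [("a", 100.0, 2.0, a), ("b", 120.0, 2.0, b), ("c", 140.0, 2.0, c)],
            samples=self._samples(),
        )
        cfg = FilterConfig(min_pearson=0.8)
        rab = np.corrcoef(list(a.values()), list(b.values()))[0, 1]
        rbc = np.corrcoef(list(b.values()), list(c.values()))[0, 1]
        rac = np.corrcoef(list(a.values()), list(c.values()))[0, 1]
        assert rab >= 0.8 and rbc >= 0.8 and rac < 0.8  # fixture sanity
        clusters = cluster_features(table, cfg)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_constant_feature_becomes_singleton(self):
        h = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "S4": 4.0}
        table = build_table(
            [("a", 100.0, 2.0, h), ("flat", 120.0, 2.0, {k: 5.0 for k in h})],
            samples=self._samples(),
        )
        clusters = cluster_features(table, FilterConfig())
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_fewer_than_three_biological_samples_errors(self):
        table = build_table(
            [("a", 100.0, 2.0, {"S1": 1.0, "S2": 2.0})],
            samples=[SampleInfo("S1"), SampleInfo("S2")],
        )
        with pytest.raises(ValidationError):
            cluster_features(table, FilterConfig())

    def test_partition_and_permutation_invariance(self, sim_exact):
        table, _ = sim_exact
        cfg = FilterConfig()
        clusters = cluster_features(table, cfg)
        members = [fid for c in clusters for fid in c.member_ids]
        active = [
            f.feature_id for f in table if f.attribution != Attribution.INTERFERENCE
        ]
        assert sorted(members) == sorted(active)  # exact partition

        shuffled = table.copy()
        shuffled.features = list(reversed(shuffled.features))
        clusters2 = cluster_features(shuffled, cfg)
        as_sets = lambda cs: {(c.cluster_id, frozenset(c.member_ids)) for c in cs}  # noqa: E731
        assert as_sets(clusters) == as_sets(clusters2)

    def test_monotone_coarsening(self, sim_exact):
        # lowering min_pearson / raising rt tol never splits clusters
        table, _ = sim_exact
        fine = cluster_features(table, FilterConfig(min_pearson=0.9, cluster_rt_tol=0.02))
        coarse = cluster_features(table, FilterConfig(min_pearson=0.7, cluster_rt_tol=0.05))
        coarse_of = {
            fid: c.cluster_id for c in coarse for fid in c.member_ids
        }
        for c in fine:
            assert len({coarse_of[fid] for fid in c.member_ids}) == 1

    def test_apply_clusters_writes_back(self):
        h = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "S4": 4.0}
        table = build_table([("a", 100.0, 2.0, h)], samples=self._samples())
        apply_clusters(table, cluster_features(table, FilterConfig()))
        assert table.feature("a").cluster_id is not None
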