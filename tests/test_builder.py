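"""Backbone construction, chimera handling, AGP finalization, statistics."""

import numpy as np
import pytest
from scipy import stats as sstats

from pmforge.builder import (
    build_backbone,
    detect_chimeras,
    finalize_agp,
    hierarchical_insert,
    n50,
    oriented_percentage,
    assembly_stats,
    split_scaffold,
    theil_sen_slope,
    validate_with_clone_assemblies,
    UNANCHORED_OBJECT,
)
from pmforge.pipeline import map_segments_to_truth
from pmforge.records import AGPRecord, AnchorPoint


def _anchor(sid, bp, lg, cm, marker=None, weight=1.0):
    return AnchorPoint(marker or f"m_{sid}_{bp}", sid, bp, lg, cm, weight=weight)


class TestBackbone:
    def test_scaffolds_sorted_by_median_cM(self):
        anchors = []
        for sid, cms in [("A", [4, 5, 6]), ("B", [9, 10, 11]), ("C", [20])]:
            anchors += [_anchor(sid, i * 1000, "chr01", c) for i, c in enumerate(cms)]
        result = build_backbone(anchors)
        ordered = [s for b in result.bins["chr01"] for s in b.scaffolds]
        assert ordered == ["A", "B", "C"]

    def test_co_positional_scaffolds_share_flagged_bin(self):
        anchors = [_anchor("A", 0, "chr01", 10.0), _anchor("B", 0, "chr01", 10.0)]
        result = build_backbone(anchors)
        (only_bin,) = result.bins["chr01"]
        assert sorted(only_bin.scaffolds) == ["A", "B"]
        assert not only_bin.ordered

    def test_split_anchors_route_to_chimera_screen(self):
        anchors = [
            _anchor("X", 0, "chr01", 5.0),
            _anchor("X", 1000, "chr02", 40.0),
            _anchor("X", 2000, "chr01", 6.0),
            _anchor("X", 3000, "chr02", 41.0),
        ]
        result = build_backbone(anchors)  # 1/2 is below the 2/3 supermajority
        assert result.ambiguous == ["X"]
        assert "X" not in result.positions

    def test_exact_supermajority_is_placed(self):
        anchors = [
            _anchor("X", 0, "chr01", 5.0),
            _anchor("X", 1000, "chr02", 40.0),
            _anchor("X", 2000, "chr01", 6.0),
        ]
        result = build_backbone(anchors)  # exactly 2/3 meets the requirement
        assert result.positions["X"][0] == "chr01"

    def test_simulated_backbone_order_matches_truth(
        self, default_bundle, default_assembly
    ):
        seg_to_part = map_segments_to_truth(default_assembly, default_bundle.truth)
        truth_rank = {}
        for chrom, keys in default_bundle.truth.order.items():
            for rank, key in enumerate(keys):
                truth_rank[key] = (chrom, rank)
        for chrom, bins in default_assembly.backbone.bins.items():
            built = []
            true = []
            for i, b in enumerate(bins):
                for sid in b.scaffolds:
                    key = seg_to_part.get(sid)
                    if key and truth_rank.get(key, (None,))[0] == chrom:
                        built.append(i)
                        true.append(truth_rank[key][1])
            rho = sstats.spearmanr(built, true).statistic
            assert rho >= 0.95, chrom


class TestHierarchicalInsert:
    def _backbone(self):
        anchors = [
            _anchor("A", 0, "chr01", 10.0),
            _anchor("B", 0, "chr01", 15.0),
            _anchor("C", 0, "chr01", 30.0),
        ]
        return build_backbone(anchors)

    def test_foreign_scaffold_inserted_in_agreeing_interval(self):
        ordering, report = hierarchical_insert(
            self._backbone(), rh_positions={"N": ("chr01", 12.0)}
        )
        assert [s for s, _ in ordering["chr01"]] == ["A", "N", "B", "C"]
        # support tally covers backbone scaffolds too: A, B, C and N
        assert report["inserted"] == 1 and report["support_1"] == 4

    def test_disagreeing_foreign_maps_leave_scaffold_unplaced(self):
        ordering, report = hierarchical_insert(
            self._backbone(),
            rh_positions={"N": ("chr01", 12.0)},
            tom_positions={"N": ("chr01", 28.0)},
        )
        assert "N" not in [s for s, _ in ordering["chr01"]]
        assert len(report["conflicts"]) == 1

    def test_agreeing_foreign_maps_count_double_support(self):
        ordering, report = hierarchical_insert(
            self._backbone(),
            rh_positions={"N": ("chr01", 12.0)},
            tom_positions={"N": ("chr01", 13.5)},
        )
        assert "N" in [s for s, _ in ordering["chr01"]]
        assert report["support_2"] >= 1

    def test_dropout_recovery_via_foreign_map(self, default_bundle):
        """Scaffolds dropped from the backbone return through the RH map."""
        from pmforge.simulate import true_backbone_positions

        truth_pos = true_backbone_positions(default_bundle.truth)
        rng = np.random.default_rng(31)
        keys = sorted(truth_pos)
        dropped = set(
            rng.choice(keys, size=int(0.3 * len(keys)), replace=False).tolist()
        )
        anchors = [
            _anchor(k, 100, chrom, cm)
            for k, (chrom, cm) in truth_pos.items()
            if k not in dropped
        ]
        backbone = build_backbone(anchors)
        ordering, report = hierarchical_insert(
            backbone, rh_positions={k: truth_pos[k] for k in dropped}
        )
        placed = {s for entries in ordering.values() for s, _ in entries}
        recovered = len(dropped & placed)
        assert recovered / len(dropped) >= 0.90


class TestChimeraDetection:
    def test_two_chromosome_scaffold_breaks_at_midpoint(self):
        anchors = {
            "S": [
                _anchor("S", 200_000, "chr04", 1.0),
                _anchor("S", 500_000, "chr04", 2.0),
                _anchor("S", 900_000, "chr04", 3.0),
                _anchor("S", 1_300_000, "chr05", 50.0),
                _anchor("S", 3_000_000, "chr05", 55.0),
                _anchor("S", 6_000_000, "chr05", 60.0),
            ]
        }
        (bp,) = detect_chimeras(anchors)
        assert bp.breakpoint_bp == 1_100_000
        assert bp.left_assignment[0] == "chr04"
        assert bp.right_assignment[0] == "chr05"
        assert (bp.support_left, bp.support_right) == (3, 3)

    def test_monotone_single_chromosome_scaffold_clean(self):
        anchors = {
            "S": [_anchor("S", i * 100_000, "chr01", i * 0.5) for i in range(10)]
        }
        assert detect_chimeras(anchors) == []

    def test_low_support_run_not_called(self):
        anchors = {
            "S": [
                _anchor("S", 100_000, "chr04", 1.0),
                _anchor("S", 200_000, "chr04", 1.5),
                _anchor("S", 900_000, "chr05", 50.0),
                _anchor("S", 950_000, "chr05", 51.0),
                _anchor("S", 990_000, "chr05", 52.0),
            ]
        }
        assert detect_chimeras(anchors) == []  # chr04 run has support 2 < 3

    def test_large_cM_jump_on_one_chromosome_is_a_breakpoint(self):
        anchors = {
            "S": [
                _anchor("S", 0, "chr01", 1.0),
                _anchor("S", 100_000, "chr01", 2.0),
                _anchor("S", 200_000, "chr01", 3.0),
                _anchor("S", 800_000, "chr01", 60.0),
                _anchor("S", 900_000, "chr01", 61.0),
                _anchor("S", 1_000_000, "chr01", 62.0),
            ]
        }
        (bp,) = detect_chimeras(anchors)
        assert bp.breakpoint_bp == 500_000


class TestSplit:
    def test_published_style_split_lengths(self):
        segs = split_scaffold("DMB2", 6_562_806, [1_117_982])
        assert [s.length for s in segs] == [1_117_982, 5_444_824]
        assert [s.id for s in segs] == ["DMB2_p1", "DMB2_p2"]
        assert segs[0].beg == 0 and segs[-1].end == 6_562_806

    def test_no_breakpoints_keeps_parent(self):
        (seg,) = split_scaffold("S", 1000, [])
        assert seg.id == "S" and seg.length == 1000

    def test_two_breakpoints_conserve_length(self):
        segs = split_scaffold("S", 10_000, [2_500, 7_000])
        assert len(segs) == 3
        assert sum(s.length for s in segs) == 10_000

    @pytest.mark.parametrize("bad", [[0], [10_000], [5_000, 5_000]])
    def test_invalid_breakpoints_rejected(self, bad):
        with pytest.raises(ValueError):
            split_scaffold("S", 10_000, bad)


class TestFinalizeAGP:
    def test_fixed_gaps_force_object_length(self):
        lengths = {"a": 1_000_000, "b": 2_000_000, "c": 3_000_000}
        records, pms = finalize_agp(
            {"chr01": ["a", "b", "c"]}, {"a": "+", "b": "-", "c": "+"}, lengths
        )
        (pm,) = pms
        assert pm.total_length == 6_100_000  # 6 Mb + 2 gaps of 50 kb
        assert [r.component_type for r in pm.records] == ["W", "U", "W", "U", "W"]

    def test_orientation_by_positive_slope(self):
        anchors = [_anchor("s", 100_000, "chr01", 5.0), _anchor("s", 900_000, "chr01", 9.0)]
        assert theil_sen_slope(anchors) > 0

    def test_flat_slope_stays_unoriented(self):
        from pmforge.builder import orient_segments

        anchors = {"s": [_anchor("s", 100_000, "chr01", 5.0),
                         _anchor("s", 900_000, "chr01", 5.01)]}
        orientation, source, _ = orient_segments(["s"], [], anchors)
        assert orientation["s"] == "?"  # below the 0.1 cM/Mb floor
        assert source["s"] == "none"

    def test_duplicate_segment_rejected(self):
        with pytest.raises(ValueError, match="more than once"):
            finalize_agp(
                {"chr01": ["a"], "chr02": ["a"]}, {"a": "+"}, {"a": 1000}
            )

    def test_unplaced_collected_in_unanchored_bin(self):
        records, _pms = finalize_agp(
            {"chr01": ["a"]}, {"a": "+"}, {"a": 1000, "z": 500}, unplaced=["z"]
        )
        unanchored = [r for r in records if r.object_id == UNANCHORED_OBJECT]
        assert len(unanchored) == 1
        assert unanchored[0].orientation == "?"


class TestStats:
    def test_n50_matches_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            lengths = rng.integers(1, 10_000, size=rng.integers(1, 40)).tolist()
            # brute force: descending cumulative sum to half the total
            ordered = sorted(lengths, reverse=True)
            acc, expected = 0, ordered[-1]
            for x in ordered:
                acc += x
                if acc >= sum(lengths) / 2:
                    expected = x
                    break
            assert n50(lengths) == expected

    @pytest.mark.parametrize(
        "oriented,anchored,expected",
        [(40.4, 49.5, 81.6), (79.8, 82.6, 96.6), (62.1, 66.3, 93.7), (0.0, 10.0, 0.0)],
    )
    def test_size_based_oriented_percentage(self, oriented, anchored, expected):
        assert oriented_percentage(oriented, anchored) == expected

    def test_stats_total_row_averages_percentages(self):
        def w(obj, beg, ln, part, comp, orientation):
            return AGPRecord(obj, beg, beg + ln - 1, part, "W", component_id=comp,
                             component_beg=1, component_end=ln, orientation=orientation)

        records = [
            w("chr01", 1, 1_000_000, 1, "a", "+"),
            w("chr02", 1, 1_000_000, 1, "b", "+"),
            AGPRecord("chr02", 1_000_001, 1_050_000, 2, "U", gap_length=50_000,
                      gap_type="contig", linkage="no"),
            w("chr02", 1_050_001, 1_000_000, 3, "c", "?"),
        ]
        records[3] = w("chr02", 1_050_001, 1_000_000, 3, "c", "?")
        df = assembly_stats(records)
        chr02 = df[df["chromosome"] == "chr02"].iloc[0]
        assert chr02["oriented_pct"] == 50.0
        total = df[df["chromosome"] == "Total"].iloc[0]
        assert total["oriented_pct"] == 75.0  # mean of 100.0 and 50.0


class TestCloneValidation:
    AGP = [
        AGPRecord("chr01", 1, 100, 1, "W", component_id="segA", component_beg=1,
                  component_end=100, orientation="+"),
        AGPRecord("chr01", 101, 150, 2, "U", gap_length=50, gap_type="contig",
                  linkage="no"),
        AGPRecord("chr01", 151, 250, 3, "W", component_id="segB", component_beg=1,
                  component_end=100, orientation="+"),
        AGPRecord("chr01", 251, 300, 4, "U", gap_length=50, gap_type="contig",
                  linkage="no"),
        AGPRecord("chr01", 301, 400, 5, "W", component_id="segC", component_beg=1,
                  component_end=100, orientation="+"),
    ]

    def test_spanning_clone_validates_join(self):
        matches = [("clone1", "ctg1", "segA"), ("clone1", "ctg1", "segB")]
        report = validate_with_clone_assemblies(matches, self.AGP)
        assert [v[:2] for v in report["validated"]] == [("segA", "segB")]
        assert report["contradicted"] == []

    def test_single_segment_clone_leaves_join_untested(self):
        matches = [("clone1", "ctg1", "segA")]
        report = validate_with_clone_assemblies(matches, self.AGP)
        assert report["validated"] == []
        assert ("segA", "segB") in report["untested"]

    def test_non_adjacent_bridge_is_contradiction(self):
        matches = [("clone1", "ctg1", "segA"), ("clone1", "ctg2", "segC")]
        report = validate_with_clone_assemblies(matches, self.AGP)
        assert ("segA", "segC", "clone1") in report["contradicted"]
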