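"""Feature extraction: unit rules, hand-computed values, and the text-scan
oracle over a full simulated SAM."""

import numpy as np
import pandas as pd
import pytest

from _oracle import sam_text_features
from svgt.features import (
    FEATURE_COLUMNS,
    count_alignment_features,
    count_direction_features,
    count_insert_size_features,
    extract_feature_matrix,
    extract_features,
    read_depth,
    sum_mapping_qualities,
    weighted_read_depth,
)
from svgt.io import (
    AlignmentRecord,
    InsertStats,
    MutatedRegion,
    ReadCollection,
    ReadPair,
    SVCall,
    load_alignments,
)


def _pair(ins, cigars=("100M", "100M"), pos=(1000, 1400), flags=(99, 147), mapq=60):
    a = AlignmentRecord("q", flags[0], pos[0], mapq, cigars[0], ins)
    b = AlignmentRecord("q", flags[1], pos[1], mapq, cigars[1], -ins)
    return ReadPair("q", a, b)


REGION = MutatedRegion("c", 1, 10_000, "core")
STATS = InsertStats(mu=500.0, sigma=15.0)


class TestInsertFeatures:
    def test_boundary_at_three_sigma_is_normal(self):
        pairs = [_pair(500), _pair(545), _pair(546)]
        normal, abnormal = count_insert_size_features(pairs, STATS)
        assert (normal, abnormal) == (2, 1)

    def test_empty_region(self):
        assert count_insert_size_features([], STATS) == (0, 0)

    def test_pair_with_unmapped_mate_counts_in_neither(self):
        p = _pair(0, flags=(73, 133))
        p.second.flag |= 0x4
        assert count_insert_size_features([p], STATS) == (0, 0)


class TestAlignmentFeatures:
    def test_full_pair_counts_fully_mapped(self):
        pairs = [(_pair(500), True, True)]
        assert count_alignment_features(pairs, [], REGION, 100) == (1, 0, 0, 0, 0)

    def test_mixed_pair_single_plus_incomplete(self):
        pairs = [(_pair(500, cigars=("100M", "60M40S")), True, True)]
        fully, single, incomplete, split, unmapped = count_alignment_features(
            pairs, [], REGION, 100
        )
        assert (fully, single, incomplete) == (0, 1, 1)

    def test_split_pair_one_mate_outside(self):
        pairs = [(_pair(500), True, False)]
        *_, split, _ = count_alignment_features(pairs, [], REGION, 100)
        assert split == 1

    def test_unmapped_record_counted_by_anchor(self):
        p = _pair(0, cigars=("100M", None))
        p.second.flag |= 0x4
        counts = count_alignment_features([(p, True, True)], [], REGION, 100)
        assert counts[4] == 1  # unmapped
        assert counts[1] == 1  # the mapped full mate becomes single_mapped

    def test_empty_inputs_all_zero(self):
        assert count_alignment_features([], [], REGION, 100) == (0, 0, 0, 0, 0)


class TestDirectionAndMapq:
    def test_exact_flag_equality(self):
        recs = [
            AlignmentRecord("a", 83, 10, 60, "100M", 500),
            AlignmentRecord("b", 83, 11, 60, "100M", 500),
            AlignmentRecord("c", 163, 12, 60, "100M", 500),
            AlignmentRecord("d", 99, 13, 60, "100M", 500),
        ]
        assert count_direction_features(recs) == (2, 1)

    def test_compound_flags_excluded(self):
        recs = [AlignmentRecord("a", 339, 10, 60, "100M", 500)]  # 83 | secondary
        assert count_direction_features(recs) == (0, 0)

    def test_mapq_sum(self):
        recs = [
            AlignmentRecord("a", 99, 10, 60, "100M", 500),
            AlignmentRecord("b", 99, 11, 30, "100M", 500),
            AlignmentRecord("c", 99, 12, 0, "100M", 500),
        ]
        assert sum_mapping_qualities(recs) == 90
        assert sum_mapping_qualities([]) == 0


class TestDepths:
    def test_read_depth_division(self):
        recs = [
            AlignmentRecord(f"r{i}", 99, 100 + i, 60, "100M", 500) for i in range(20)
        ]
        assert read_depth(recs, 2000) == pytest.approx(0.01)
        assert read_depth([], 2000) == 0.0

    def test_weighted_depth_hand_value(self):
        mapqs = [60, 30, 60, 15]
        recs = [
            AlignmentRecord(f"r{i}", 99, 100 + i, q, "100M", 500)
            for i, q in enumerate(mapqs)
        ]
        # sum of weights = (60+30+60+15)/60 = 2.75; / L=1000
        assert weighted_read_depth(recs, 1000, 60) == pytest.approx(0.00275)

    def test_all_max_quality_collapses_to_depth(self):
        recs = [
            AlignmentRecord(f"r{i}", 99, 100 + i, 60, "100M", 500) for i in range(8)
        ]
        assert weighted_read_depth(recs, 400, 60) == pytest.approx(
            read_depth(recs, 400)
        )

    def test_zero_qmax_defined_as_zero(self):
        recs = [AlignmentRecord("r", 99, 100, 0, "100M", 500)]
        assert weighted_read_depth(recs, 100, 0) == 0.0


class TestExtractFeatures:
    def test_empty_region_zeroes_with_length_preserved(self):
        coll = ReadCollection([])
        call = SVCall("c", "chr1", 5000, 6000, "DEL")
        fv = extract_features(call, coll, STATS, q_max=60, read_length=100,
                              reference_length=100_000)
        arr = fv.as_array()
        assert fv.variant_length == 1000
        assert np.all(arr[:12] == 0) and np.all(arr[13:] == 0)

    def test_point_call_uses_core_width_denominator(self):
        recs = [
            AlignmentRecord(f"r{i}", 99, 4950 + i, 60, "100M", 500) for i in range(10)
        ]
        coll = ReadCollection(recs)
        call = SVCall("c", "chr1", 5000, 5000, "INS")
        fv = extract_features(call, coll, STATS, q_max=60, read_length=100,
                              reference_length=100_000)
        assert fv.read_depth == pytest.approx(10 / 201)

    def test_deterministic_feature_table(self, small_sim):
        cfg = small_sim.config
        kwargs = dict(read_length=cfg.read_length,
                      reference_length=cfg.region_length)
        m1 = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                    cfg.insert_stats(), **kwargs)
        m2 = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                    cfg.insert_stats(), **kwargs)
        pd.testing.assert_frame_equal(m1, m2)

    def test_column_order_contract(self, small_sim):
        cfg = small_sim.config
        mat = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                     cfg.insert_stats(),
                                     read_length=cfg.read_length,
                                     reference_length=cfg.region_length)
        assert tuple(mat.columns) == FEATURE_COLUMNS


class TestOracle:
    def test_all_fifteen_features_match_text_scan(self, small_sim, small_sim_sam):
        """The streaming implementation equals a naive SAM text scan."""
        cfg = small_sim.config
        coll = load_alignments(small_sim_sam)
        mat = extract_feature_matrix(
            small_sim.calls, coll, cfg.insert_stats(),
            read_length=cfg.read_length, reference_length=cfg.region_length,
        )
        expected = sam_text_features(
            small_sim_sam, small_sim.calls, cfg.insert_mu, cfg.insert_sigma,
            cfg.read_length, cfg.region_length,
        )
        for call_id, row in mat.iterrows():
            for col in FEATURE_COLUMNS:
                assert row[col] == pytest.approx(expected[call_id][col]), (
                    call_id, col,
                )

    def test_in_memory_collection_matches_file_scan(self, small_sim, small_sim_sam):
        cfg = small_sim.config
        kwargs = dict(read_length=cfg.read_length,
                      reference_length=cfg.region_length)
        direct = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                        cfg.insert_stats(), **kwargs)
        loaded = extract_feature_matrix(small_sim.calls,
                                        load_alignments(small_sim_sam),
                                        cfg.insert_stats(), **kwargs)
        pd.testing.assert_frame_equal(direct, loaded)


class TestFeatureInvariants:
    def test_weighted_depth_bounded_by_depth(self, small_sim):
        cfg = small_sim.config
        mat = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                     cfg.insert_stats(),
                                     read_length=cfg.read_length,
                                     reference_length=cfg.region_length)
        assert (mat["weighted_read_depth"] <= mat["read_depth"] + 1e-12).all()

    def test_extended_depth_dominates_core(self, small_sim):
        cfg = small_sim.config
        mat = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                     cfg.insert_stats(),
                                     read_length=cfg.read_length,
                                     reference_length=cfg.region_length)
        assert (
            mat["extended_weighted_read_depth"]
            >= mat["weighted_read_depth"] - 1e-12
        ).all()

    def test_g3_regions_show_more_abnormal_reads_than_g2(self, small_sim):
        cfg = small_sim.config
        mat = extract_feature_matrix(small_sim.calls, small_sim.collection,
                                     cfg.insert_stats(),
                                     read_length=cfg.read_length,
                                     reference_length=cfg.region_length)
        labels = pd.Series(small_sim.labels).reindex(mat.index)
        g2 = mat.loc[labels == "G2", "abnormal_read"].mean()
        g3 = mat.loc[labels == "G3", "abnormal_read"].mean()
        assert g3 > g2
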