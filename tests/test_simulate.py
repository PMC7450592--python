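"""Simulator: planting, SNVs, read sampling, alignment emulation."""

import numpy as np
import pytest

from conftest import small_config
from svgt.io import CLASS_ORDER
from svgt.simulate import (
    Block,
    Haplotype,
    SimConfig,
    _Edit,
    _segment_blocks,
    elevated_windows,
    plant_snvs,
    plant_variants,
    random_reference,
    read_sequences,
    sample_read_pairs,
    simulate_dataset,
    write_fastq,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestPlantVariants:
    def test_null_planting_leaves_haplotypes_identical(self):
        cfg = small_config(class_counts=(5, 0, 0, 0, 0))
        ref = random_reference(cfg.region_length, _rng(1))
        genome, truth = plant_variants(ref, cfg, _rng(1))
        assert np.array_equal(genome.h1.sequence(ref), ref)
        assert np.array_equal(genome.h2.sequence(ref), ref)
        assert [v.genotype for v in truth.variants] == ["N"] * 5

    def test_default_config_class_histogram(self):
        cfg = SimConfig(seed=5)
        ref = random_reference(cfg.region_length, _rng(5))
        _, truth = plant_variants(ref, cfg, _rng(5))
        counts = {g: 0 for g in CLASS_ORDER}
        for v in truth.variants:
            counts[v.genotype] += 1
        assert tuple(counts[g] for g in CLASS_ORDER) == (60, 80, 80, 50, 30)

    def test_g3_deletion_amplified_to_copy_number(self):
        cfg = small_config(
            class_counts=(0, 0, 0, 1, 0), sv_types=("DEL",), copy_number=3
        )
        ref = random_reference(cfg.region_length, _rng(2))
        genome, truth = plant_variants(ref, cfg, _rng(2))
        (v,) = truth.variants
        L = v.call.length
        cnv_len = v.cnv_end - v.cnv_start + 1
        hap_v = genome.h1 if v.haplotype_of_variant == "H1" else genome.h2
        hap_w = genome.h2 if v.haplotype_of_variant == "H1" else genome.h1
        # the amplified haplotype replaces the CNV segment by 3 copies, each
        # shortened by the inner deletion; the wild haplotype is untouched
        assert hap_v.length == cfg.region_length - cnv_len + 3 * (cnv_len - L)
        assert hap_w.length == cfg.region_length

    def test_g4_amplification_sits_on_wild_haplotype(self):
        cfg = small_config(
            class_counts=(0, 0, 0, 0, 1), sv_types=("DEL",), copy_number=4
        )
        ref = random_reference(cfg.region_length, _rng(3))
        genome, truth = plant_variants(ref, cfg, _rng(3))
        (v,) = truth.variants
        assert v.cnv_haplotype != v.haplotype_of_variant
        cnv_len = v.cnv_end - v.cnv_start + 1
        hap_c = genome.h1 if v.cnv_haplotype == "H1" else genome.h2
        hap_v = genome.h2 if v.cnv_haplotype == "H1" else genome.h1
        assert hap_c.length == cfg.region_length + 3 * cnv_len
        assert hap_v.length == cfg.region_length - v.call.length  # the DEL

    def test_footprints_disjoint(self):
        cfg = small_config(seed=11)
        ref = random_reference(cfg.region_length, _rng(11))
        _, truth = plant_variants(ref, cfg, _rng(11))
        spans = []
        for v in truth.variants:
            lo, hi = v.call.pos, v.call.end
            if v.cnv_copy_number > 1:
                lo, hi = min(lo, v.cnv_start), max(hi, v.cnv_end)
            spans.append((lo, hi))
        spans.sort()
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b < c

    def test_infeasible_packing_raises(self):
        from svgt.simulate import PackingError

        cfg = small_config(region_length=10_000, class_counts=(0, 40, 0, 0, 0))
        ref = random_reference(10_000, _rng(0))
        with pytest.raises(PackingError, match="enlarge the region"):
            plant_variants(ref, cfg, _rng(0))


class TestPlantSnvs:
    def test_zero_rates_identity(self):
        cfg = small_config(elevated_snv_rate=0.0, background_snv_rate=0.0)
        ref = random_reference(cfg.region_length, _rng(4))
        genome, truth = plant_variants(ref, cfg, _rng(4))
        before = genome.h1.sequence(ref).copy()
        plant_snvs(genome, truth, cfg, _rng(4))
        assert np.array_equal(genome.h1.sequence(ref), before)

    def test_certain_substitution_changes_every_base(self):
        cfg = small_config(
            class_counts=(3, 0, 0, 0, 0), background_snv_rate=1.0,
            elevated_snv_rate=0.0,
        )
        ref = random_reference(cfg.region_length, _rng(5))
        genome, truth = plant_variants(ref, cfg, _rng(5))
        plant_snvs(genome, truth, cfg, _rng(5))
        assert not np.any(genome.h1.sequence(ref) == ref)

    def test_background_count_binomial(self):
        cfg = SimConfig(class_counts=(0, 0, 0, 0, 0), seed=6)
        ref = random_reference(cfg.region_length, _rng(6))
        genome, truth = plant_variants(ref, cfg, _rng(6))
        plant_snvs(genome, truth, cfg, _rng(6))
        # 1 Mbps at 1e-4: mean 100, allow 3 binomial sd
        for hap in genome.haplotypes:
            assert abs(hap.snv_ref_pos.shape[0] - 100) <= 3 * np.sqrt(100)

    def test_elevated_windows_pad_to_1000_extra(self):
        cfg = small_config(class_counts=(0, 0, 1, 0, 0))
        ref = random_reference(cfg.region_length, _rng(7))
        genome, truth = plant_variants(ref, cfg, _rng(7))
        (v,) = truth.variants
        ((s, e),) = elevated_windows(truth, cfg, cfg.region_length)
        assert (e - s) - v.call.length == pytest.approx(1000, abs=1)


class TestSampleReads:
    def test_pair_count_matches_coverage(self):
        cfg = small_config(class_counts=(0, 0, 0, 0, 0), region_length=200_000,
                          coverage=10.0)
        ref = random_reference(cfg.region_length, _rng(8))
        genome, _ = plant_variants(ref, cfg, _rng(8))
        raw = sample_read_pairs(genome, cfg, _rng(8))
        expected = cfg.coverage * cfg.region_length / (2 * cfg.read_length)
        assert abs(len(raw) - expected) / expected < 0.05

    def test_zero_error_reads_match_haplotype(self):
        cfg = small_config(class_counts=(2, 0, 0, 0, 0), base_error_rate=0.0,
                          coverage=2.0)
        ref = random_reference(cfg.region_length, _rng(9))
        genome, truth = plant_variants(ref, cfg, _rng(9))
        raw = sample_read_pairs(genome, cfg, _rng(9))
        seqL, seqR = read_sequences(raw, genome, cfg, _rng(9))
        comp = np.array([3, 2, 1, 0], dtype=np.uint8)
        for i in range(0, len(raw), 200):
            src = genome.haplotypes[int(raw.hap_index[i])].sequence(ref)
            s, ins = int(raw.frag_start[i]), int(raw.insert[i])
            assert np.array_equal(seqL[i], src[s : s + 100])
            assert np.array_equal(seqR[i], comp[src[s + ins - 100 : s + ins][::-1]])

    def test_errors_perturb_some_bases(self):
        cfg = small_config(class_counts=(2, 0, 0, 0, 0), base_error_rate=0.01,
                          coverage=2.0)
        ref = random_reference(cfg.region_length, _rng(10))
        genome, _ = plant_variants(ref, cfg, _rng(10))
        raw = sample_read_pairs(genome, cfg, _rng(10))
        seqL, _ = read_sequences(raw, genome, cfg, _rng(10))
        src = genome.h1.sequence(ref)
        mismatches = sum(
            int((seqL[i] != src[int(raw.frag_start[i]) : int(raw.frag_start[i]) + 100]).sum())
            for i in range(min(200, len(raw)))
            if raw.hap_index[i] == 0
        )
        assert mismatches > 0


class TestEmulationRules:
    def _plain_hap(self, n=10_000):
        return Haplotype([Block(length=n, ref_start=0, strand=1)])

    def test_read_in_unaltered_block_full_match(self):
        hap = self._plain_hap()
        m = hap.map_reads(np.array([1234]), 100)
        assert m["pos"][0] == 1234 and m["matchlen"][0] == 100

    def test_read_half_inside_novel_insertion_soft_clipped(self):
        # 1 kb novel insertion at reference offset 5000
        blocks = _segment_blocks(
            0,
            10_000,
            [_Edit("ins", 5000, 5000,
                   ins_blocks=[Block(1000, -1, 0, seq=np.zeros(1000, np.uint8))])],
        )
        hap = Haplotype(blocks)
        m = hap.map_reads(np.array([4950]), 100)  # 50 bp anchor, 50 bp novel
        assert m["pos"][0] == 4950
        assert (m["matchlen"][0], m["lclip"][0], m["rclip"][0]) == (50, 0, 50)

    def test_read_fully_inside_novel_insertion_unmapped(self):
        blocks = _segment_blocks(
            0,
            10_000,
            [_Edit("ins", 5000, 5000,
                   ins_blocks=[Block(1000, -1, 0, seq=np.zeros(1000, np.uint8))])],
        )
        hap = Haplotype(blocks)
        m = hap.map_reads(np.array([5400]), 100)
        assert m["pos"][0] == -1 and m["strand"][0] == 0

    def test_anchor_below_threshold_unmapped(self):
        blocks = _segment_blocks(
            0,
            10_000,
            [_Edit("ins", 5000, 5000,
                   ins_blocks=[Block(1000, -1, 0, seq=np.zeros(1000, np.uint8))])],
        )
        hap = Haplotype(blocks)
        m = hap.map_reads(np.array([4990]), 100)  # 10 bp anchor < 20
        assert m["pos"][0] == -1

    def test_inverted_block_reflects_position(self):
        blocks = _segment_blocks(0, 10_000, [_Edit("inv", 4000, 6000)])
        hap = Haplotype(blocks)
        m = hap.map_reads(np.array([4500]), 100)
        # read at haplotype offset 4500 sits 500 into the inversion; it maps
        # reverse-complemented, mirrored within [4000, 6000)
        assert m["strand"][0] == -1
        assert m["pos"][0] == 6000 - 500 - 100

    def test_deletion_inflates_template_length(self):
        cfg = small_config()
        ref = random_reference(10_000, _rng(0))
        blocks = _segment_blocks(0, 10_000, [_Edit("del", 5000, 7000)])
        hap = Haplotype(blocks)
        # fragment [4700, 5200) on the haplotype straddles the junction at 5000
        mL = hap.map_reads(np.array([4700]), 100)
        mR = hap.map_reads(np.array([5100]), 100)
        tlen = (mR["pos"][0] + 100) - mL["pos"][0]
        assert tlen == 2500  # true insert 500 + deleted 2000


class TestEndToEnd:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = small_config(region_length=40_000, class_counts=(2, 2, 2, 1, 1),
                          coverage=4.0, seed=13)
        outs = []
        for run in ("a", "b"):
            sim = simulate_dataset(cfg)
            vcf = tmp_path / f"{run}.vcf"
            fq1 = tmp_path / f"{run}.r1.fastq"
            fq2 = tmp_path / f"{run}.r2.fastq"
            sim.truth.to_vcf(vcf, cfg.region_length, cfg.chrom)
            write_fastq(fq1, fq2, sim.raw, sim.genome, cfg, _rng(99))
            body = b"".join(
                line for line in vcf.read_bytes().splitlines(keepends=True)
                if not line.startswith(b"##fileDate")
            )
            outs.append((body, fq1.read_bytes(), fq2.read_bytes()))
        assert outs[0] == outs[1]

    def test_realized_depth_near_nominal(self):
        cfg = small_config(class_counts=(0, 0, 0, 0, 0), region_length=150_000,
                          coverage=10.0)
        sim = simulate_dataset(cfg)
        mapped = sum(1 for r in sim.collection.records if not r.is_unmapped)
        depth = mapped * cfg.read_length / cfg.region_length
        assert abs(depth - cfg.coverage) / cfg.coverage < 0.10

    def test_sam_roundtrip_preserves_records(self, small_sim, small_sim_sam):
        from svgt.io import load_alignments

        loaded = load_alignments(small_sim_sam)
        assert len(loaded) == len(small_sim.collection)
        want = sorted(
            (r.pos, r.flag, r.mapq, r.cigar or "", r.tlen)
            for r in small_sim.collection.records
        )
        got = sorted(
            (r.pos, r.flag, r.mapq, r.cigar or "", r.tlen)
            for r in loaded.records
        )
        assert want == got

    def test_proper_pair_flags_occur_in_both_orientations(self, small_sim):
        flags = {r.flag for r in small_sim.collection.records}
        assert {83, 163, 99, 147} <= flags
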