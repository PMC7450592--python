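"""Diploid genome and paired-end read simulation with emulated alignment.

The simulator plants structural variants (insertion, deletion, inversion,
complex indel) in five genotype classes on a diploid genome:

* ``N``  - no variant on either haplotype;
* ``G1`` - the variant on both haplotypes (homozygous);
* ``G2`` - the variant on one haplotype, no CNV (plain heterozygote);
* ``G3`` - heterozygote with a tandem amplification (to ``copy_number``
  copies) of the segment carrying the variant, on the variant haplotype;
* ``G4`` - heterozygote with the amplification on the wild haplotype.

Paired-end fragments are sampled uniformly along each haplotype (so amplified
segments are over-sampled in proportion to their copy number) and converted
into alignment records by deterministic rules driven by the planted truth:
reads inside unaltered blocks align full-length at MAPQ 60; reads crossing a
breakpoint with a >= ``ANCHOR_MIN`` bp anchor are soft-clipped at MAPQ 30;
reads fully inside novel inserted sequence are unmapped and placed at their
mate's position; reads inside inverted segments map to the reverse strand so
pair-orientation anomalies arise naturally.  Template length is the distance
between the mapped mate ends, so deletions inflate and insertions deflate the
observed insert size.

Base-call errors and planted SNVs affect only the emitted sequences
(FASTQ/SAM SEQ); the alignment records themselves are functions of the truth,
which keeps the feature signals exact and the simulation fast.  A FASTQ is
emitted so a real aligner can be substituted for the emulation when desired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io import (
    CLASS_ORDER,
    AlignmentRecord,
    InsertStats,
    ReadCollection,
    SVCall,
    build_vcf_header,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space

#: Minimum reference anchor (bp) for a breakpoint-crossing read to stay mapped.
ANCHOR_MIN = 20
MAPQ_FULL = 60
MAPQ_CLIPPED = 30


class PackingError(RuntimeError):
    """Planted footprints could not be packed into the region."""


# ---------------------------------------------------------------------------
# Configuration and truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters.

    Defaults reproduce the study conditions used throughout the evaluation
    protocol: a 1 Mbps region, 300 candidate calls split 60/80/80/50/30 over
    N/G1/G2/G3/G4, SV lengths 0.5-5 kbps, CNV lengths 1-5 kbps, 100 bp reads
    with insert sizes ~ Normal(500, 15), base error rate 0.005, SNV rate 0.01
    inside an elevated window 1000 bp longer than each variant and 1e-4
    elsewhere, and about one fourth of each complex-indel insertion copied
    from the adjacent sequence.  ``coverage`` is the total (diploid) fold
    coverage; each haplotype is sampled at half of it.
    """

    region_length: int = 1_000_000
    class_counts: tuple[int, int, int, int, int] = (60, 80, 80, 50, 30)
    sv_length_range: tuple[int, int] = (500, 5000)
    cnv_length_range: tuple[int, int] = (1000, 5000)
    copy_number: int = 3
    coverage: float = 10.0
    read_length: int = 100
    insert_mu: float = 500.0
    insert_sigma: float = 15.0
    base_error_rate: float = 0.005
    elevated_snv_rate: float = 0.01
    background_snv_rate: float = 1e-4
    elevated_extra: int = 1000  # elevated window is this much longer than the SV
    cpx_nearby_fraction: float = 0.25
    sv_types: tuple[str, ...] = ("INS", "DEL", "INV", "CPX")
    purity: float = 1.0
    min_gap: int = 200
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.base_error_rate,
            self.elevated_snv_rate,
            self.background_snv_rate,
            self.cpx_nearby_fraction,
            self.purity,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.copy_number < 2:
            raise ValueError("copy_number must be >= 2")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be >= 0")

    @property
    def n_calls(self) -> int:
        return int(sum(self.class_counts))

    def insert_stats(self) -> InsertStats:
        return InsertStats(mu=self.insert_mu, sigma=self.insert_sigma, source="user")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("class_counts", "sv_length_range", "cnv_length_range", "sv_types"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class PlantedVariant:
    call: SVCall
    genotype: str  # one of CLASS_ORDER
    haplotype_of_variant: str  # H1 | H2 | both | none
    cnv_haplotype: str  # H1 | H2 | none
    cnv_copy_number: int  # 1 when no CNV
    cnv_start: int = 0  # 1-based, 0 when no CNV
    cnv_end: int = 0


@dataclass
class TruthSet:
    variants: list[PlantedVariant]

    @property
    def labels(self) -> dict[str, str]:
        return {v.call.id: v.genotype for v in self.variants}

    @property
    def calls(self) -> list[SVCall]:
        return [v.call for v in self.variants]

    def to_vcf(self, path: str | Path, reference_length: int, chrom: str) -> None:
        header = build_vcf_header(
            chrom,
            reference_length,
            extra_info=[("GTCLASS", "1", "String", "Planted genotype class")],
        )
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for v in sorted(self.variants, key=lambda v: v.call.pos):
                c = v.call
                rec = vf.new_record(
                    contig=chrom,
                    start=c.pos - 1,
                    stop=c.end,
                    alleles=("N", f"<{c.sv_type}>"),
                    id=c.id,
                )
                rec.info["SVTYPE"] = c.sv_type
                rec.info["SVLEN"] = c.length
                rec.info["GTCLASS"] = v.genotype
                vf.write(rec)


# ---------------------------------------------------------------------------
# Haplotype block model
# ---------------------------------------------------------------------------


@dataclass
class Block:
    """A haplotype segment: a reference slice (strand +/-1) or novel sequence."""

    length: int
    ref_start: int  # 0-based reference start; -1 for novel sequence
    strand: int  # +1 forward, -1 inverted, 0 novel
    seq: np.ndarray | None = None  # codes, only for novel blocks


class Haplotype:
    """One haplotype as an ordered list of blocks over the reference."""

    def __init__(self, blocks: Sequence[Block]):
        self.blocks = [b for b in blocks if b.length > 0]
        lens = np.fromiter((b.length for b in self.blocks), dtype=np.int64)
        self.starts = np.concatenate(([0], np.cumsum(lens)))
        self.lens = lens
        self.ref_starts = np.fromiter(
            (b.ref_start for b in self.blocks), dtype=np.int64
        )
        self.strands = np.fromiter((b.strand for b in self.blocks), dtype=np.int64)
        self.length = int(self.starts[-1])
        # per-haplotype SNVs in reference coordinates (applied at materialization)
        self.snv_ref_pos = np.empty(0, dtype=np.int64)
        self.snv_alt = np.empty(0, dtype=np.uint8)

    # -- sequence materialization ------------------------------------------

    def sequence(self, reference: np.ndarray) -> np.ndarray:
        chunks: list[np.ndarray] = []
        order = np.argsort(self.snv_ref_pos, kind="stable")
        snv_pos = self.snv_ref_pos[order]
        snv_alt = self.snv_alt[order]
        for b in self.blocks:
            if b.strand == 0:
                chunks.append(b.seq)
                continue
            seg = reference[b.ref_start : b.ref_start + b.length].copy()
            lo = np.searchsorted(snv_pos, b.ref_start)
            hi = np.searchsorted(snv_pos, b.ref_start + b.length)
            if hi > lo:
                seg[snv_pos[lo:hi] - b.ref_start] = snv_alt[lo:hi]
            if b.strand < 0:
                seg = _COMP[seg[::-1]]
            chunks.append(seg)
        if not chunks:
            return np.empty(0, dtype=np.uint8)
        return np.concatenate(chunks)

    # -- read mapping -------------------------------------------------------

    def map_reads(self, starts: np.ndarray, read_length: int) -> dict[str, np.ndarray]:
        """Map reads [s, s+read_length) on this haplotype to the reference.

        Returns arrays: ``pos`` (0-based reference start of the matched part,
        -1 for unmapped), ``strand`` (block strand, 0 unmapped), ``matchlen``,
        ``lclip``, ``rclip``.
        """
        n = starts.shape[0]
        rl = read_length
        idx = np.searchsorted(self.starts, starts, side="right") - 1
        off = starts - self.starts[idx]
        single = off + rl <= self.lens[idx]

        pos = np.full(n, -1, dtype=np.int64)
        strand = np.zeros(n, dtype=np.int64)
        matchlen = np.zeros(n, dtype=np.int64)
        lclip = np.zeros(n, dtype=np.int64)
        rclip = np.zeros(n, dtype=np.int64)

        # single-block reads (vast majority), vectorized
        s_idx = idx[single]
        s_off = off[single]
        s_strand = self.strands[s_idx]
        s_pos = np.where(
            s_strand > 0,
            self.ref_starts[s_idx] + s_off,
            self.ref_starts[s_idx] + self.lens[s_idx] - s_off - rl,
        )
        mapped = s_strand != 0
        pos[single] = np.where(mapped, s_pos, -1)
        strand[single] = s_strand
        matchlen[single] = np.where(mapped, rl, 0)

        # breakpoint-crossing reads, per-read
        for i in np.flatnonzero(~single):
            b = int(idx[i])
            o = int(off[i])
            remaining = rl
            runs: list[tuple[int, int, int]] = []  # (block_idx, off_in_block, runlen)
            while remaining > 0 and b < len(self.blocks):
                take = min(remaining, int(self.lens[b]) - o)
                runs.append((b, o, take))
                remaining -= take
                b += 1
                o = 0
            best = -1
            best_len = 0
            consumed = 0
            best_off = 0
            for k, (bi, bo, ln) in enumerate(runs):
                if self.strands[bi] != 0 and ln > best_len:
                    best, best_len = k, ln
            if best >= 0 and best_len >= ANCHOR_MIN:
                bi, bo, ln = runs[best]
                left = sum(r[2] for r in runs[:best])
                right = rl - left - ln
                if self.strands[bi] > 0:
                    pos[i] = self.ref_starts[bi] + bo
                else:
                    pos[i] = self.ref_starts[bi] + self.lens[bi] - bo - ln
                strand[i] = self.strands[bi]
                matchlen[i] = ln
                # clips are reported in mapped (reference) orientation
                if self.strands[bi] > 0:
                    lclip[i], rclip[i] = left, right
                else:
                    lclip[i], rclip[i] = right, left
        return {
            "pos": pos,
            "strand": strand,
            "matchlen": matchlen,
            "lclip": lclip,
            "rclip": rclip,
        }


@dataclass
class DiploidGenome:
    reference: np.ndarray  # uint8 codes
    h1: Haplotype
    h2: Haplotype

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (self.h1, self.h2)


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------


def random_reference(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


def load_reference(path: str | Path, max_length: int | None = None) -> np.ndarray:
    """First contig of a FASTA, as base codes; non-ACGT bases become A."""
    with pysam.FastaFile(str(path)) as fa:
        seq = fa.fetch(fa.references[0]).upper()
    if max_length is not None:
        seq = seq[:max_length]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(arr.shape[0], dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes


def codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


@dataclass
class _Edit:
    kind: str  # del | ins | inv | cpx | dup
    ref_start: int  # 0-based half-open [ref_start, ref_end)
    ref_end: int
    ins_blocks: list[Block] = field(default_factory=list)
    n_copies: int = 1
    inner: "_Edit | None" = None


def _ins_content_blocks(
    ins_len: int,
    source_start: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[Block]:
    """Inserted fragment: a nearby-copied prefix plus novel random sequence."""
    copy_len = int(round(cfg.cpx_nearby_fraction * ins_len))
    copy_len = min(copy_len, max(0, cfg.region_length - source_start))
    blocks = []
    if copy_len > 0:
        blocks.append(Block(length=copy_len, ref_start=source_start, strand=1))
    novel_len = ins_len - copy_len
    if novel_len > 0:
        blocks.append(
            Block(
                length=novel_len,
                ref_start=-1,
                strand=0,
                seq=random_reference(novel_len, rng),
            )
        )
    return blocks


def _sv_edit(
    sv_type: str, pos0: int, length: int, cfg: SimConfig, rng: np.random.Generator
) -> _Edit:
    """The haplotype edit realizing one SV at 0-based position ``pos0``."""
    if sv_type == "DEL":
        return _Edit("del", pos0, pos0 + length)
    if sv_type == "INV":
        return _Edit("inv", pos0, pos0 + length)
    if sv_type == "INS":
        # fully novel insertion at the call position
        return _Edit(
            "ins",
            pos0,
            pos0,
            ins_blocks=[
                Block(length=length, ref_start=-1, strand=0,
                      seq=random_reference(length, rng))
            ],
        )
    if sv_type == "CPX":
        # complex indel: deletion plus an insertion at the same locus, part of
        # which is copied from the sequence just downstream of the deletion
        lo, hi = cfg.sv_length_range
        ins_len = int(rng.integers(lo, hi + 1))
        return _Edit(
            "cpx",
            pos0,
            pos0 + length,
            ins_blocks=_ins_content_blocks(ins_len, pos0 + length, cfg, rng),
        )
    raise ValueError(f"cannot plant SV type {sv_type!r}")


def _segment_blocks(ref_s: int, ref_e: int, edits: Sequence[_Edit]) -> list[Block]:
    """Blocks for reference segment [ref_s, ref_e) with the given inner edits."""
    blocks: list[Block] = []
    cursor = ref_s
    for e in sorted(edits, key=lambda e: e.ref_start):
        if e.ref_start > cursor:
            blocks.append(Block(length=e.ref_start - cursor, ref_start=cursor, strand=1))
        if e.kind == "del":
            cursor = e.ref_end
        elif e.kind == "inv":
            blocks.append(
                Block(length=e.ref_end - e.ref_start, ref_start=e.ref_start, strand=-1)
            )
            cursor = e.ref_end
        elif e.kind == "ins":
            blocks.extend(e.ins_blocks)
            cursor = e.ref_end
        elif e.kind == "cpx":
            blocks.extend(e.ins_blocks)
            cursor = e.ref_end
        elif e.kind == "dup":
            inner = [e.inner] if e.inner is not None else []
            for _ in range(e.n_copies):
                blocks.extend(_segment_blocks(e.ref_start, e.ref_end, inner))
            cursor = e.ref_end
        else:  # pragma: no cover - guarded upstream
            raise ValueError(e.kind)
    if ref_e > cursor:
        blocks.append(Block(length=ref_e - cursor, ref_start=cursor, strand=1))
    return blocks


def _allocate_gaps(
    extra: int, n_gaps: int, rng: np.random.Generator
) -> np.ndarray:
    """Split ``extra`` bp into ``n_gaps`` random non-negative integer gaps."""
    if extra <= 0:
        return np.zeros(n_gaps, dtype=np.int64)
    raw = rng.exponential(1.0, size=n_gaps)
    gaps = np.floor(raw / raw.sum() * extra).astype(np.int64)
    remainder = extra - int(gaps.sum())
    if remainder > 0:
        bump = rng.choice(n_gaps, size=remainder, replace=True)
        np.add.at(gaps, bump, 1)
    return gaps


def plant_variants(
    reference: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
) -> tuple[DiploidGenome, TruthSet]:
    """Plant the configured calls on a diploid genome.

    Call footprints (SV span united with any CNV span, plus ``cfg.min_gap``)
    are pairwise disjoint; placements are random over the feasible
    arrangements.  Elevated SNV windows may overlap neighbouring footprints
    (they modulate only SNV placement).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref_len = int(reference.shape[0])
    sv_lo, sv_hi = cfg.sv_length_range
    cnv_lo, cnv_hi = cfg.cnv_length_range

    genotypes = [
        g for g, count in zip(CLASS_ORDER, cfg.class_counts) for _ in range(count)
    ]
    rng.shuffle(genotypes)

    for _attempt in range(max_retries):
        specs = []
        for g in genotypes:
            L = int(rng.integers(sv_lo, sv_hi + 1))
            sv_type = (
                "NONE" if g == "N" else str(rng.choice(cfg.sv_types))
            )
            has_cnv = g in ("G3", "G4")
            if has_cnv:
                cnv_len = int(rng.integers(max(cnv_lo, L), max(cnv_hi, L) + 1))
                slack = cnv_len - L
                cnv_offset = int(rng.integers(0, slack + 1))  # CNV starts this far left of POS
                footprint = cnv_len
            else:
                cnv_len = 0
                cnv_offset = 0
                footprint = L
            specs.append((g, sv_type, L, cnv_len, cnv_offset, footprint))
        total = sum(s[5] for s in specs) + cfg.min_gap * (len(specs) + 1)
        if total <= ref_len:
            break
    else:
        raise PackingError(
            f"could not pack {len(genotypes)} calls into {ref_len} bp after "
            f"{max_retries} attempts; enlarge the region or plant fewer calls"
        )

    extra = ref_len - total
    gaps = _allocate_gaps(extra, len(specs) + 1, rng)

    edits: dict[str, list[_Edit]] = {"H1": [], "H2": []}
    variants: list[PlantedVariant] = []
    cursor = 0
    for i, ((g, sv_type, L, cnv_len, cnv_offset, footprint), gap) in enumerate(
        zip(specs, gaps[:-1])
    ):
        cursor += int(gap) + cfg.min_gap
        fp_start = cursor
        cursor += footprint
        pos0 = fp_start + cnv_offset  # 0-based SV position
        call = SVCall(
            id=f"call_{i + 1:04d}",
            chrom=cfg.chrom,
            pos=pos0 + 1,
            end=pos0 + 1 + L,
            sv_type=sv_type,
        )
        if g == "N":
            variants.append(
                PlantedVariant(call, g, "none", "none", 1)
            )
            continue
        sv = _sv_edit(sv_type, pos0, L, cfg, rng)
        hap_v = "H1" if rng.integers(0, 2) == 0 else "H2"
        hap_w = "H2" if hap_v == "H1" else "H1"
        if g == "G1":
            edits["H1"].append(sv)
            edits["H2"].append(replace(sv))
            variants.append(PlantedVariant(call, g, "both", "none", 1))
        elif g == "G2":
            edits[hap_v].append(sv)
            variants.append(PlantedVariant(call, g, hap_v, "none", 1))
        else:
            cnv_s = fp_start
            cnv_e = fp_start + cnv_len
            if g == "G3":
                edits[hap_v].append(
                    _Edit("dup", cnv_s, cnv_e, n_copies=cfg.copy_number, inner=sv)
                )
                cnv_hap = hap_v
            else:  # G4: variant on hap_v, amplification on the wild haplotype
                edits[hap_v].append(sv)
                edits[hap_w].append(
                    _Edit("dup", cnv_s, cnv_e, n_copies=cfg.copy_number)
                )
                cnv_hap = hap_w
            variants.append(
                PlantedVariant(
                    call, g, hap_v, cnv_hap, cfg.copy_number, cnv_s + 1, cnv_e
                )
            )

    h1 = Haplotype(_segment_blocks(0, ref_len, edits["H1"]))
    h2 = Haplotype(_segment_blocks(0, ref_len, edits["H2"]))
    return DiploidGenome(reference=reference, h1=h1, h2=h2), TruthSet(variants)


# ---------------------------------------------------------------------------
# SNV planting
# ---------------------------------------------------------------------------


def elevated_windows(truth: TruthSet, cfg: SimConfig, ref_len: int) -> list[tuple[int, int]]:
    """0-based half-open elevated windows: each variant padded so the window
    is ``cfg.elevated_extra`` bp longer than the variant itself."""
    pad = cfg.elevated_extra // 2
    wins = []
    for v in truth.variants:
        if v.genotype == "N":
            continue
        s = max(0, v.call.pos - 1 - pad)
        e = min(ref_len, v.call.end + pad)
        wins.append((s, e))
    return wins


def plant_snvs(
    genome: DiploidGenome,
    truth: TruthSet,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> DiploidGenome:
    """Substitute bases at the elevated rate inside variant windows and the
    background rate elsewhere, independently per haplotype.

    SNVs live in reference coordinates and are applied when haplotype
    sequences are materialized (reverse-complemented inside inversions).
    """
    ref_len = int(genome.reference.shape[0])
    wins = elevated_windows(truth, cfg, ref_len)
    in_window = np.zeros(ref_len, dtype=bool)
    for s, e in wins:
        in_window[s:e] = True
    window_pos = np.flatnonzero(in_window)
    bg_len = ref_len - window_pos.shape[0]

    for hap in genome.haplotypes:
        positions = []
        if window_pos.shape[0] and cfg.elevated_snv_rate > 0:
            k = rng.binomial(window_pos.shape[0], cfg.elevated_snv_rate)
            if k:
                positions.append(rng.choice(window_pos, size=k, replace=False))
        if bg_len and cfg.background_snv_rate > 0:
            k = rng.binomial(bg_len, cfg.background_snv_rate)
            if k:
                bg_pos = np.flatnonzero(~in_window)
                positions.append(rng.choice(bg_pos, size=k, replace=False))
        if not positions:
            continue
        pos = np.unique(np.concatenate(positions))
        alt = (
            genome.reference[pos].astype(np.int64)
            + rng.integers(1, 4, size=pos.shape[0])
        ) % 4
        hap.snv_ref_pos = pos
        hap.snv_alt = alt.astype(np.uint8)
    return genome


# ---------------------------------------------------------------------------
# Read sampling and alignment emulation
# ---------------------------------------------------------------------------


@dataclass
class RawPairs:
    """Sampled fragments per source haplotype (coordinates, not sequences)."""

    hap_index: np.ndarray  # 0 = H1, 1 = H2, 2 = reference (impurity fragments)
    frag_start: np.ndarray  # on the source haplotype
    insert: np.ndarray

    def __len__(self) -> int:
        return int(self.hap_index.shape[0])


def sample_read_pairs(
    genome: DiploidGenome, cfg: SimConfig, rng: np.random.Generator
) -> RawPairs:
    """Sample fragment coordinates so each haplotype's expected depth is
    ``coverage/2``; with ``purity < 1`` the complementary fraction of each
    haplotype's fragments is drawn from the unaltered reference instead."""
    rl = cfg.read_length
    min_insert = 2 * rl
    hap_idx_parts, start_parts, insert_parts = [], [], []
    ref_len = int(genome.reference.shape[0])
    for hi, hap in enumerate(genome.haplotypes):
        n_pairs = int(round((cfg.coverage / 2.0) * hap.length / (2.0 * rl)))
        n_tumor = int(round(n_pairs * cfg.purity))
        for src, n, src_len in (
            (hi, n_tumor, hap.length),
            (2, n_pairs - n_tumor, ref_len),
        ):
            if n <= 0:
                continue
            inserts = np.rint(rng.normal(cfg.insert_mu, cfg.insert_sigma, n)).astype(
                np.int64
            )
            bad = (inserts < min_insert) | (inserts > src_len)
            while bad.any():  # redraw out-of-range inserts (documented)
                inserts[bad] = np.rint(
                    rng.normal(cfg.insert_mu, cfg.insert_sigma, int(bad.sum()))
                ).astype(np.int64)
                bad = (inserts < min_insert) | (inserts > src_len)
            starts = np.floor(
                rng.random(n) * (src_len - inserts + 1)
            ).astype(np.int64)
            hap_idx_parts.append(np.full(n, src, dtype=np.int64))
            start_parts.append(starts)
            insert_parts.append(inserts)
    return RawPairs(
        hap_index=np.concatenate(hap_idx_parts),
        frag_start=np.concatenate(start_parts),
        insert=np.concatenate(insert_parts),
    )


def _cigar(matchlen: int, lclip: int, rclip: int, read_length: int) -> str:
    if matchlen == read_length:
        return f"{read_length}M"
    parts = []
    if lclip:
        parts.append(f"{lclip}S")
    parts.append(f"{matchlen}M")
    if rclip:
        parts.append(f"{rclip}S")
    return "".join(parts)


def emulate_alignment(
    raw: RawPairs,
    genome: DiploidGenome,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> ReadCollection:
    """Turn sampled fragments into alignment records by the truth-driven rules.

    Mate L is the fragment-start read (forward on its haplotype), mate R the
    fragment-end read (reverse); which one is "read 1" is decided by a fair
    coin so both proper-pair flag patterns (99/147 and 83/163) occur.
    """
    rl = cfg.read_length
    n = len(raw)
    ref_hap = Haplotype([Block(length=int(genome.reference.shape[0]), ref_start=0, strand=1)])
    sources = (*genome.haplotypes, ref_hap)

    posL = np.full(n, -1, dtype=np.int64)
    strandL = np.zeros(n, dtype=np.int64)
    matchL = np.zeros(n, dtype=np.int64)
    lclipL = np.zeros(n, dtype=np.int64)
    rclipL = np.zeros(n, dtype=np.int64)
    posR = posL.copy()
    strandR = strandL.copy()
    matchR = matchL.copy()
    lclipR = lclipL.copy()
    rclipR = rclipL.copy()

    startR_all = raw.frag_start + raw.insert - rl
    for hi, hap in enumerate(sources):
        sel = raw.hap_index == hi
        if not sel.any():
            continue
        mL = hap.map_reads(raw.frag_start[sel], rl)
        mR = hap.map_reads(startR_all[sel], rl)
        posL[sel], strandL[sel] = mL["pos"], mL["strand"]
        matchL[sel], lclipL[sel], rclipL[sel] = mL["matchlen"], mL["lclip"], mL["rclip"]
        posR[sel], strandR[sel] = mR["pos"], mR["strand"]
        matchR[sel], lclipR[sel], rclipR[sel] = mR["matchlen"], mR["lclip"], mR["rclip"]

    # read orientation on the reference: mate L is forward on its haplotype,
    # mate R reverse-complemented, then possibly flipped by an inverted block
    revL = strandL == -1
    revR = strandR != -1  # reverse unless inside an inverted block
    mappedL = posL >= 0
    mappedR = posR >= 0
    both = mappedL & mappedR

    endL = posL + matchL
    endR = posR + matchR
    left_is_L = np.where(posL <= posR, True, False)
    span_lo = np.minimum(posL, posR)
    span_hi = np.maximum(endL, endR)
    tlen_abs = np.where(both, span_hi - span_lo, 0)

    # FR orientation: leftmost mate forward, rightmost mate reverse
    fwd_left = np.where(left_is_L, ~revL, ~revR)
    rev_right = np.where(left_is_L, revR, revL)
    lo = cfg.insert_mu - 3 * cfg.insert_sigma
    hi_ = cfg.insert_mu + 3 * cfg.insert_sigma
    proper = both & fwd_left & rev_right & (tlen_abs >= lo) & (tlen_abs <= hi_)

    l_is_read1 = rng.integers(0, 2, size=n).astype(bool)

    records: list[AlignmentRecord] = []
    pair_index: list[tuple[int, int | None]] = []
    append = records.append
    for i in range(n):
        pL = int(posL[i]) + 1 if mappedL[i] else (int(posR[i]) + 1 if mappedR[i] else 0)
        pR = int(posR[i]) + 1 if mappedR[i] else (int(posL[i]) + 1 if mappedL[i] else 0)
        tl = int(tlen_abs[i])
        if both[i]:
            if pL <= pR:
                tlL, tlR = tl, -tl
            else:
                tlL, tlR = -tl, tl
        else:
            tlL = tlR = 0
        flagL = 0x1
        flagR = 0x1
        if proper[i]:
            flagL |= 0x2
            flagR |= 0x2
        if not mappedL[i]:
            flagL |= 0x4
            flagR |= 0x8
        if not mappedR[i]:
            flagR |= 0x4
            flagL |= 0x8
        if mappedL[i] and revL[i]:
            flagL |= 0x10
            flagR |= 0x20
        if mappedR[i] and revR[i]:
            flagR |= 0x10
            flagL |= 0x20
        if l_is_read1[i]:
            flagL |= 0x40
            flagR |= 0x80
        else:
            flagL |= 0x80
            flagR |= 0x40
        qname = f"sim{i}"
        if mappedL[i]:
            cigL = _cigar(int(matchL[i]), int(lclipL[i]), int(rclipL[i]), rl)
            mqL = MAPQ_FULL if matchL[i] == rl else MAPQ_CLIPPED
        else:
            cigL, mqL = None, 0
        if mappedR[i]:
            cigR = _cigar(int(matchR[i]), int(lclipR[i]), int(rclipR[i]), rl)
            mqR = MAPQ_FULL if matchR[i] == rl else MAPQ_CLIPPED
        else:
            cigR, mqR = None, 0
        iL = len(records)
        append(AlignmentRecord(qname, flagL, pL, mqL, cigL, tlL, mate_pos=pR))
        append(AlignmentRecord(qname, flagR, pR, mqR, cigR, tlR, mate_pos=pL))
        pair_index.append((iL, iL + 1))
    return ReadCollection(records, pair_index=pair_index)


# ---------------------------------------------------------------------------
# Sequence emission (FASTQ / SAM)
# ---------------------------------------------------------------------------


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hit = rng.random(seq.shape[0]) < rate
    k = int(hit.sum())
    if k:
        seq = seq.copy()
        seq[hit] = (seq[hit].astype(np.int64) + rng.integers(1, 4, size=k)) % 4
    return seq


def read_sequences(
    raw: RawPairs,
    genome: DiploidGenome,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Sequences of mate L (forward) and mate R (reverse-complemented), with
    base-call errors applied, in as-sequenced orientation."""
    rl = cfg.read_length
    seqs = [
        hap.sequence(genome.reference) for hap in genome.haplotypes
    ] + [genome.reference]
    outL, outR = [], []
    for i in range(len(raw)):
        src = seqs[int(raw.hap_index[i])]
        s = int(raw.frag_start[i])
        e = s + int(raw.insert[i])
        mateL = _apply_errors(src[s : s + rl], cfg.base_error_rate, rng)
        mateR = _apply_errors(_COMP[src[e - rl : e][::-1]], cfg.base_error_rate, rng)
        outL.append(mateL)
        outR.append(mateR)
    return outL, outR


def write_fastq(
    path1: str | Path,
    path2: str | Path,
    raw: RawPairs,
    genome: DiploidGenome,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    seqL, seqR = read_sequences(raw, genome, cfg, rng)
    qual = "I" * cfg.read_length
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(len(raw)):
            f1.write(f"@sim{i}/1\n{codes_to_str(seqL[i])}\n+\n{qual}\n")
            f2.write(f"@sim{i}/2\n{codes_to_str(seqR[i])}\n+\n{qual}\n")


def write_sam(
    path: str | Path,
    collection: ReadCollection,
    cfg: SimConfig,
    raw: RawPairs | None = None,
    genome: DiploidGenome | None = None,
    rng: np.random.Generator | None = None,
    reference_length: int | None = None,
) -> None:
    """Write a coordinate-sorted SAM (or BAM if the path ends in .bam).

    When ``raw``/``genome``/``rng`` are given, read sequences (with base
    errors) are embedded; otherwise SEQ is '*'.
    """
    ref_len = reference_length or (
        int(genome.reference.shape[0]) if genome is not None else cfg.region_length
    )
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": ref_len}],
    }
    seqs: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    if raw is not None and genome is not None and rng is not None:
        seqs = read_sequences(raw, genome, cfg, rng)
    mode = "wb" if str(path).endswith(".bam") else "w"
    order = sorted(
        range(len(collection.records)), key=lambda i: collection.records[i].pos
    )
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i in order:
            rec = collection.records[i]
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = rec.flag
            a.reference_id = 0 if rec.pos > 0 else -1
            a.reference_start = rec.pos - 1 if rec.pos > 0 else -1
            a.mapping_quality = rec.mapq
            a.cigarstring = rec.cigar
            a.next_reference_id = 0 if rec.mate_pos > 0 else -1
            a.next_reference_start = rec.mate_pos - 1 if rec.mate_pos > 0 else -1
            a.template_length = rec.tlen
            if seqs is not None:
                pair_i = int(rec.qname[3:])
                # mate L maps forward unless inverted; emit in ref orientation
                raw_seq = (
                    seqs[0][pair_i] if _is_mate_l(rec, collection) else seqs[1][pair_i]
                )
                if rec.cigar is not None and rec.flag & 0x10:
                    raw_seq = _COMP[raw_seq[::-1]]
                a.query_sequence = codes_to_str(raw_seq)
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * cfg.read_length
                )
            out.write(a)


def _is_mate_l(rec: AlignmentRecord, collection: ReadCollection) -> bool:
    """Whether a record is the fragment-start mate (emitted first per pair)."""
    pair_i = int(rec.qname[3:])
    return collection.pairs[pair_i].first is rec


# ---------------------------------------------------------------------------
# One-call convenience
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """One simulated dataset: genome, truth, and emulated alignments."""

    config: SimConfig
    genome: DiploidGenome
    truth: TruthSet
    raw: RawPairs
    collection: ReadCollection

    @property
    def calls(self) -> list[SVCall]:
        return self.truth.calls

    @property
    def labels(self) -> dict[str, str]:
        return self.truth.labels


def simulate_dataset(
    cfg: SimConfig,
    reference: np.ndarray | None = None,
    plant_snv: bool = True,
) -> SimResult:
    """Full simulation: reference -> planted genome -> reads -> alignments."""
    rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = random_reference(cfg.region_length, rng)
    genome, truth = plant_variants(reference, cfg, rng)
    if plant_snv:
        plant_snvs(genome, truth, cfg, rng)
    raw = sample_read_pairs(genome, cfg, rng)
    collection = emulate_alignment(raw, genome, cfg, rng)
    return SimResult(cfg, genome, truth, raw, collection)
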