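"""Variant and alignment I/O, region arithmetic, and insert-size statistics.

Coordinate convention: 1-based, fully closed intervals throughout, matching SAM
``POS`` and the membership tests the feature extractor performs on it.  A record
belongs to a region iff its leftmost mapped position (SAM column 4) lies inside
the closed interval; span overlap is deliberately not considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

SV_TYPES = ("INS", "DEL", "INV", "CPX", "NONE")

#: Fixed genotype class order used everywhere a 5-vector is laid out.
CLASS_ORDER = ("N", "G1", "G2", "G3", "G4")


class VariantParseError(ValueError):
    """A VCF/TSV record could not be converted into an SV call."""


class InsertStatsError(ValueError):
    """Insert-size statistics could not be estimated from the alignments."""


@dataclass(frozen=True, slots=True)
class SVCall:
    """One candidate structural variant.

    ``end >= pos`` always; ``length == end - pos`` is the L used both as a
    classification feature and in the region arithmetic.  Insertions are
    annotated with ``end = pos + SVLEN`` so that L reflects the inserted
    length (see :func:`parse_sv_calls` for the fallback applied to the
    standard END==POS insertion convention).
    """

    id: str
    chrom: str
    pos: int
    end: int
    sv_type: str = "NONE"

    def __post_init__(self) -> None:
        if self.end < self.pos:
            raise VariantParseError(
                f"call {self.id}: END ({self.end}) < POS ({self.pos})"
            )
        if self.sv_type not in SV_TYPES:
            raise VariantParseError(
                f"call {self.id}: unknown SV type {self.sv_type!r}"
            )

    @property
    def length(self) -> int:
        """Variant length L = |POS - END|."""
        return self.end - self.pos


@dataclass(frozen=True, slots=True)
class MutatedRegion:
    """A closed interval [start, stop] derived from a call.

    kind is one of ``core`` ([POS-r, END+r] with r the read length),
    ``extended`` ([POS-2r, END+2r]) or ``vicinity`` ([POS-L//10, END+L//10]).
    """

    call_id: str
    start: int
    stop: int
    kind: str

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"region {self.call_id}/{self.kind}: start > stop")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.stop

    @property
    def width(self) -> int:
        return self.stop - self.start + 1


@dataclass(slots=True)
class AlignmentRecord:
    """One SAM row, reduced to the fields the genotyper consumes."""

    qname: str
    flag: int
    pos: int  # 1-based leftmost mapped base; mate position for unmapped reads
    mapq: int
    cigar: str | None  # None when the record carries no CIGAR ('*')
    tlen: int
    mate_pos: int = 0

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)


@dataclass(slots=True)
class ReadPair:
    """Two mates joined by query name; ``second`` may be absent.

    ``insert_size`` is the absolute observed template length; it is 0 when it
    is undefined (a mate absent or unmapped), and such pairs contribute to no
    insert-size feature.
    """

    qname: str
    first: AlignmentRecord
    second: AlignmentRecord | None = None

    @property
    def insert_size(self) -> int:
        if self.second is None:
            return 0
        if self.first.is_unmapped or self.second.is_unmapped:
            return 0
        return abs(self.first.tlen)

    @property
    def both_present(self) -> bool:
        return self.second is not None

    def records(self) -> tuple[AlignmentRecord, ...]:
        return (self.first,) if self.second is None else (self.first, self.second)


@dataclass(frozen=True, slots=True)
class InsertStats:
    """Library insert-size mean/sd, user-supplied or estimated from the file."""

    mu: float
    sigma: float
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InsertStatsError(
                f"insert-size sigma must be > 0 (got {self.sigma}); "
                "supply mu/sigma explicitly"
            )

    @property
    def lo(self) -> float:
        return self.mu - 3.0 * self.sigma

    @property
    def hi(self) -> float:
        return self.mu + 3.0 * self.sigma


# ---------------------------------------------------------------------------
# SV call parsing / writing
# ---------------------------------------------------------------------------


def _resolve_end(pos: int, end, svlen) -> int:
    """END resolution: INFO END, else POS+|SVLEN|.

    END == POS together with a nonzero SVLEN is the standard point-insertion
    convention; it is resolved to POS+|SVLEN| so that L carries the inserted
    length.
    """
    if end is not None and end != pos:
        return int(end)
    if svlen is not None and int(svlen) != 0:
        return pos + abs(int(svlen))
    if end is not None:
        return int(end)
    raise VariantParseError("record has no resolvable END (no INFO END or SVLEN)")


def parse_sv_calls(path: str | Path) -> list[SVCall]:
    """Read candidate SV calls from a VCF (4.x) or the simplified TSV dialect.

    The TSV dialect (headered columns id, chrom, pos, end, sv_type) is a test
    fixture format, not a standard; files named ``*.tsv`` use it.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        return _parse_sv_calls_tsv(path)
    return _parse_sv_calls_vcf(path)


def _parse_sv_calls_vcf(path: Path) -> list[SVCall]:
    calls: list[SVCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            try:
                info = rec.info
                svtype = str(info.get("SVTYPE", "NONE")) if "SVTYPE" in info else "NONE"
                svlen = info.get("SVLEN") if "SVLEN" in info else None
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                # rec.stop mirrors INFO END (or pos+len(ref)-1 when absent).
                end = rec.stop
                call_id = rec.id if rec.id else f"call_{i + 1}"
                pos = rec.pos  # pysam exposes the 1-based POS here
                calls.append(
                    SVCall(
                        id=call_id,
                        chrom=rec.chrom,
                        pos=pos,
                        end=_resolve_end(pos, end, svlen),
                        sv_type=svtype if svtype in SV_TYPES else "NONE",
                    )
                )
            except VariantParseError as exc:
                raise VariantParseError(f"{path} record {i + 1}: {exc}") from exc
    return calls


def _parse_sv_calls_tsv(path: Path) -> list[SVCall]:
    calls: list[SVCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "chrom", "pos", "end", "sv_type"]
        if header != expected:
            raise VariantParseError(f"{path} line 1: expected header {expected}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise VariantParseError(
                    f"{path} line {lineno}: expected 5 columns, got {len(fields)}"
                )
            try:
                calls.append(
                    SVCall(
                        id=fields[0],
                        chrom=fields[1],
                        pos=int(fields[2]),
                        end=int(fields[3]),
                        sv_type=fields[4],
                    )
                )
            except (ValueError, VariantParseError) as exc:
                raise VariantParseError(f"{path} line {lineno}: {exc}") from exc
    return calls


def write_sv_calls_tsv(calls: Sequence[SVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\tend\tsv_type\n")
        for c in calls:
            fh.write(f"{c.id}\t{c.chrom}\t{c.pos}\t{c.end}\t{c.sv_type}\n")


def build_vcf_header(
    chrom: str, reference_length: int, extra_info: Iterable[tuple[str, str, str, str]] = ()
) -> pysam.VariantHeader:
    """VCF 4.2 header with contig plus the SV INFO keys this package emits."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={reference_length}>")
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">'
    )
    for key, number, vtype, desc in extra_info:
        header.add_line(
            f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">'
        )
    return header


# ---------------------------------------------------------------------------
# Region arithmetic
# ---------------------------------------------------------------------------


def derive_regions(
    call: SVCall, read_length: int, reference_length: int
) -> tuple[MutatedRegion, MutatedRegion, MutatedRegion]:
    """(core, extended, vicinity) regions for a call.

    core pads by one read length, extended by two, vicinity by L//10; all
    coordinates are clamped to [1, reference_length].
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if call.pos > reference_length:
        raise ValueError(
            f"call {call.id}: POS {call.pos} beyond reference length {reference_length}"
        )

    def clamp(lo: int, hi: int, kind: str) -> MutatedRegion:
        return MutatedRegion(
            call_id=call.id,
            start=max(1, lo),
            stop=min(reference_length, hi),
            kind=kind,
        )

    pad_v = call.length // 10
    core = clamp(call.pos - read_length, call.end + read_length, "core")
    extended = clamp(call.pos - 2 * read_length, call.end + 2 * read_length, "extended")
    vicinity = clamp(call.pos - pad_v, call.end + pad_v, "vicinity")
    return core, extended, vicinity


# ---------------------------------------------------------------------------
# Insert-size statistics
# ---------------------------------------------------------------------------


def estimate_insert_stats(pairs: Iterable[ReadPair]) -> InsertStats:
    """Mean/sd of absolute insert sizes over all fully mapped pairs.

    Uses the population (n) denominator for sigma; pairs with an absent or
    unmapped mate are skipped.
    """
    inserts = [p.insert_size for p in pairs if p.insert_size > 0]
    if len(inserts) < 2:
        raise InsertStatsError(
            "fewer than 2 usable read pairs; supply mu/sigma explicitly"
        )
    arr = np.asarray(inserts, dtype=float)
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=0))
    if sigma <= 0:
        raise InsertStatsError(
            "insert sizes have zero spread; supply mu/sigma explicitly"
        )
    return InsertStats(mu=mu, sigma=sigma, source="estimated")


# ---------------------------------------------------------------------------
# Alignment collections and region scans
# ---------------------------------------------------------------------------


class ReadCollection:
    """All alignment records of one file, joined into pairs, scan-indexed.

    The collection holds the full file in memory (a documented full-scan
    design: region membership is by leftmost POS only, so a coordinate-sorted
    scan with ``searchsorted`` answers every region query exactly; no BAM
    index is required).
    """

    def __init__(
        self,
        records: Sequence[AlignmentRecord],
        pair_index: Sequence[tuple[int, int | None]] | None = None,
    ):
        self.records = list(records)
        n = len(self.records)
        self._pos = np.fromiter((r.pos for r in self.records), dtype=np.int64, count=n)
        self._order = np.argsort(self._pos, kind="stable")
        self._sorted_pos = self._pos[self._order]
        self.max_mapq = int(
            max((r.mapq for r in self.records), default=0)
        )
        if pair_index is None:
            # Pair joining by qname.
            by_name: dict[str, list[int]] = {}
            for i, rec in enumerate(self.records):
                by_name.setdefault(rec.qname, []).append(i)
            pair_index = [
                (idxs[0], idxs[1] if len(idxs) > 1 else None)
                for idxs in by_name.values()
            ]
        self.pairs: list[ReadPair] = []
        pair_pos1: list[int] = []
        pair_pos2: list[int] = []
        for i1, i2 in pair_index:
            first = self.records[i1]
            second = self.records[i2] if i2 is not None else None
            self.pairs.append(ReadPair(qname=first.qname, first=first, second=second))
            pair_pos1.append(first.pos)
            pair_pos2.append(second.pos if second is not None else first.pos)
        self._pair_pos1 = np.asarray(pair_pos1, dtype=np.int64)
        self._pair_pos2 = np.asarray(pair_pos2, dtype=np.int64)
        self._pair_order1 = np.argsort(self._pair_pos1, kind="stable")
        self._pair_order2 = np.argsort(self._pair_pos2, kind="stable")
        self._pair_sorted1 = self._pair_pos1[self._pair_order1]
        self._pair_sorted2 = self._pair_pos2[self._pair_order2]

    def __len__(self) -> int:
        return len(self.records)

    def records_in(self, region: MutatedRegion) -> list[AlignmentRecord]:
        """Records whose POS lies in the closed region interval."""
        lo = np.searchsorted(self._sorted_pos, region.start, side="left")
        hi = np.searchsorted(self._sorted_pos, region.stop, side="right")
        return [self.records[i] for i in self._order[lo:hi]]

    def pairs_in(self, region: MutatedRegion) -> list[tuple[ReadPair, bool, bool]]:
        """Pairs with >= 1 mate POS in the region, with per-mate indicators."""
        lo1 = np.searchsorted(self._pair_sorted1, region.start, side="left")
        hi1 = np.searchsorted(self._pair_sorted1, region.stop, side="right")
        lo2 = np.searchsorted(self._pair_sorted2, region.start, side="left")
        hi2 = np.searchsorted(self._pair_sorted2, region.stop, side="right")
        idx = np.union1d(self._pair_order1[lo1:hi1], self._pair_order2[lo2:hi2])
        out = []
        for i in idx:
            p = self.pairs[i]
            in1 = p.first.pos in region
            in2 = p.second.pos in region if p.second is not None else False
            out.append((p, in1, in2))
        return out


def load_alignments(path: str | Path) -> ReadCollection:
    """Load a SAM/BAM file into a :class:`ReadCollection` (full scan)."""
    records: list[AlignmentRecord] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for seg in af:
                if seg.is_secondary or seg.is_supplementary:
                    continue
                records.append(
                    AlignmentRecord(
                        qname=seg.query_name or "",
                        flag=seg.flag,
                        pos=(seg.reference_start + 1) if seg.reference_start is not None
                        and seg.reference_start >= 0
                        else (seg.next_reference_start + 1 if seg.next_reference_start is not None and seg.next_reference_start >= 0 else 0),
                        mapq=seg.mapping_quality,
                        cigar=seg.cigarstring,
                        tlen=seg.template_length,
                        mate_pos=(seg.next_reference_start + 1)
                        if seg.next_reference_start is not None and seg.next_reference_start >= 0
                        else 0,
                    )
                )
    finally:
        pysam.set_verbosity(save)
    return records_to_collection(records)


def records_to_collection(records: Sequence[AlignmentRecord]) -> ReadCollection:
    return ReadCollection(records)


def collect_region_records(
    alignments: ReadCollection, region: MutatedRegion
) -> tuple[list[tuple[ReadPair, bool, bool]], list[AlignmentRecord]]:
    """Region scan: pairs with in-region indicators, plus mate-less singletons.

    A record is in the region iff its POS is in [start, stop] inclusive.  A
    pair is returned when at least one mate's POS is in-region; singletons are
    in-region records whose mate never occurs in the file.
    """
    pairs = [t for t in alignments.pairs_in(region) if t[0].both_present]
    singles = [
        p.first
        for (p, in1, _in2) in alignments.pairs_in(region)
        if not p.both_present and in1
    ]
    return pairs, singles
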