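"""The fifteen per-call classification features.

Feature order (the on-disk column contract):

====  ==========================  ============================================
 F1   abnormal_read               pairs with |insert| outside mu +/- 3 sigma
 F2   normal_read                 pairs with |insert| inside mu +/- 3 sigma
 F3   incompletely_mapped         mapped records whose CIGAR is not the
                                  full-match token (clips/indels)
 F4   fully_mapped                pairs whose two CIGARs both equal the token
 F5   split_mapped                pairs with exactly one mate POS in-region
 F6   single_mapped               full-match records whose mate is absent or
                                  not full-match
 F7   unmapped                    unmapped-flag records anchored in-region
 F8   mapq_sum                    sum of MAPQ over in-region records
 F9   read_depth                  in-region mapped records / L
 F10  weighted_read_depth         sum(MAPQ_i / Q_max) / L, same records
 F11  extended_weighted_read_depth  F10 over the extended region, same L
 F12  affected_reads              records with POS in the vicinity range
 F13  variant_length              L = END - POS
 F14  direction1                  records with FLAG exactly 83
 F15  direction2                  records with FLAG exactly 163
====  ==========================  ============================================

All interval tests are inclusive; membership is by leftmost POS.  The
direction features use exact integer FLAG equality (83 / 163), so compound
flags (e.g. secondary 339) are deliberately not counted.  When L = 0 (a point
call), the depth denominators fall back to the core-region width and the
vicinity pad is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    AlignmentRecord,
    InsertStats,
    MutatedRegion,
    ReadCollection,
    ReadPair,
    SVCall,
    collect_region_records,
    derive_regions,
)

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "abnormal_read",
    "normal_read",
    "incompletely_mapped",
    "fully_mapped",
    "split_mapped",
    "single_mapped",
    "unmapped",
    "mapq_sum",
    "read_depth",
    "weighted_read_depth",
    "extended_weighted_read_depth",
    "affected_reads",
    "variant_length",
    "direction1",
    "direction2",
)


@dataclass(frozen=True, slots=True)
class FeatureVector:
    abnormal_read: int
    normal_read: int
    incompletely_mapped: int
    fully_mapped: int
    split_mapped: int
    single_mapped: int
    unmapped: int
    mapq_sum: int
    read_depth: float
    weighted_read_depth: float
    extended_weighted_read_depth: float
    affected_reads: int
    variant_length: int
    direction1: int
    direction2: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dataclass_fields(self)],
                        dtype=float)


def _full_token(read_length: int) -> str:
    return f"{read_length}M"


# ---------------------------------------------------------------------------
# Individual feature groups
# ---------------------------------------------------------------------------


def count_insert_size_features(
    pairs: Sequence[tuple[ReadPair, bool, bool]] | Sequence[ReadPair],
    stats: InsertStats,
) -> tuple[int, int]:
    """(normal_read, abnormal_read): pairs split by |insert| vs mu +/- 3 sigma.

    The boundary is inclusive on the normal side.  Pairs without a usable
    insert size (absent or unmapped mate) count in neither.
    """
    normal = abnormal = 0
    for item in pairs:
        pair = item[0] if isinstance(item, tuple) else item
        ins = pair.insert_size
        if ins <= 0:
            continue
        if stats.lo <= ins <= stats.hi:
            normal += 1
        else:
            abnormal += 1
    return normal, abnormal


def count_alignment_features(
    pairs: Sequence[tuple[ReadPair, bool, bool]],
    singletons: Sequence[AlignmentRecord],
    region: MutatedRegion,
    read_length: int,
) -> tuple[int, int, int, int, int]:
    """(fully_mapped, single_mapped, incompletely_mapped, split_mapped, unmapped).

    Record-level counts (incompletely_mapped, unmapped) run over in-region
    records; pair-level counts (fully_mapped, split_mapped) over pairs with at
    least one mate in-region; single_mapped over in-region full-match records
    whose mate does not also match fully.
    """
    token = _full_token(read_length)
    fully = single = incomplete = split = unmapped = 0

    def record_counts(rec: AlignmentRecord, in_region: bool) -> None:
        nonlocal incomplete, unmapped
        if not in_region:
            return
        if rec.is_unmapped:
            unmapped += 1
        elif rec.cigar is None:
            logger.warning("mapped record %s has no CIGAR; counted incomplete",
                           rec.qname)
            incomplete += 1
        elif rec.cigar != token:
            incomplete += 1

    for pair, in1, in2 in pairs:
        recs = pair.records()
        flags = (in1, in2)[: len(recs)]
        for rec, inr in zip(recs, flags):
            record_counts(rec, inr)
        full = [
            (rec.cigar == token and not rec.is_unmapped) for rec in recs
        ]
        if len(recs) == 2:
            if full[0] and full[1]:
                fully += 1
            else:
                for rec, f, inr in zip(recs, full, flags):
                    if f and inr:
                        single += 1
            if in1 != in2:
                split += 1
        else:
            if full[0] and flags[0]:
                single += 1
    for rec in singletons:
        record_counts(rec, True)
        if rec.cigar == token and not rec.is_unmapped:
            single += 1
    return fully, single, incomplete, split, unmapped


def count_direction_features(records: Sequence[AlignmentRecord]) -> tuple[int, int]:
    """Counts of records whose FLAG equals exactly 83 and exactly 163."""
    d1 = sum(1 for r in records if r.flag == 83)
    d2 = sum(1 for r in records if r.flag == 163)
    return d1, d2


def sum_mapping_qualities(records: Sequence[AlignmentRecord]) -> int:
    return int(sum(r.mapq for r in records))


def _depth_denominator(call: SVCall, core: MutatedRegion) -> int:
    if call.length > 0:
        return call.length
    logger.info("call %s has L=0; depth denominators use core width %d",
                call.id, core.width)
    return core.width


def read_depth(records: Sequence[AlignmentRecord], length: int) -> float:
    """Mapped in-region record count divided by L."""
    n = sum(1 for r in records if not r.is_unmapped)
    return n / length if length > 0 else 0.0


def weighted_read_depth(
    records: Sequence[AlignmentRecord], length: int, q_max: int
) -> float:
    """MAPQ-weighted depth: sum(Q_i / Q_max) / L over mapped in-region records."""
    if q_max <= 0:
        logger.warning("Q_max is 0; weighted read depth defined as 0")
        return 0.0
    w = sum(r.mapq / q_max for r in records if not r.is_unmapped)
    return w / length if length > 0 else 0.0


def extended_weighted_read_depth(
    records_extended: Sequence[AlignmentRecord], length: int, q_max: int
) -> float:
    """Same weighted-depth formula over the extended region, same denominator."""
    return weighted_read_depth(records_extended, length, q_max)


def count_affected_reads(
    records_vicinity: Sequence[AlignmentRecord],
) -> int:
    return len(records_vicinity)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def extract_features(
    call: SVCall,
    alignments: ReadCollection,
    stats: InsertStats,
    q_max: int | None = None,
    read_length: int = 100,
    reference_length: int | None = None,
) -> FeatureVector:
    """All fifteen features for one call."""
    if reference_length is None:
        reference_length = int(max(call.end + 2 * read_length, 1))
    if q_max is None:
        q_max = alignments.max_mapq
    try:
        core, extended, vicinity = derive_regions(call, read_length, reference_length)
        pairs, singles = collect_region_records(alignments, core)
        records = alignments.records_in(core)
        records_ext = alignments.records_in(extended)
        records_vic = alignments.records_in(vicinity)

        normal, abnormal = count_insert_size_features(pairs, stats)
        fully, single, incomplete, split, unmapped = count_alignment_features(
            pairs, singles, core, read_length
        )
        d1, d2 = count_direction_features(records)
        mapq_sum = sum_mapping_qualities(records)
        denom = _depth_denominator(call, core)
        depth = read_depth(records, denom)
        wrd = weighted_read_depth(records, denom, q_max)
        ewrd = extended_weighted_read_depth(records_ext, denom, q_max)
        affected = count_affected_reads(records_vic)
    except Exception as exc:
        raise type(exc)(f"call {call.id}: {exc}") from exc

    return FeatureVector(
        abnormal_read=abnormal,
        normal_read=normal,
        incompletely_mapped=incomplete,
        fully_mapped=fully,
        split_mapped=split,
        single_mapped=single,
        unmapped=unmapped,
        mapq_sum=mapq_sum,
        read_depth=depth,
        weighted_read_depth=wrd,
        extended_weighted_read_depth=ewrd,
        affected_reads=affected,
        variant_length=call.length,
        direction1=d1,
        direction2=d2,
    )


def extract_feature_matrix(
    calls: Sequence[SVCall],
    alignments: ReadCollection,
    stats: InsertStats,
    read_length: int = 100,
    reference_length: int | None = None,
) -> pd.DataFrame:
    """Feature table indexed by call id, columns in the fixed F1-F15 order."""
    q_max = alignments.max_mapq
    rows = []
    for call in calls:
        fv = extract_features(
            call,
            alignments,
            stats,
            q_max=q_max,
            read_length=read_length,
            reference_length=reference_length,
        )
        rows.append(fv.as_array())
    mat = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, len(FEATURE_COLUMNS))),
        columns=list(FEATURE_COLUMNS),
        index=pd.Index([c.id for c in calls], name="call_id"),
    )
    return mat


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="call_id")
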