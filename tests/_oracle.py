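"""Brute-force text-scan oracle for the fifteen features.

Reads the SAM file as plain text (no pysam, no ReadCollection) and recomputes
every feature from the column-value rules directly.  Kept deliberately naive
and independent of the package implementation.
"""

from __future__ import annotations


def _parse_sam_text(sam_path):
    records = []
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                {
                    "qname": f[0],
                    "flag": int(f[1]),
                    "pos": int(f[3]),
                    "mapq": int(f[4]),
                    "cigar": f[5],
                    "tlen": int(f[8]),
                }
            )
    return records


def sam_text_features(sam_path, calls, mu, sigma, read_length, ref_length):
    """One dict of the fifteen features per call, keyed by call id."""
    records = _parse_sam_text(sam_path)
    qmax = max((r["mapq"] for r in records), default=0)
    by_name = {}
    for r in records:
        by_name.setdefault(r["qname"], []).append(r)
    pairs = list(by_name.values())
    token = f"{read_length}M"
    lo, hi = mu - 3 * sigma, mu + 3 * sigma

    out = {}
    for call in calls:
        L = call.end - call.pos
        core = (max(1, call.pos - read_length), min(ref_length, call.end + read_length))
        ext = (
            max(1, call.pos - 2 * read_length),
            min(ref_length, call.end + 2 * read_length),
        )
        pad = L // 10
        vic = (max(1, call.pos - pad), min(ref_length, call.end + pad))

        def inside(p, iv):
            return iv[0] <= p <= iv[1]

        core_recs = [r for r in records if inside(r["pos"], core)]
        sel_pairs = [
            pr for pr in pairs if any(inside(r["pos"], core) for r in pr)
        ]

        normal = abnormal = 0
        fully = split = single = 0
        for pr in sel_pairs:
            if len(pr) == 2:
                a, b = pr
                both_mapped = not (a["flag"] & 4) and not (b["flag"] & 4)
                ins = abs(a["tlen"])
                if both_mapped and ins > 0:
                    if lo <= ins <= hi:
                        normal += 1
                    else:
                        abnormal += 1
                full_a = a["cigar"] == token and not (a["flag"] & 4)
                full_b = b["cigar"] == token and not (b["flag"] & 4)
                if full_a and full_b:
                    fully += 1
                else:
                    if full_a and inside(a["pos"], core):
                        single += 1
                    if full_b and inside(b["pos"], core):
                        single += 1
                if inside(a["pos"], core) != inside(b["pos"], core):
                    split += 1
            else:
                a = pr[0]
                if (
                    a["cigar"] == token
                    and not (a["flag"] & 4)
                    and inside(a["pos"], core)
                ):
                    single += 1

        unmapped = sum(1 for r in core_recs if r["flag"] & 4)
        incomplete = sum(
            1
            for r in core_recs
            if not (r["flag"] & 4) and r["cigar"] != token
        )
        mapq_sum = sum(r["mapq"] for r in core_recs)
        denom = L if L > 0 else (core[1] - core[0] + 1)
        n_mapped = sum(1 for r in core_recs if not (r["flag"] & 4))
        depth = n_mapped / denom
        wrd = (
            sum(r["mapq"] / qmax for r in core_recs if not (r["flag"] & 4)) / denom
            if qmax > 0
            else 0.0
        )
        ewrd = (
            sum(
                r["mapq"] / qmax
                for r in records
                if inside(r["pos"], ext) and not (r["flag"] & 4)
            )
            / denom
            if qmax > 0
            else 0.0
        )
        affected = sum(1 for r in records if inside(r["pos"], vic))
        d1 = sum(1 for r in core_recs if r["flag"] == 83)
        d2 = sum(1 for r in core_recs if r["flag"] == 163)

        out[call.id] = {
            "abnormal_read": abnormal,
            "normal_read": normal,
            "incompletely_mapped": incomplete,
            "fully_mapped": fully,
            "split_mapped": split,
            "single_mapped": single,
            "unmapped": unmapped,
            "mapq_sum": mapq_sum,
            "read_depth": depth,
            "weighted_read_depth": wrd,
            "extended_weighted_read_depth": ewrd,
            "affected_reads": affected,
            "variant_length": L,
            "direction1": d1,
            "direction2": d2,
        }
    return out
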