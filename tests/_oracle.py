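"""Independent brute-force recomputation of per-site pseudogenome decisions.

Everything here is computed by naive walks over alignment ops and read
records - dictionaries of per-site base lists, linear scans for indel
distances, per-read pileups - deliberately sharing none of the vectorized
code paths in pseudosnp.pseudogenome / pseudosnp.read_support.
"""
from __future__ import annotations

import math
from collections import defaultdict

from pseudosnp.alignment import LocalAlignment, select_one_to_one
from pseudosnp.io_formats import ReadAlignmentRecord, SequenceSet


def walk_alignment(aln: LocalAlignment, contigs: SequenceSet):
    """Yield (ref_pos, base or None) for every reference-consuming column,
    plus a list of gap-event coordinates (D columns at r, I runs at r-0.5)."""
    seq = contigs[aln.ctg_id]
    if aln.strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        seq = "".join(comp[b] for b in reversed(seq))
    sites = []
    gaps = []
    r, q = aln.ref_start, aln.q_start
    for op, n in aln.ops:
        for _ in range(n):
            if op in "=X":
                sites.append((r, seq[q]))
                r += 1
                q += 1
            elif op == "D":
                sites.append((r, None))
                gaps.append(float(r))
                r += 1
            else:  # I
                if not gaps or gaps[-1] != r - 0.5:
                    gaps.append(r - 0.5)
                q += 1
    return sites, gaps


def naive_dedupe(records):
    best = {}
    order = []
    for rec in records:
        if rec.is_duplicate:
            continue
        key = (rec.ref_id, rec.ref_start, rec.ref_end, rec.is_reverse)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.mapq > best[key].mapq:
            best[key] = rec
    return [best[k] for k in order]


def naive_pileup(records: list[ReadAlignmentRecord]):
    """site -> (base counts dict, total depth) per contig, by per-read walks."""
    counts = defaultdict(lambda: defaultdict(int))
    depth = defaultdict(int)
    for rec in records:
        r, q = rec.ref_start, 0
        for op, n in rec.ops:
            if op == "M":
                for j in range(n):
                    base = rec.seq[q + j]
                    depth[(rec.ref_id, r + j)] += 1
                    if base in "ACGT":
                        counts[(rec.ref_id, r + j)][base] += 1
                r += n
                q += n
            elif op == "D":
                for j in range(n):
                    depth[(rec.ref_id, r + j)] += 1
                r += n
            else:  # I or S consume the read only
                q += n
    return counts, depth


def brute_force_pseudogenome(
    reference: SequenceSet,
    contigs: SequenceSet,
    alignments: list[LocalAlignment],
    records: list[ReadAlignmentRecord],
    min_align_len: int = 0,
    indel_margin: int = 5,
    min_depth: int = 10,
    min_frac: float = 0.9,
):
    """Per-site decisions {(contig, pos): (char, n_allele, d_indel, c_all,
    c_allele)} recomputed from raw alignments and reads."""
    pool = [a for a in alignments if a.ref_span >= min_align_len]
    o2o = select_one_to_one(pool, 0)

    seen = defaultdict(set)  # (contig, pos) -> distinct bases over the pool
    for aln in pool:
        sites, _ = walk_alignment(aln, contigs)
        for r, base in sites:
            if base is not None and base in "ACGT":
                seen[(aln.ref_id, r)].add(base)

    chosen = {}  # (contig, pos) -> (base or None, d_indel)
    for aln in o2o.alignments:
        sites, gaps = walk_alignment(aln, contigs)
        for r, base in sites:
            if gaps:
                d = math.ceil(min(abs(r - g) for g in gaps))
            else:
                d = math.inf
            chosen[(aln.ref_id, r)] = (base, d)

    counts, depth = naive_pileup(naive_dedupe(records))

    out = {}
    for contig, seq in reference:
        for pos in range(len(seq)):
            key = (contig, pos)
            n_allele = len(seen.get(key, ()))
            base, d = chosen.get(key, (None, math.inf))
            c_all = depth.get(key, 0)
            c_allele = (
                counts.get(key, {}).get(base, 0)
                if base is not None and base in "ACGT"
                else 0
            )
            call = "N"
            if (
                base is not None
                and base in "ACGT"
                and n_allele == 1
                and d > indel_margin
                and c_all > 0
                and c_allele >= min_depth
                and (c_allele / c_all) >= min_frac
            ):
                call = base
            out[key] = (call, n_allele, d, c_all, c_allele)
    return out
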