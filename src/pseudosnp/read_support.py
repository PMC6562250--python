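"""Per-site read support: duplicate removal, pileups and soft-clip regions.

The pileup supplies the two read-side quantities the masking step needs at
every reference site: c_all, the depth of all mapped reads covering the
site, and (via the per-base counts) c_allele, the depth of reads whose base
equals a given allele. Base qualities are ignored throughout; mapping
quality is filtered only if a threshold is requested.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode
from .io_formats import ReadAlignmentRecord, SequenceSet


def dedupe(records: list[ReadAlignmentRecord]) -> list[ReadAlignmentRecord]:
    """Remove PCR/optical duplicates from one isolate's records.

    Records flagged as duplicates are dropped. Among the rest, records that
    share (ref_id, aligned start, aligned end, orientation) are collapsed to
    the single record with the highest mapping quality (ties: first in input
    order). Idempotent by construction.
    """
    best: dict[tuple, ReadAlignmentRecord] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.is_duplicate:
            continue
        key = (rec.ref_id, rec.ref_start, rec.ref_end, rec.is_reverse)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            order.append(key)
        elif rec.mapq > cur.mapq:
            best[key] = rec
    return [best[k] for k in order]


@dataclass
class SitePileup:
    """Per-site read evidence over one reference contig.

    ``base_counts`` is a (4, L) array of A/C/G/T depths from aligned (M)
    columns; ``depth_total`` additionally counts reads whose deletion spans
    the site (and reads contributing an N base), so the sum of base counts
    never exceeds it. ``softclip_count[p]`` counts reads whose soft-clipped
    segment meets its aligned segment at p; ``spanning_count[p]`` counts
    reads whose aligned span covers p.
    """

    length: int
    base_counts: np.ndarray = field(default=None)
    depth_total: np.ndarray = field(default=None)
    softclip_count: np.ndarray = field(default=None)
    spanning_count: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.base_counts is None:
            self.base_counts = np.zeros((4, self.length), dtype=np.int32)
        if self.depth_total is None:
            self.depth_total = np.zeros(self.length, dtype=np.int32)
        if self.softclip_count is None:
            self.softclip_count = np.zeros(self.length, dtype=np.int32)
        if self.spanning_count is None:
            self.spanning_count = np.zeros(self.length, dtype=np.int32)

    def c_all(self, pos: int) -> int:
        return int(self.depth_total[pos])

    def c_allele(self, pos: int, base_code: int) -> int:
        return int(self.base_counts[base_code, pos])


def pileup(
    records: list[ReadAlignmentRecord],
    reference: SequenceSet,
    min_mapq: int = 0,
) -> dict[str, SitePileup]:
    """Accumulate per-site base counts and depth from deduplicated records.

    Aligned (M) columns contribute their read base; deletion (D) columns
    contribute to total depth only; soft-clipped bases contribute to nothing
    except the clip-breakpoint bookkeeping used by soft-clip region
    detection.
    """
    lengths = reference.lengths()
    piles = {name: SitePileup(length) for name, length in lengths.items()}

    # per contig: column positions/bases gathered then histogrammed once
    m_pos: dict[str, list[np.ndarray]] = {n: [] for n in lengths}
    m_base: dict[str, list[np.ndarray]] = {n: [] for n in lengths}
    d_pos: dict[str, list[np.ndarray]] = {n: [] for n in lengths}

    for rec in records:
        if rec.mapq < min_mapq:
            continue
        pile = piles[rec.ref_id]
        r = rec.ref_start
        q = 0
        codes = encode(rec.seq)
        for op, n in rec.ops:
            if op == "M":
                m_pos[rec.ref_id].append(np.arange(r, r + n))
                m_base[rec.ref_id].append(codes[q : q + n])
                r += n
                q += n
            elif op == "D":
                d_pos[rec.ref_id].append(np.arange(r, r + n))
                r += n
            elif op == "I":
                q += n
            else:  # soft clip: record the breakpoint where it meets the alignment
                if q == 0 and rec.ref_start < pile.length:
                    pile.softclip_count[rec.ref_start] += 1
                elif q > 0 and rec.ref_end > 0:
                    pile.softclip_count[rec.ref_end - 1] += 1
                q += n
        lo, hi = rec.ref_start, rec.ref_end
        if hi > lo:
            pile.spanning_count[lo] += 1
            if hi < pile.length:
                pile.spanning_count[hi] -= 1

    for name, pile in piles.items():
        length = pile.length
        pile.spanning_count = np.cumsum(pile.spanning_count).astype(np.int32)
        if m_pos[name]:
            pos = np.concatenate(m_pos[name])
            base = np.concatenate(m_base[name])
            keep = base < 4
            idx = pos[keep] * 4 + base[keep]
            pile.base_counts = (
                np.bincount(idx, minlength=4 * length)
                .reshape(length, 4)
                .T.astype(np.int32)
            )
            depth = np.bincount(pos, minlength=length)
        else:
            depth = np.zeros(length, dtype=np.int64)
        if d_pos[name]:
            depth = depth + np.bincount(
                np.concatenate(d_pos[name]), minlength=length
            )
        pile.depth_total = depth.astype(np.int32)
    return piles


@dataclass
class SoftClipRegions:
    """Sorted disjoint half-open intervals per reference contig where read
    soft-clipping is dense (a footprint of structural differences)."""

    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __contains__(self, site: tuple[str, int]) -> bool:
        contig, pos = site
        for s, e in self.regions.get(contig, ()):
            if s <= pos < e:
                return True
        return False

    def total_size(self) -> int:
        return sum(e - s for ivs in self.regions.values() for s, e in ivs)


def detect_softclip_regions(
    records: list[ReadAlignmentRecord],
    reference: SequenceSet,
    clip_frac: float = 0.5,
    min_reads: int = 5,
    merge_gap: int = 10,
) -> SoftClipRegions:
    """Find reference intervals where many reads are soft-clipped.

    A position seeds a region when at least ``min_reads`` reads have a clip
    breakpoint there and those reads are at least ``clip_frac`` of all reads
    overlapping the position; seeds within ``merge_gap`` bp are merged. The
    thresholds are explicit surrogates and deliberately configurable.
    """
    piles = pileup(records, reference)
    out: dict[str, list[tuple[int, int]]] = {}
    for name, pile in piles.items():
        overlap = np.maximum(pile.spanning_count, pile.softclip_count)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(overlap > 0, pile.softclip_count / np.maximum(overlap, 1), 0.0)
        seeds = np.flatnonzero((pile.softclip_count >= min_reads) & (frac >= clip_frac))
        if seeds.size == 0:
            continue
        intervals = []
        start = prev = int(seeds[0])
        for s in seeds[1:]:
            s = int(s)
            if s - prev <= merge_gap:
                prev = s
            else:
                intervals.append((start, prev + 1))
                start = prev = s
        intervals.append((start, prev + 1))
        out[name] = intervals
    return SoftClipRegions(out)


def classify_fp_by_softclip(
    fp_sites: list[tuple[str, int]], regions: SoftClipRegions
) -> tuple[int, int, float | None]:
    """Count false-positive sites that fall inside soft-clip regions.

    Returns (inside, total, fraction); the fraction is None when there are
    no false positives at all (rendered as '–' downstream).
    """
    total = len(fp_sites)
    inside = sum(1 for site in fp_sites if site in regions)
    return inside, total, (inside / total if total else None)


def render_fraction(fraction: float | None, percent: bool = True) -> str:
    """Render a possibly undefined ratio the way the benchmark tables do."""
    if fraction is None:
        return "–"
    return f"{fraction * 100:.2f}" if percent else f"{fraction:.4f}"
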