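"""Pseudogenome construction: assembly-side allele determination plus
read-support masking.

A pseudogenome is a per-isolate sequence in strict one-to-one site
correspondence with the reference: every reference site holds the isolate's
allele (A/C/G/T) or N when the evidence is ambiguous. A site's allele is
determined from the contig-reference alignments iff

    (1) n_allele = 1        exactly one distinct contig base aligns there
    (2) d_indel > margin    the site is farther than `indel_margin` (default
                            5 bp) from the nearest gap column

and the determined allele is then kept only if the mapped reads support it:

    (3) c_allele >= min_depth   (default 10)
    (4) c_allele / c_all >= min_frac   (default 0.9)

By default both (3) and (4) are required; `mask_mode="any"` keeps a site
that satisfies at least one of them. n_allele is counted over *all*
alignments surviving the length filter, before one-to-one selection, so
ambiguity evidence from a rejected duplicate placement still masks a site.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._seq import BASES, decode, encode, revcomp_codes
from .alignment import LocalAlignment, OneToOneMap, align_contigs, select_one_to_one
from .io_formats import ReadAlignmentRecord, SequenceSet
from .read_support import SitePileup, dedupe, pileup

_INF = float("inf")
_POPCOUNT4 = np.array([bin(i).count("1") for i in range(16)], dtype=np.int8)

MaskMode = Literal["both", "any"]


@dataclass
class SiteSupport:
    """Evidence at one reference site for one isolate."""

    n_allele: int
    allele: str | None  # defined only when n_allele == 1
    d_indel: float  # inf when the covering alignment is gap-free / site unaligned
    c_all: int
    c_allele: int


@dataclass
class Pseudogenome:
    """Per-reference-contig isolate sequence over {A,C,G,T,N}, with every
    contig exactly as long as its reference counterpart."""

    contigs: dict[str, np.ndarray]  # uint8 codes; N = 4

    def contig_strings(self) -> dict[str, str]:
        return {name: decode(codes) for name, codes in self.contigs.items()}

    def lengths(self) -> dict[str, int]:
        return {name: len(codes) for name, codes in self.contigs.items()}

    def called_mask(self) -> dict[str, np.ndarray]:
        return {name: codes < 4 for name, codes in self.contigs.items()}


def assembly_allele(support: SiteSupport, indel_margin: int = 5) -> str | None:
    """Assembly-side decision: the aligned allele iff n_allele == 1 and
    d_indel > indel_margin; otherwise mask (None)."""
    if support.n_allele != 1 or support.allele is None:
        return None
    if not (support.d_indel > indel_margin):
        return None
    return support.allele


def read_mask(
    pseudo_allele: str | None,
    c_all: int,
    c_allele: int,
    min_depth: int = 10,
    min_frac: float = 0.9,
    mask_mode: MaskMode = "both",
) -> str | None:
    """Read-support decision on an already-determined allele.

    With the default ``mask_mode="both"`` the allele is retained iff
    c_allele >= min_depth AND c_allele/c_all >= min_frac; with "any" one
    condition suffices. Zero total depth always masks.
    """
    if pseudo_allele is None:
        return None
    if c_all <= 0:
        return None
    depth_ok = c_allele >= min_depth
    frac_ok = (c_allele / c_all) >= min_frac
    ok = (depth_ok and frac_ok) if mask_mode == "both" else (depth_ok or frac_ok)
    return pseudo_allele if ok else None


@dataclass
class SupportTable:
    """Vectorized per-site support for one isolate, plus accessors.

    Arrays are per reference contig and cover every site: ``seen_mask`` is a
    4-bit set of distinct contig bases aligned at the site (over all
    length-filtered alignments), ``sel_allele`` the base at the one-to-one
    selected alignment's column (-1 unaligned/deleted, 4 an N contig base),
    ``d_ok`` the d_indel > margin verdict along that alignment.
    """

    reference: SequenceSet
    o2o: OneToOneMap
    piles: dict[str, SitePileup]
    indel_margin: int
    seen_mask: dict[str, np.ndarray] = field(default_factory=dict)
    sel_allele: dict[str, np.ndarray] = field(default_factory=dict)
    d_ok: dict[str, np.ndarray] = field(default_factory=dict)

    def n_allele(self, contig: str) -> np.ndarray:
        return _POPCOUNT4[self.seen_mask[contig]]

    def support_at(self, contig: str, pos: int) -> SiteSupport:
        n_allele = int(self.n_allele(contig)[pos])
        sel = int(self.sel_allele[contig][pos])
        allele = BASES[sel] if (n_allele == 1 and 0 <= sel < 4) else None
        aln = self.o2o.alignment_at(contig, pos)
        d = aln.d_indel(pos) if aln is not None else _INF
        pile = self.piles[contig]
        c_all = pile.c_all(pos)
        c_allele = pile.c_allele(pos, sel) if 0 <= sel < 4 else 0
        return SiteSupport(n_allele, allele, d, c_all, c_allele)


def compute_supports(
    reference: SequenceSet,
    contigs: SequenceSet,
    alignments: list[LocalAlignment],
    records: list[ReadAlignmentRecord],
    min_align_len: int = 0,
    indel_margin: int = 5,
    min_mapq: int = 0,
    deduplicate: bool = True,
) -> SupportTable:
    """Assemble the per-site evidence arrays for one isolate."""
    pool = [a for a in alignments if a.ref_span >= min_align_len]
    o2o = select_one_to_one(pool, 0)
    if deduplicate:
        records = dedupe(records)
    piles = pileup(records, reference, min_mapq=min_mapq)

    qcodes_cache: dict[tuple[str, str], np.ndarray] = {}

    def qcodes(aln: LocalAlignment) -> np.ndarray:
        key = (aln.ctg_id, aln.strand)
        if key not in qcodes_cache:
            codes = encode(contigs[aln.ctg_id])
            qcodes_cache[key] = codes if aln.strand == "+" else revcomp_codes(codes)
        return qcodes_cache[key]

    table = SupportTable(reference, o2o, piles, indel_margin)
    for name, length in reference.lengths().items():
        table.seen_mask[name] = np.zeros(length, dtype=np.uint8)
        table.sel_allele[name] = np.full(length, -1, dtype=np.int8)
        table.d_ok[name] = np.zeros(length, dtype=bool)

    for aln in pool:
        ref_pos, q_pos = aln.aligned_pairs
        bases = qcodes(aln)[q_pos]
        ok = bases < 4
        seen = table.seen_mask[aln.ref_id]
        idx = ref_pos[ok]
        seen[idx] = seen[idx] | np.left_shift(np.uint8(1), bases[ok])

    for aln in o2o.alignments:
        ref_pos, q_pos = aln.aligned_pairs
        bases = qcodes(aln)[q_pos]
        table.sel_allele[aln.ref_id][ref_pos] = bases.astype(np.int8)
        table.d_ok[aln.ref_id][ref_pos] = aln.d_ok_mask(ref_pos, indel_margin)
    return table


def build_pseudogenome(
    reference: SequenceSet,
    contigs: SequenceSet,
    records: list[ReadAlignmentRecord],
    alignments: list[LocalAlignment] | None = None,
    min_depth: int = 10,
    min_frac: float = 0.9,
    indel_margin: int = 5,
    min_align_len: int = 0,
    mask_mode: MaskMode = "both",
    min_mapq: int = 0,
    aligner_kwargs: dict | None = None,
) -> tuple[Pseudogenome, SupportTable]:
    """Build one isolate's pseudogenome: assembly-side allele determination
    composed with read-support masking at every reference site.

    ``alignments`` may carry externally computed contig-reference alignments
    (e.g. reconstructed from a nucmer coords file); otherwise the internal
    aligner runs.
    """
    collide = set(reference.ids) & set(contigs.ids)
    if collide:
        raise ValueError(f"reference/contig id collision: {sorted(collide)}")
    if alignments is None:
        alignments = align_contigs(contigs, reference, **(aligner_kwargs or {}))
    table = compute_supports(
        reference,
        contigs,
        alignments,
        records,
        min_align_len=min_align_len,
        indel_margin=indel_margin,
        min_mapq=min_mapq,
    )
    out: dict[str, np.ndarray] = {}
    for name, length in reference.lengths().items():
        sel = table.sel_allele[name]
        n_allele = table.n_allele(name)
        assembly_ok = (sel >= 0) & (sel < 4) & (n_allele == 1) & table.d_ok[name]

        pile = table.piles[name]
        sel_idx = np.where(assembly_ok, sel, 0).astype(np.int64)
        c_allele = pile.base_counts[sel_idx, np.arange(length)]
        c_all = pile.depth_total
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(c_all > 0, c_allele / np.maximum(c_all, 1), 0.0)
        depth_ok = c_allele >= min_depth
        frac_ok = (c_all > 0) & (frac >= min_frac)
        reads_ok = (
            (depth_ok & frac_ok) if mask_mode == "both" else (depth_ok | frac_ok)
        ) & (c_all > 0)

        codes = np.full(length, 4, dtype=np.uint8)
        keep = assembly_ok & reads_ok
        codes[keep] = sel[keep].astype(np.uint8)
        out[name] = codes
    return Pseudogenome(out), table
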