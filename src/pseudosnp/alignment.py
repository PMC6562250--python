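"""Contig-to-reference alignment and one-to-one region selection.

The aligner is a desk-scale seed-chain-extend scheme: exact k-mer anchors on
both strands are merged along diagonals into maximal exact matches, chained
under a collinear longest-chain criterion, and the gaps between chained
anchors are closed by global edit-distance alignment (edlib). Alignment ends
are extended by an X-drop ungapped walk so substitutions close to a region
boundary are still covered.

`select_one_to_one` then greedily resolves the alignments into a set whose
intervals are pairwise disjoint on both the reference and the contigs, the
structure the pseudogenome construction and the simulator's substitution
placement both rely on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Literal

import edlib
import numpy as np

from ._seq import encode, revcomp
from .io_formats import CoordsInterval, FormatError, SequenceSet

GAP = None  # exposed marker for gap columns in `LocalAlignment.columns`

_XDROP = 12
_MISMATCH_PENALTY = 3
_MAX_CHAINS_PER_STRAND = 50
_LOOKBACK = 96


def _parse_edlib_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ops and ops[-1][0] == ch:
                ops[-1] = (ch, ops[-1][1] + int(num))
            else:
                ops.append((ch, int(num)))
            num = ""
    return ops


def _coalesce(ops: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


@dataclass
class LocalAlignment:
    """One gapped local alignment between a contig and a reference interval.

    Columns are stored as run-length ops over {'=', 'X', 'I', 'D'}: '='/'X'
    consume both sequences, 'I' the contig only, 'D' the reference only.
    For strand '-' the ops (and the internal query frame) follow the
    reverse-complemented contig so that both ref and query offsets increase
    monotonically along the alignment; ``ctg_start``/``ctg_end`` are always
    forward-strand contig coordinates.
    """

    ref_id: str
    ref_start: int
    ref_end: int
    ctg_id: str
    ctg_start: int
    ctg_end: int
    strand: Literal["+", "-"]
    ops: list[tuple[str, int]]
    ctg_len: int

    def __post_init__(self):
        ref_span = sum(n for op, n in self.ops if op in "=XD")
        q_span = sum(n for op, n in self.ops if op in "=XI")
        if ref_span != self.ref_end - self.ref_start:
            raise ValueError("ops inconsistent with reference interval")
        if q_span != self.ctg_end - self.ctg_start:
            raise ValueError("ops inconsistent with contig interval")

    # -- aligned-frame (reverse-complemented if '-') query interval ---------
    @property
    def q_start(self) -> int:
        return self.ctg_start if self.strand == "+" else self.ctg_len - self.ctg_end

    @property
    def q_end(self) -> int:
        return self.ctg_end if self.strand == "+" else self.ctg_len - self.ctg_start

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def identity(self) -> float:
        return self.matches / self.n_columns

    @property
    def score(self) -> float:
        """Greedy-selection score: aligned columns weighted by identity."""
        return self.n_columns * self.identity

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    def q_to_forward(self, q_pos: int) -> int:
        return q_pos if self.strand == "+" else self.ctg_len - 1 - q_pos

    def columns(self) -> Iterator[tuple[int | None, int | None]]:
        """Yield (ref_offset, q_offset) per column; gaps yield ``GAP``."""
        r, q = self.ref_start, self.q_start
        for op, n in self.ops:
            for _ in range(n):
                if op in "=X":
                    yield r, q
                    r += 1
                    q += 1
                elif op == "D":
                    yield r, GAP
                    r += 1
                else:
                    yield GAP, q
                    q += 1

    @cached_property
    def _ref_map(self) -> np.ndarray:
        """Per reference offset in [ref_start, ref_end): q offset, or -1 at
        columns where the contig is gapped (deleted in the isolate)."""
        out = np.full(self.ref_span, -1, dtype=np.int64)
        r, q = 0, self.q_start
        for op, n in self.ops:
            if op in "=X":
                out[r : r + n] = np.arange(q, q + n)
                r += n
                q += n
            elif op == "D":
                r += n
            else:
                q += n
        return out

    @cached_property
    def aligned_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(ref positions, q positions) of all '='/'X' columns."""
        m = self._ref_map
        keep = m >= 0
        return np.flatnonzero(keep) + self.ref_start, m[keep]

    @cached_property
    def indel_coords(self) -> np.ndarray:
        """Sorted doubled reference coordinates of gap columns.

        A contig-gap ('D') column at reference position r contributes 2r; a
        contig-insertion ('I') run lying between reference positions r-1 and
        r contributes 2r-1. Distances measured on this doubled axis make
        d_indel well defined at and next to either gap type.
        """
        events: list[np.ndarray] = []
        r = self.ref_start
        for op, n in self.ops:
            if op == "D":
                events.append(np.arange(2 * r, 2 * (r + n), 2))
                r += n
            elif op == "I":
                events.append(np.array([2 * r - 1]))
            else:
                r += n
        if not events:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(events))

    def d_indel(self, ref_pos: int) -> float:
        """Distance (bp) from a reference site to the nearest indel column
        of this alignment; inf when the alignment is gap-free."""
        ev = self.indel_coords
        if ev.size == 0:
            return float("inf")
        i = np.searchsorted(ev, 2 * ref_pos)
        cands = []
        if i < ev.size:
            cands.append(ev[i] - 2 * ref_pos)
        if i > 0:
            cands.append(2 * ref_pos - ev[i - 1])
        return int(np.ceil(min(cands) / 2))

    def d_ok_mask(self, ref_positions: np.ndarray, margin: int) -> np.ndarray:
        """Vectorized d_indel > margin test for reference positions."""
        ev = self.indel_coords
        if ev.size == 0:
            return np.ones(len(ref_positions), dtype=bool)
        doubled = 2 * ref_positions
        i = np.searchsorted(ev, doubled)
        right = np.where(i < ev.size, ev[np.minimum(i, ev.size - 1)] - doubled, 2**62)
        left = np.where(i > 0, doubled - ev[np.maximum(i - 1, 0)], 2**62)
        return np.minimum(left, right) > 2 * margin

    def liftover_ref(self, ref_pos: int) -> int | None:
        """Reference position -> forward contig position (None in a gap)."""
        if not (self.ref_start <= ref_pos < self.ref_end):
            return None
        q = int(self._ref_map[ref_pos - self.ref_start])
        return None if q < 0 else self.q_to_forward(q)

    @cached_property
    def _q_map(self) -> np.ndarray:
        out = np.full(self.q_end - self.q_start, -1, dtype=np.int64)
        r, q = self.ref_start, 0
        for op, n in self.ops:
            if op in "=X":
                out[q : q + n] = np.arange(r, r + n)
                r += n
                q += n
            elif op == "D":
                r += n
            else:
                q += n
        return out

    def liftover_ctg(self, ctg_pos: int) -> int | None:
        """Forward contig position -> reference position (None in a gap)."""
        if not (self.ctg_start <= ctg_pos < self.ctg_end):
            return None
        q = ctg_pos if self.strand == "+" else self.ctg_len - 1 - ctg_pos
        r = int(self._q_map[q - self.q_start])
        return None if r < 0 else r


# ---------------------------------------------------------------------------
# anchor collection and chaining
# ---------------------------------------------------------------------------

class _RefIndex:
    """k-mer index over the concatenated reference (contigs separated by a
    run of N so no window spans two contigs)."""

    def __init__(self, reference: SequenceSet, k: int, max_occ: int):
        self.k = k
        self.contig_ids = reference.ids
        parts = []
        offsets = []
        pos = 0
        sep = "N" * k
        for i, (name, seq) in enumerate(reference):
            if i > 0:
                parts.append(sep)
                pos += k
            offsets.append(pos)
            parts.append(seq)
            pos += len(seq)
        self.concat = "".join(parts)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.contig_lengths = np.array(
            [len(s) for _, s in reference], dtype=np.int64
        )
        index: dict[str, list[int]] = {}
        concat = self.concat
        for i in _valid_starts(concat, k):
            index.setdefault(concat[i : i + k], []).append(i)
        self.index = {
            kmer: positions
            for kmer, positions in index.items()
            if len(positions) <= max_occ
        }

    def contig_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def to_local(self, gpos: int) -> tuple[str, int]:
        ci = self.contig_of(gpos)
        return self.contig_ids[ci], int(gpos - self.offsets[ci])

    def contig_bounds(self, ci: int) -> tuple[int, int]:
        start = int(self.offsets[ci])
        return start, start + int(self.contig_lengths[ci])


def _valid_starts(seq: str, k: int) -> np.ndarray:
    """Start offsets of k-windows containing no N."""
    codes = encode(seq)
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    bad = np.cumsum(np.concatenate(([0], (codes == 4).astype(np.int64))))
    window_n = bad[k:] - bad[:-k]
    return np.flatnonzero(window_n == 0)


def _collect_anchors(q: str, index: _RefIndex) -> np.ndarray:
    """Merged maximal exact matches as an (n, 3) array of (q0, r0, length);
    r0 is in concatenated-reference coordinates."""
    k = index.k
    table = index.index
    qpos: list[int] = []
    rpos: list[int] = []
    for i in _valid_starts(q, k):
        hit = table.get(q[i : i + k])
        if hit:
            for r in hit:
                qpos.append(i)
                rpos.append(r)
    if not qpos:
        return np.empty((0, 3), dtype=np.int64)
    qa = np.asarray(qpos, dtype=np.int64)
    ra = np.asarray(rpos, dtype=np.int64)
    diag = ra - qa
    order = np.lexsort((qa, diag))
    qa, ra, diag = qa[order], ra[order], diag[order]
    # merge hits on the same diagonal whose starts are <= k apart: the union
    # of overlapping/adjacent exact windows is itself exact
    new_run = np.concatenate(
        ([True], (np.diff(diag) != 0) | (np.diff(qa) > k))
    )
    starts = np.flatnonzero(new_run)
    ends = np.concatenate((starts[1:], [len(qa)]))
    q0 = qa[starts]
    r0 = ra[starts]
    length = qa[ends - 1] - q0 + k
    return np.column_stack((q0, r0, length))


def _chain_anchors(
    anchors: np.ndarray,
    index: _RefIndex,
    max_gap_ctg: int,
    max_gap_ref: int,
    min_anchor_chain: int,
    min_chain_bases: int,
    k: int,
) -> list[np.ndarray]:
    """Extract collinear chains by repeated best-chain dynamic programming."""
    n = len(anchors)
    if n == 0:
        return []
    order = np.argsort(anchors[:, 0], kind="stable")
    q0 = anchors[order, 0].tolist()
    r0 = anchors[order, 1].tolist()
    ln = anchors[order, 2].tolist()
    qe = [a + b for a, b in zip(q0, ln)]
    re_ = [a + b for a, b in zip(r0, ln)]
    ci = [index.contig_of(r) for r in r0]
    used = [False] * n
    chains: list[np.ndarray] = []
    overlap = k - 1
    while len(chains) < _MAX_CHAINS_PER_STRAND:
        dp = [0.0] * n
        parent = [-1] * n
        count = [1] * n
        best_i, best_score = -1, -1.0
        for i in range(n):
            if used[i]:
                continue
            score_i = float(ln[i])
            dp[i] = score_i
            lo = max(0, i - _LOOKBACK)
            qi, ri, c = q0[i], r0[i], ci[i]
            for j in range(i - 1, lo - 1, -1):
                if used[j] or ci[j] != c:
                    continue
                qg = qi - qe[j]
                rg = ri - re_[j]
                if qg < -overlap or rg < -overlap or qg > max_gap_ctg or rg > max_gap_ref:
                    continue
                cand = dp[j] + score_i - 0.05 * max(qg, rg, 0)
                if cand > dp[i]:
                    dp[i] = cand
                    parent[i] = j
                    count[i] = count[j] + 1
            if dp[i] > best_score:
                best_score, best_i = dp[i], i
        if best_i < 0 or best_score < min_chain_bases:
            break
        chain = []
        i = best_i
        while i >= 0:
            chain.append(i)
            used[i] = True
            i = parent[i]
        chain.reverse()
        if len(chain) >= min_anchor_chain and sum(ln[i] for i in chain) >= min_chain_bases:
            chains.append(
                np.array(
                    [[q0[i], r0[i], ln[i]] for i in chain], dtype=np.int64
                )
            )
    return chains


def _xdrop_extend(
    q: str,
    ref: str,
    qpos: int,
    rpos: int,
    step: int,
    q_stop: int,
    r_stop: int,
    max_len: int = 500,
) -> list[tuple[str, int]]:
    """Ungapped X-drop extension from (qpos, rpos) moving by ``step``.

    Returns ops ('='/'X') for the best-scoring extension, which by
    construction ends on a match; the walk is capped at ``max_len`` bases.
    Ops are returned in walk order.
    """
    score, best, best_len, i = 0, 0, 0, 0
    qi, ri = qpos, rpos
    while qi != q_stop and ri != r_stop and i < max_len:
        if q[qi] == ref[ri] and q[qi] != "N":
            score += 1
        else:
            score -= _MISMATCH_PENALTY
        i += 1
        if score > best:
            best, best_len = score, i
        if score < best - _XDROP:
            break
        qi += step
        ri += step
    ops = []
    for j in range(best_len):
        a = q[qpos + step * j]
        b = ref[rpos + step * j]
        ops.append(("=" if (a == b and a != "N") else "X", 1))
    return _coalesce(ops)


def _canonicalize_ops(
    ops: list[tuple[str, int]],
    q: str,
    ref: str,
    q_start: int,
    r_start: int,
    anchor_len: int = 6,
    max_span: int = 30,
) -> list[tuple[str, int]]:
    """Replace gap-pair artifacts with mismatch columns.

    Unit-cost edit alignment can represent two adjacent substitutions such
    as ref "TC" / contig "CT" as a deletion plus an insertion at the same
    cost as two mismatches; the gapped form then wrongly triggers the
    indel-distance mask. Between anchoring match runs (>= ``anchor_len``),
    any short segment whose insertions and deletions balance exactly is
    rewritten as a direct base-to-base comparison - but only when that does
    not increase the edit cost, so genuine nearby indel pairs are left
    untouched.
    """
    out: list[tuple[str, int]] = []
    seg: list[tuple[str, int]] = []
    qi, ri = q_start, r_start
    seg_q, seg_r = qi, ri

    def flush():
        nonlocal seg, seg_q, seg_r
        if not seg:
            return
        ins = sum(n for op, n in seg if op == "I")
        dels = sum(n for op, n in seg if op == "D")
        r_span = sum(n for op, n in seg if op in "=XD")
        if ins and ins == dels and r_span <= max_span:
            cost = sum(n for op, n in seg if op in "XID")
            q_seg = q[seg_q : seg_q + r_span]
            r_seg = ref[seg_r : seg_r + r_span]
            direct = sum(1 for a, b in zip(q_seg, r_seg) if a != b or a == "N")
            if direct <= cost:
                out.extend(
                    ("=" if (a == b and a != "N") else "X", 1)
                    for a, b in zip(q_seg, r_seg)
                )
                seg = []
                return
        out.extend(seg)
        seg = []

    for op, n in ops:
        if op == "=" and n >= anchor_len:
            flush()
            out.append((op, n))
            qi += n
            ri += n
            seg_q, seg_r = qi, ri
        else:
            seg.append((op, n))
            if op in "=XI":
                qi += n
            if op in "=XD":
                ri += n
    flush()
    return _coalesce(out)


def _fill_gap(q_seg: str, r_seg: str) -> list[tuple[str, int]]:
    if not q_seg and not r_seg:
        return []
    if not q_seg:
        return [("D", len(r_seg))]
    if not r_seg:
        return [("I", len(q_seg))]
    res = edlib.align(q_seg, r_seg, mode="NW", task="path")
    return _parse_edlib_cigar(res["cigar"])


def _stitch_chain(
    q: str,
    index: _RefIndex,
    chain: np.ndarray,
) -> tuple[list[tuple[str, int]], int, int, int, int] | None:
    """Turn a chain of anchors into ops plus aligned-frame intervals."""
    concat = index.concat
    ci = index.contig_of(int(chain[0, 1]))
    c_lo, c_hi = index.contig_bounds(ci)
    ops: list[tuple[str, int]] = []
    cur_q = cur_r = None
    start_q = start_r = None
    for qs, rs, ln in chain:
        qs, rs, ln = int(qs), int(rs), int(ln)
        if cur_q is None:
            start_q, start_r = qs, rs
            ops.append(("=", ln))
        else:
            trim = max(cur_q - qs, cur_r - rs, 0)
            qs, rs, ln = qs + trim, rs + trim, ln - trim
            if ln <= 0:
                continue
            ops.extend(_fill_gap(q[cur_q:qs], concat[cur_r:rs]))
            ops.append(("=", ln))
        cur_q, cur_r = qs + ln, rs + ln
    if cur_q is None:
        return None
    left = _xdrop_extend(q, concat, start_q - 1, start_r - 1, -1, -1, c_lo - 1)
    if left:
        n_left = sum(n for _, n in left)
        start_q -= n_left
        start_r -= n_left
        ops = list(reversed(left)) + ops
    right = _xdrop_extend(q, concat, cur_q, cur_r, +1, len(q), c_hi)
    if right:
        cur_q += sum(n for _, n in right)
        cur_r += sum(n for _, n in right)
        ops = ops + right
    ops = _canonicalize_ops(_coalesce(ops), q, concat, start_q, start_r)
    return ops, start_q, cur_q, start_r, cur_r


def align_contigs(
    contigs: SequenceSet,
    reference: SequenceSet,
    k: int = 17,
    min_anchor_chain: int = 1,
    max_occ: int = 8,
    max_gap_ctg: int = 300,
    max_gap_ref: int = 6000,
    min_chain_bases: int = 100,
) -> list[LocalAlignment]:
    """Align contigs to a reference with exact anchors, collinear chaining
    and edit-distance gap closing, on both strands.

    The chain-gap limits are deliberately asymmetric: the contig-side limit
    only needs to bridge small isolate indels and anchor deserts, while the
    larger reference-side limit lets a chain jump over reference-only
    content (an inserted segment or a tandem duplicate copy) as a clean
    deletion, instead of letting a lower-identity homology-confused chain
    win. Returns gapped local alignments (possibly several per contig, e.g.
    on either side of a structural difference, or secondary placements
    against duplicated reference copies). No alignment found yields an
    empty list.
    """
    if k < 11:
        raise ValueError("anchor length k must be >= 11")
    # the index depends only on (reference, k, max_occ); reuse it across the
    # per-isolate calls of one pipeline run
    cache = getattr(reference, "_kmer_index_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(reference, "_kmer_index_cache", cache)
    key = (k, max_occ)
    index = cache.get(key)
    if index is None:
        index = cache[key] = _RefIndex(reference, k, max_occ)
    out: list[LocalAlignment] = []
    for ctg_id, seq in contigs:
        ctg_len = len(seq)
        for strand in "+-":
            q = seq if strand == "+" else revcomp(seq)
            anchors = _collect_anchors(q, index)
            chains = _chain_anchors(
                anchors, index, max_gap_ctg, max_gap_ref,
                min_anchor_chain, min_chain_bases, k,
            )
            for chain in chains:
                st = _stitch_chain(q, index, chain)
                if st is None:
                    continue
                ops, qs, qe, rs, re_ = st
                ref_id, local_rs = index.to_local(rs)
                if strand == "+":
                    cs, ce = qs, qe
                else:
                    cs, ce = ctg_len - qe, ctg_len - qs
                out.append(
                    LocalAlignment(
                        ref_id=ref_id,
                        ref_start=local_rs,
                        ref_end=local_rs + (re_ - rs),
                        ctg_id=ctg_id,
                        ctg_start=cs,
                        ctg_end=ce,
                        strand=strand,
                        ops=ops,
                        ctg_len=ctg_len,
                    )
                )
    return out


def alignments_from_coords(
    coords: list[CoordsInterval],
    contigs: SequenceSet,
    reference: SequenceSet,
) -> list[LocalAlignment]:
    """Reconstruct gapped alignments for externally computed (nucmer-style)
    coordinate intervals by globally aligning each interval pair."""
    out = []
    for c in coords:
        if c.ref_id not in reference:
            raise FormatError(f"coords reference {c.ref_id!r} not in reference set")
        if c.ctg_id not in contigs:
            raise FormatError(f"coords contig {c.ctg_id!r} not in contig set")
        ref_seg = reference[c.ref_id][c.ref_start : c.ref_end]
        ctg_seq = contigs[c.ctg_id]
        seg = ctg_seq[c.ctg_start : c.ctg_end]
        if c.strand == "-":
            seg = revcomp(seg)
        ops = _canonicalize_ops(_fill_gap(seg, ref_seg), seg, ref_seg, 0, 0)
        out.append(
            LocalAlignment(
                ref_id=c.ref_id,
                ref_start=c.ref_start,
                ref_end=c.ref_end,
                ctg_id=c.ctg_id,
                ctg_start=c.ctg_start,
                ctg_end=c.ctg_end,
                strand=c.strand,
                ops=ops,
                ctg_len=len(ctg_seq),
            )
        )
    return out


# ---------------------------------------------------------------------------
# one-to-one selection and liftover
# ---------------------------------------------------------------------------

@dataclass
class OneToOneMap:
    """Alignments of one isolate whose intervals are pairwise disjoint on
    both the reference and the contigs."""

    alignments: list[LocalAlignment] = field(default_factory=list)

    def __post_init__(self):
        self._by_ref: dict[str, tuple[np.ndarray, np.ndarray, list[LocalAlignment]]] = {}
        self._by_ctg: dict[str, tuple[np.ndarray, np.ndarray, list[LocalAlignment]]] = {}
        for key, get_lo, get_hi, store in (
            ("ref", lambda a: a.ref_start, lambda a: a.ref_end, self._by_ref),
            ("ctg", lambda a: a.ctg_start, lambda a: a.ctg_end, self._by_ctg),
        ):
            groups: dict[str, list[LocalAlignment]] = {}
            for a in self.alignments:
                groups.setdefault(a.ref_id if key == "ref" else a.ctg_id, []).append(a)
            for name, alns in groups.items():
                alns.sort(key=get_lo)
                starts = np.array([get_lo(a) for a in alns])
                ends = np.array([get_hi(a) for a in alns])
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"overlapping intervals on {key} {name!r}")
                store[name] = (starts, ends, alns)

    def _lookup(self, table, seq_id: str, pos: int) -> LocalAlignment | None:
        entry = table.get(seq_id)
        if entry is None:
            return None
        starts, ends, alns = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return alns[i]
        return None

    def alignment_at(self, ref_id: str, pos: int) -> LocalAlignment | None:
        return self._lookup(self._by_ref, ref_id, pos)

    def alignment_at_ctg(self, ctg_id: str, pos: int) -> LocalAlignment | None:
        return self._lookup(self._by_ctg, ctg_id, pos)


def _slice_ops_to_ref(
    aln: LocalAlignment, ref_lo: int, ref_hi: int
) -> LocalAlignment | None:
    """Restrict an alignment to the reference window [ref_lo, ref_hi)."""
    new_ops: list[tuple[str, int]] = []
    r, q = aln.ref_start, aln.q_start
    new_q_start = None
    for op, n in aln.ops:
        if op in "=XD":
            lo = max(r, ref_lo)
            hi = min(r + n, ref_hi)
            if hi > lo:
                new_ops.append((op, hi - lo))
                if op != "D" and new_q_start is None:
                    new_q_start = q + (lo - r)
        elif op == "I" and ref_lo < r <= ref_hi and new_q_start is not None:
            new_ops.append((op, n))
        if op in "=XD":
            r += n
        if op in "=XI":
            q += n
    # strip boundary gaps: the window must start and end on aligned columns
    while new_ops and new_ops[0][0] in "ID":
        if new_ops[0][0] == "I":
            new_q_start += new_ops[0][1]
        new_ops.pop(0)
    while new_ops and new_ops[-1][0] in "ID":
        new_ops.pop()
    if not new_ops or new_q_start is None:
        return None
    ref_span = sum(n for op, n in new_ops if op in "=XD")
    q_span = sum(n for op, n in new_ops if op in "=XI")
    new_ref_start = max(aln.ref_start, ref_lo)
    # leading D ops shift the first aligned reference column rightwards
    r, shift = aln.ref_start, 0
    for op, n in aln.ops:
        if op in "=XD":
            lo = max(r, ref_lo)
            hi = min(r + n, ref_hi)
            if hi > lo:
                if op == "D":
                    shift += hi - lo
                    r += n
                    continue
                break
            r += n
    new_ref_start += shift
    if aln.strand == "+":
        cs, ce = new_q_start, new_q_start + q_span
    else:
        cs, ce = aln.ctg_len - (new_q_start + q_span), aln.ctg_len - new_q_start
    return LocalAlignment(
        ref_id=aln.ref_id,
        ref_start=new_ref_start,
        ref_end=new_ref_start + ref_span,
        ctg_id=aln.ctg_id,
        ctg_start=cs,
        ctg_end=ce,
        strand=aln.strand,
        ops=_coalesce(new_ops),
        ctg_len=aln.ctg_len,
    )


def select_one_to_one(
    alignments: list[LocalAlignment],
    min_align_len: int = 0,
    boundary_slop: int = 20,
) -> OneToOneMap:
    """Greedy one-to-one filtering of local alignments.

    Alignments with reference span below ``min_align_len`` are discarded
    first; the rest are taken in order of descending score (ties: smaller
    ref_start, then contig id), each kept only if it conflicts with no
    previously retained alignment on either the reference or the contig
    side. Substantial or interior overlaps reject the whole alignment (so a
    duplicated region is represented by its single best placement), but a
    boundary overlap of at most ``boundary_slop`` bp in total - the
    unavoidable end-ambiguity where two adjacent alignments meet at a
    structural breakpoint - is trimmed off the lower-scoring alignment
    instead of discarding it wholesale.
    """
    pool = [a for a in alignments if a.ref_span >= min_align_len]
    pool.sort(key=lambda a: (-a.score, a.ref_id, a.ref_start, a.ctg_id))
    kept: list[LocalAlignment] = []
    ref_iv: dict[str, list[tuple[int, int]]] = {}
    ctg_iv: dict[str, list[tuple[int, int]]] = {}

    def shrink(table, key, lo, hi):
        """Shrink [lo, hi) past boundary overlaps; None on interior overlap."""
        changed = True
        while changed and lo < hi:
            changed = False
            for s, e in table.get(key, ()):
                if e <= lo or hi <= s:
                    continue
                if s <= lo:
                    lo = e
                    changed = True
                elif hi <= e:
                    hi = s
                    changed = True
                else:  # kept interval strictly inside the candidate
                    return None
        return (lo, hi) if lo < hi else None

    for a in pool:
        ref_win = shrink(ref_iv, a.ref_id, a.ref_start, a.ref_end)
        ctg_win = shrink(ctg_iv, a.ctg_id, a.ctg_start, a.ctg_end)
        if ref_win is None or ctg_win is None:
            continue
        trimmed = (a.ref_span - (ref_win[1] - ref_win[0])) + (
            (a.ctg_end - a.ctg_start) - (ctg_win[1] - ctg_win[0])
        )
        if trimmed > boundary_slop:
            continue
        cand = a
        if trimmed:
            cand = _slice_ops_to_ref(a, *ref_win)
            if cand is not None and (
                cand.ctg_start < ctg_win[0] or cand.ctg_end > ctg_win[1]
            ):
                # contig-side overlap not resolved by the reference trim:
                # map the contig window through the alignment and re-trim
                lo = cand.liftover_ctg(ctg_win[0])
                hi = cand.liftover_ctg(ctg_win[1] - 1)
                if lo is None or hi is None:
                    continue
                lo, hi = min(lo, hi), max(lo, hi) + 1
                cand = _slice_ops_to_ref(cand, lo, hi)
            if cand is None:
                continue
            if (
                shrink(ref_iv, cand.ref_id, cand.ref_start, cand.ref_end)
                != (cand.ref_start, cand.ref_end)
            ) or (
                shrink(ctg_iv, cand.ctg_id, cand.ctg_start, cand.ctg_end)
                != (cand.ctg_start, cand.ctg_end)
            ):
                continue
        kept.append(cand)
        ref_iv.setdefault(cand.ref_id, []).append((cand.ref_start, cand.ref_end))
        ctg_iv.setdefault(cand.ctg_id, []).append((cand.ctg_start, cand.ctg_end))
    return OneToOneMap(kept)


def liftover(
    obj: OneToOneMap | LocalAlignment,
    from_frame: Literal["ref", "ctg"],
    pos: int,
    seq_id: str | None = None,
):
    """Map a position through an alignment (or a one-to-one map).

    For a single alignment, returns the partner coordinate or None when the
    position falls in a gap column or outside the alignment. For a map,
    ``seq_id`` selects the sequence and the result is ``(partner_id, pos)``
    or None.
    """
    if from_frame not in ("ref", "ctg"):
        raise ValueError("from_frame must be 'ref' or 'ctg'")
    if isinstance(obj, LocalAlignment):
        return obj.liftover_ref(pos) if from_frame == "ref" else obj.liftover_ctg(pos)
    if seq_id is None:
        raise ValueError("seq_id required when lifting through a OneToOneMap")
    aln = (
        obj.alignment_at(seq_id, pos)
        if from_frame == "ref"
        else obj.alignment_at_ctg(seq_id, pos)
    )
    if aln is None:
        return None
    if from_frame == "ref":
        q = aln.liftover_ref(pos)
        return None if q is None else (aln.ctg_id, q)
    r = aln.liftover_ctg(pos)
    return None if r is None else (aln.ref_id, r)
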