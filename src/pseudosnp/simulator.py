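"""Synthetic benchmark construction for the SNP-calling pipeline.

The generator emulates the situation the pipeline targets: a reference
genome and a closely related "root" genome (97-99.9% identity in their
one-to-one regions, plus structural differences: duplications, deletions,
insertions), ten virtual isolates evolved from the root along a random
bifurcating tree with on average ~10 substitutions, ~1 insertion and ~0.25
deletions per edge, substitutions relocated into one-to-one aligned regions
>= 1 kbp so every true SNP has a well-defined reference coordinate,
paired-end reads with substitution sequencing errors, and fragmented
"assembled" contigs per isolate.

Reads are emitted together with truth placements in the reference frame
(via the composed isolate->root->reference coordinate map), which allows
mapper-free pileups. All randomness flows from one seed through named
substreams (pair, tree, variants, relocation, reads, fragmentation), so a
TruthSet is byte-reproducible given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import decode, revcomp
from .alignment import OneToOneMap, align_contigs, select_one_to_one
from .io_formats import ReadAlignmentRecord, SequenceSet

_SUBSTREAMS = ("pair", "tree", "variants", "relocation", "reads", "fragmentation")
_MAX_INTERNAL_DELETION = 100  # ref-frame jump beyond which a read is clipped
_MAX_INTERNAL_INSERTION = 50  # unmappable interior run a read may carry as 'I'


@dataclass
class SVSpec:
    """Structural differences written into the reference relative to root."""

    n_duplications: int = 2
    dup_len: tuple[int, int] = (1000, 5000)
    dup_extra_divergence: float = 0.03
    tandem_prob: float = 0.5
    n_deletions: int = 2
    del_len: tuple[int, int] = (1000, 5000)
    n_insertions: int = 2
    ins_len: tuple[int, int] = (1000, 5000)


@dataclass
class SimParams:
    genome_size: int = 200_000
    identity: float = 0.99
    sv: SVSpec = field(default_factory=SVSpec)
    n_isolates: int = 10
    sub_mean: float = 10.0
    ins_mean: float = 1.0
    del_mean: float = 0.25
    indel_len: tuple[int, int] = (1, 10)
    read_len: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 40.0
    coverage: float = 20.0
    error_rate: float = 0.005
    n_breaks: int = 15
    min_contig_len: int = 1000
    end_trim: int = 0
    min_region_len: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0.9 < self.identity <= 1.0):
            raise ValueError("identity must lie in (0.9, 1.0]")
        if self.n_isolates < 2:
            raise ValueError("need at least 2 isolates")
        if self.read_len > self.frag_mean:
            raise ValueError("read length exceeds mean fragment length")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# reference-root pair
# ---------------------------------------------------------------------------

@dataclass
class RefRootPair:
    reference: SequenceSet  # single contig 'ref'
    root: SequenceSet  # single contig 'root'
    root2ref: np.ndarray  # per root position: ref position, -1 if absent in ref
    ref2root: np.ndarray

    @property
    def root_codes(self) -> np.ndarray:
        from ._seq import encode

        return encode(self.root["root"])


def make_reference_root_pair(
    params: SimParams, rng: np.random.Generator | None = None
) -> RefRootPair:
    """Generate a root genome and a reference diverged from it.

    The reference carries substitutions at rate (1 - identity) everywhere
    plus the configured structural differences. Duplication copies receive
    `dup_extra_divergence` additional substitutions against the root segment
    so the original copy stays every isolate's unambiguous best alignment
    target (as for an aged paralog).
    """
    rng = rng or _streams(params.seed)["pair"]
    L = params.genome_size
    sv = params.sv
    root = rng.integers(0, 4, size=L).astype(np.uint8)
    core = _mutate(root, 1.0 - params.identity, rng)

    # sample mutually disjoint root intervals / anchor points for SV events
    reserved: list[tuple[int, int]] = []

    def grab_interval(lo_len: int, hi_len: int) -> tuple[int, int]:
        for _ in range(1000):
            n = int(rng.integers(lo_len, hi_len + 1))
            if n >= L:
                break
            s = int(rng.integers(0, L - n))
            if all(e <= s or s + n <= b for b, e in reserved):
                reserved.append((s, s + n))
                return s, s + n
        raise ValueError("could not place structural events in the genome")

    def grab_point() -> int:
        for _ in range(1000):
            p = int(rng.integers(1, L - 1))
            if all(p < b or p >= e for b, e in reserved):
                reserved.append((p, p + 1))
                return p
        raise ValueError("could not place structural events in the genome")

    deletions = [grab_interval(*sv.del_len) for _ in range(sv.n_deletions)]
    dup_sources = [grab_interval(*sv.dup_len) for _ in range(sv.n_duplications)]
    if sum(e - s for s, e in deletions + dup_sources) >= L:
        raise ValueError("total structural-event length exceeds the genome size")

    events: list[tuple[int, str, object]] = [(a, "del", b) for a, b in deletions]
    for sa, sb in dup_sources:
        extra = (1.0 - params.identity) + sv.dup_extra_divergence
        copy = _mutate(root[sa:sb], extra, rng)
        target = sb if rng.random() < sv.tandem_prob else grab_point()
        events.append((target, "dup", copy))
    for _ in range(sv.n_insertions):
        n = int(rng.integers(sv.ins_len[0], sv.ins_len[1] + 1))
        events.append((grab_point(), "ins", rng.integers(0, 4, size=n).astype(np.uint8)))
    events.sort(key=lambda e: e[0])

    pieces: list[np.ndarray] = []
    root2ref = np.full(L, -1, dtype=np.int64)
    cur = 0
    ref_pos = 0
    for pos, kind, payload in events:
        if pos > cur:
            seg = core[cur:pos]
            pieces.append(seg)
            root2ref[cur:pos] = ref_pos + np.arange(pos - cur)
            ref_pos += pos - cur
            cur = pos
        if kind == "del":
            cur = int(payload)  # skip the deleted root interval
        else:  # dup copy or novel insertion, no root correspondence
            seg = np.asarray(payload)
            pieces.append(seg)
            ref_pos += len(seg)
    if cur < L:
        pieces.append(core[cur:])
        root2ref[cur:] = ref_pos + np.arange(L - cur)
    ref_codes = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    ref2root = np.full(len(ref_codes), -1, dtype=np.int64)
    valid = np.flatnonzero(root2ref >= 0)
    ref2root[root2ref[valid]] = valid
    return RefRootPair(
        reference=SequenceSet([("ref", decode(ref_codes.astype(np.uint8)))]),
        root=SequenceSet([("root", decode(root))]),
        root2ref=root2ref,
        ref2root=ref2root,
    )


# ---------------------------------------------------------------------------
# tree and isolate evolution
# ---------------------------------------------------------------------------

@dataclass
class EdgeVariants:
    """Variant events on one tree edge, in root coordinates."""

    parent: str
    child: str
    sub_pos: np.ndarray  # root positions
    sub_shift: np.ndarray  # 1..3 added to the parent's base, mod 4
    insertions: list[tuple[int, np.ndarray]]  # (anchor root pos, inserted codes)
    deletions: list[tuple[int, int]]  # root intervals

    @property
    def n_sub(self) -> int:
        return len(self.sub_pos)

    @property
    def n_ins(self) -> int:
        return len(self.insertions)

    @property
    def n_del(self) -> int:
        return len(self.deletions)


@dataclass
class IsolateTruth:
    name: str
    codes: np.ndarray  # materialized genome
    iso2root: np.ndarray  # -1 for inserted bases
    root2iso: np.ndarray  # -1 for deleted root positions
    root_alleles: np.ndarray  # allele per root position, before deletions
    deleted: np.ndarray  # bool per root position

    @property
    def sequence(self) -> str:
        return decode(self.codes)


@dataclass
class Evolution:
    tree_newick: str
    edges: list[EdgeVariants]
    leaf_paths: dict[str, list[int]]  # leaf name -> indices into `edges`
    isolates: dict[str, IsolateTruth]


def _random_tree(n_leaves: int, rng: np.random.Generator) -> tuple[str, list[tuple[str, str]], dict[str, list[int]]]:
    """Random bifurcating tree over leaves A1..An by successive random joins.

    Returns (newick, edge list (parent, child) in creation order, and per
    leaf the list of edge indices on the root-to-leaf path).
    """
    leaves = [f"A{i + 1}" for i in range(n_leaves)]
    lineages = list(leaves)
    children: dict[str, tuple[str, str]] = {}
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        counter += 1
        node = f"N{counter}"
        a, b = lineages[i], lineages[j]
        children[node] = (a, b)
        lineages = [x for t, x in enumerate(lineages) if t not in (i, j)] + [node]
    root = lineages[0]
    edges: list[tuple[str, str]] = []

    def walk(node: str):
        if node in children:
            for ch in children[node]:
                edges.append((node, ch))
                walk(ch)

    walk(root)
    edge_index = {e: i for i, e in enumerate(edges)}
    paths: dict[str, list[int]] = {}

    def collect(node: str, path: list[int]):
        if node in children:
            for ch in children[node]:
                collect(ch, path + [edge_index[(node, ch)]])
        else:
            paths[node] = path

    collect(root, [])

    def newick(node: str) -> str:
        if node in children:
            a, b = children[node]
            return f"({newick(a)},{newick(b)}){node}"
        return node

    return newick(root) + ";", edges, paths


def _draw_edge_events(
    parent: str,
    child: str,
    root_len: int,
    params: SimParams,
    rng: np.random.Generator,
) -> EdgeVariants:
    n_sub = int(rng.poisson(params.sub_mean))
    n_ins = int(rng.poisson(params.ins_mean))
    n_del = int(rng.poisson(params.del_mean))
    sub_pos = rng.choice(root_len, size=min(n_sub, root_len), replace=False)
    sub_shift = rng.integers(1, 4, size=len(sub_pos))
    lo, hi = params.indel_len
    insertions = []
    for _ in range(n_ins):
        n = int(rng.integers(lo, hi + 1))
        insertions.append(
            (int(rng.integers(0, root_len)), rng.integers(0, 4, size=n).astype(np.uint8))
        )
    deletions = []
    for _ in range(n_del):
        n = int(rng.integers(lo, hi + 1))
        a = int(rng.integers(0, max(root_len - n, 1)))
        deletions.append((a, a + n))
    return EdgeVariants(parent, child, np.sort(sub_pos), sub_shift[np.argsort(sub_pos)],
                        insertions, deletions)


def _materialize(
    name: str,
    root_codes: np.ndarray,
    path_edges: list[EdgeVariants],
) -> IsolateTruth:
    L = len(root_codes)
    shift = np.zeros(L, dtype=np.int64)
    deleted = np.zeros(L, dtype=bool)
    insertions: list[tuple[int, np.ndarray]] = []
    for edge in path_edges:
        if edge.n_sub:
            np.add.at(shift, edge.sub_pos, edge.sub_shift)
        for a, b in edge.deletions:
            deleted[a:b] = True
        insertions.extend(edge.insertions)
    root_alleles = ((root_codes.astype(np.int64) + shift) % 4).astype(np.uint8)
    insertions = [(p, seq) for p, seq in insertions if not deleted[p]]
    insertions.sort(key=lambda t: t[0])

    kept = np.flatnonzero(~deleted)
    base = root_alleles[kept]
    cut = np.searchsorted(kept, [p for p, _ in insertions], side="right")
    seg_codes: list[np.ndarray] = []
    seg_roots: list[np.ndarray] = []
    prev = 0
    for (p, seq), c in zip(insertions, cut):
        seg_codes.append(base[prev:c])
        seg_roots.append(kept[prev:c])
        seg_codes.append(seq)
        seg_roots.append(np.full(len(seq), -1, dtype=np.int64))
        prev = c
    seg_codes.append(base[prev:])
    seg_roots.append(kept[prev:])
    codes = np.concatenate(seg_codes).astype(np.uint8)
    iso2root = np.concatenate(seg_roots)
    root2iso = np.full(L, -1, dtype=np.int64)
    src = np.flatnonzero(iso2root >= 0)
    root2iso[iso2root[src]] = src
    return IsolateTruth(name, codes, iso2root, root2iso, root_alleles, deleted)


def evolve_isolates(
    root: SequenceSet | np.ndarray,
    params: SimParams,
    rng: np.random.Generator | None = None,
    rng_variants: np.random.Generator | None = None,
) -> Evolution:
    """Evolve `n_isolates` leaf genomes from the root along a random tree.

    Per-edge variant counts are Poisson with the configured means;
    substitution positions are uniform (they are typically re-drawn by
    :func:`relocate_substitutions` afterwards), indels are 1-10 bp uniform.
    """
    if rng is None:
        s = _streams(params.seed)
        rng, rng_variants = s["tree"], s["variants"]
    if rng_variants is None:
        rng_variants = rng
    root_codes = root if isinstance(root, np.ndarray) else SequenceSet(root.records).codes(root.ids[0])
    newick, edge_pairs, paths = _random_tree(params.n_isolates, rng)
    edges = [
        _draw_edge_events(p, c, len(root_codes), params, rng_variants)
        for p, c in edge_pairs
    ]
    isolates = {
        leaf: _materialize(leaf, root_codes, [edges[i] for i in path])
        for leaf, path in paths.items()
    }
    return Evolution(newick, edges, paths, isolates)


# ---------------------------------------------------------------------------
# substitution relocation and the truth set
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Machine-readable ground truth for one simulated benchmark run."""

    tree_newick: str
    edges: list[EdgeVariants]
    isolates: dict[str, IsolateTruth]
    snp_sites: pd.DataFrame  # root_pos, ref_contig, ref_pos, one column per isolate
    regions: pd.DataFrame  # ref_contig, ref_start, ref_end, root_start, root_end
    pair: RefRootPair

    @property
    def isolate_names(self) -> list[str]:
        return list(self.isolates)

    def ref_sites(self) -> list[tuple[str, int]]:
        return list(
            zip(self.snp_sites["ref_contig"], self.snp_sites["ref_pos"].astype(int))
        )

    def to_tsv(self, path) -> None:
        self.snp_sites.to_csv(path, sep="\t", index=False)


def pair_one_to_one(
    pair: RefRootPair,
    min_region_len: int = 1000,
    aligner_kwargs: dict | None = None,
) -> OneToOneMap:
    """One-to-one alignment regions between the root and the reference,
    computed with the package's own aligner (root playing the contig role)."""
    alns = align_contigs(pair.root, pair.reference, **(aligner_kwargs or {}))
    return select_one_to_one(alns, min_align_len=min_region_len)


def _qualifying_root_positions(
    o2o: OneToOneMap, margin: int, root2ref: np.ndarray
) -> np.ndarray:
    """Root positions eligible for substitution placement.

    A position qualifies when it sits on an aligned column of a retained
    pair alignment, at least `margin`+1 bp from any gap column, and the
    column's reference coordinate agrees with the true root-to-reference
    map (columns pairing a root site with a diverged duplicate copy are
    thereby excluded, keeping the truth coordinate frame unambiguous)."""
    chunks = []
    for aln in o2o.alignments:
        ref_pos, q_pos = aln.aligned_pairs
        ok = aln.d_ok_mask(ref_pos, margin)
        qp = q_pos[ok]
        rp = ref_pos[ok]
        if aln.strand == "-":
            qp = aln.ctg_len - 1 - qp
        consistent = root2ref[qp] == rp
        chunks.append(qp[consistent])
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def relocate_substitutions(
    evolution: Evolution,
    pair: RefRootPair,
    pair_map: OneToOneMap,
    min_region_len: int = 1000,
    rng: np.random.Generator | None = None,
    placement_margin: int = 6,
) -> TruthSet:
    """Re-draw every substitution position uniformly inside the qualifying
    one-to-one regions (reference span >= min_region_len), rebuild the leaf
    genomes and tabulate the true SNP sites in both coordinate frames."""
    rng = rng or _streams(0)["relocation"]
    retained = [a for a in pair_map.alignments if a.ref_span >= min_region_len]
    o2o = OneToOneMap(retained)
    qualifying = _qualifying_root_positions(o2o, placement_margin, pair.root2ref)
    root_codes = pair.root_codes
    edges = []
    for edge in evolution.edges:
        n = edge.n_sub
        if n > len(qualifying):
            raise ValueError(
                f"qualifying regions hold {len(qualifying)} sites but edge "
                f"{edge.parent}->{edge.child} needs {n} substitutions"
            )
        pos = np.sort(rng.choice(qualifying, size=n, replace=False))
        shift = rng.integers(1, 4, size=n)
        edges.append(replace(edge, sub_pos=pos, sub_shift=shift))
    isolates = {
        leaf: _materialize(leaf, root_codes, [edges[i] for i in path])
        for leaf, path in evolution.leaf_paths.items()
    }

    names = list(isolates)
    candidates = np.unique(np.concatenate([e.sub_pos for e in edges])) if edges else np.empty(0, int)
    rows = []
    for pos in candidates.tolist():
        alleles = []
        for name in names:
            iso = isolates[name]
            alleles.append("-" if iso.deleted[pos] else "ACGT"[iso.root_alleles[pos]])
        distinct = {a for a in alleles if a != "-"}
        if len(distinct) < 2:
            continue
        lifted = None
        aln = o2o.alignment_at_ctg("root", pos)
        if aln is not None:
            r = aln.liftover_ctg(pos)
            if r is not None:
                lifted = (aln.ref_id, r)
        if lifted is None:  # placement guarantees this never triggers
            raise AssertionError(f"true SNP at root position {pos} does not lift")
        rows.append([pos, lifted[0], lifted[1]] + alleles)
    snp_sites = pd.DataFrame(rows, columns=["root_pos", "ref_contig", "ref_pos"] + names)
    regions = pd.DataFrame(
        [
            {
                "ref_contig": a.ref_id,
                "ref_start": a.ref_start,
                "ref_end": a.ref_end,
                "root_start": a.ctg_start,
                "root_end": a.ctg_end,
            }
            for a in sorted(retained, key=lambda a: (a.ref_id, a.ref_start))
        ],
        columns=["ref_contig", "ref_start", "ref_end", "root_start", "root_end"],
    )
    return TruthSet(evolution.tree_newick, edges, isolates, snp_sites, regions, pair)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class RawReadSet:
    """Paired-end reads of one isolate, in isolate-forward coordinates.

    ``r2_codes`` holds the forward-strand bases under read 2's footprint;
    the FASTQ representation of read 2 is its reverse complement.
    """

    isolate: str
    read_len: int
    r1_start: np.ndarray
    r2_start: np.ndarray
    r1_codes: np.ndarray
    r2_codes: np.ndarray


def simulate_reads(
    isolates: dict[str, IsolateTruth],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> dict[str, RawReadSet]:
    """Uniform paired-end fragments with i.i.d. substitution errors.

    The chromosome is treated as circular (as bacterial chromosomes are):
    fragment starts are uniform over the whole genome and fragments may span
    the origin, so coverage has no linear-end ramp. Start coordinates are
    stored mod genome length; origin-spanning reads are placed as split
    records by :func:`place_reads`.
    """
    rng = rng or _streams(params.seed)["reads"]
    if params.coverage <= 0:
        raise ValueError("coverage must be positive")
    out = {}
    rl = params.read_len
    for name, iso in isolates.items():
        L = len(iso.codes)
        n_pairs = int(round(params.coverage * L / (2 * rl)))
        frag = np.clip(
            np.rint(rng.normal(params.frag_mean, params.frag_sd, size=n_pairs)),
            rl,
            L,
        ).astype(np.int64)
        start = np.floor(rng.random(n_pairs) * L).astype(np.int64)
        r1s = start
        r2s = (start + frag - rl) % L
        window = np.arange(rl)
        r1 = iso.codes[(r1s[:, None] + window) % L]
        r2 = iso.codes[(r2s[:, None] + window) % L]
        if params.error_rate > 0:
            for mat in (r1, r2):
                hit = rng.random(mat.shape) < params.error_rate
                mat[hit] = (mat[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        out[name] = RawReadSet(name, rl, r1s, r2s, r1.astype(np.uint8), r2.astype(np.uint8))
    return out


def _ops_from_map(m: np.ndarray) -> tuple[int, list[tuple[str, int]]] | None:
    """Derive placement ops for one read from its per-base target positions
    (-1 = no correspondence). Returns (ref_start, ops) or None if unmapped."""
    valid = np.flatnonzero(m >= 0)
    if valid.size == 0:
        return None
    ops: list[tuple[str, int]] = []
    first = int(valid[0])
    if first > 0:
        ops.append(("S", first))
    run_start = first
    prev = first
    i = first

    def close_run(end_i: int):
        if end_i >= run_start:
            ops.append(("M", end_i - run_start + 1))

    out_start = int(m[first])
    clipped_from = None
    for j in valid[1:]:
        j = int(j)
        read_gap = j - prev - 1
        ref_gap = int(m[j]) - int(m[prev]) - 1
        if ref_gap < 0 or ref_gap > _MAX_INTERNAL_DELETION or read_gap > _MAX_INTERNAL_INSERTION:
            clipped_from = prev + 1
            break
        if read_gap or ref_gap:
            close_run(prev)
            if read_gap:
                ops.append(("I", read_gap))
            if ref_gap:
                ops.append(("D", ref_gap))
            run_start = j
        prev = j
    if clipped_from is None:
        close_run(prev)
        tail = len(m) - prev - 1
        if tail:
            ops.append(("S", tail))
    else:
        close_run(prev)
        ops.append(("S", len(m) - clipped_from))
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if not any(op == "M" for op, _ in merged):
        return None
    return out_start, merged


def place_reads(
    raw: RawReadSet,
    frame_map: np.ndarray,
    frame_id: str,
) -> list[ReadAlignmentRecord]:
    """Truth placements of a read set against a target coordinate frame.

    ``frame_map`` maps isolate positions to target positions (-1 = absent).
    Reads with no mappable base are dropped (the unmapped fraction);
    interior unmappable runs become insertions, long target-side jumps or
    end-touching unmappable runs become soft-clips.
    """
    rl = raw.read_len
    L = len(frame_map)
    breaks = np.flatnonzero(np.diff(frame_map) != 1)
    out: list[ReadAlignmentRecord] = []
    for mate, starts, codes, reverse in (
        (1, raw.r1_start, raw.r1_codes, False),
        (2, raw.r2_start, raw.r2_codes, True),
    ):
        n = len(starts)
        lo = np.searchsorted(breaks, starts)
        hi = np.searchsorted(breaks, starts + rl - 1)
        simple = (starts + rl <= L) & (hi == lo) & (frame_map[starts % L] >= 0)
        for i in range(n):
            s = int(starts[i])
            seq = decode(codes[i])
            name = f"{raw.isolate}_r{i}/{mate}"
            if simple[i]:
                out.append(
                    ReadAlignmentRecord(
                        read_id=name,
                        ref_id=frame_id,
                        ref_start=int(frame_map[s]),
                        ops=[("M", rl)],
                        seq=seq,
                        is_reverse=reverse,
                    )
                )
                continue
            # origin-spanning reads (circular chromosome) are placed as one
            # split record per genome arm, soft-clipping the other arm
            pieces = (
                [(0, s, min(s + rl, L)), (L - s, 0, s + rl - L)]
                if s + rl > L
                else [(0, s, s + rl)]
            )
            for offset, p_lo, p_hi in pieces:
                if p_hi <= p_lo:
                    continue
                placed = _ops_from_map(frame_map[p_lo:p_hi])
                if placed is None:
                    continue
                ref_start, ops = placed
                head = offset
                tail = rl - offset - (p_hi - p_lo)
                if head:
                    ops = [("S", head)] + ops
                if tail:
                    ops = ops + [("S", tail)]
                ops = [
                    (op, n_) for op, n_ in _merge_adjacent(ops)
                ]
                out.append(
                    ReadAlignmentRecord(
                        read_id=name,
                        ref_id=frame_id,
                        ref_start=ref_start,
                        ops=ops,
                        seq=seq,
                        is_reverse=reverse,
                    )
                )
    return out


def _merge_adjacent(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def fastq_records(raw: RawReadSet) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """FASTQ-ready (id, sequence) lists for the two mates; mate 2 is
    reverse-complemented as it comes off the opposite strand."""
    r1 = [
        (f"{raw.isolate}_r{i}/1", decode(raw.r1_codes[i]))
        for i in range(len(raw.r1_start))
    ]
    r2 = [
        (f"{raw.isolate}_r{i}/2", revcomp(decode(raw.r2_codes[i])))
        for i in range(len(raw.r2_start))
    ]
    return r1, r2


# ---------------------------------------------------------------------------
# contig fragmentation
# ---------------------------------------------------------------------------

def fragment_contigs(
    isolates: dict[str, IsolateTruth],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> dict[str, SequenceSet]:
    """Cut each isolate genome into contigs at random break positions.

    Breaks closer than ``min_contig_len`` to a previous boundary are
    discarded, so every emitted contig meets the minimum length; optional
    end-trimming mimics ragged assembly ends.
    """
    rng = rng or _streams(params.seed)["fragmentation"]
    out = {}
    t = params.end_trim
    for name, iso in isolates.items():
        L = len(iso.codes)
        raw_breaks = np.sort(rng.integers(1, L, size=params.n_breaks)) if params.n_breaks else np.empty(0, int)
        bounds = [0]
        for b in raw_breaks.tolist():
            if b - bounds[-1] >= params.min_contig_len and L - b >= params.min_contig_len:
                bounds.append(int(b))
        bounds.append(L)
        records = []
        for j in range(len(bounds) - 1):
            s, e = bounds[j], bounds[j + 1]
            if t and e - s > 2 * t + 1:
                s, e = s + t, e - t
            records.append((f"{name}_c{j:02d}", decode(iso.codes[s:e])))
        out[name] = SequenceSet(records)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    params: SimParams
    pair: RefRootPair
    truth: TruthSet
    contigs: dict[str, SequenceSet]
    raw_reads: dict[str, RawReadSet]
    reads: dict[str, list[ReadAlignmentRecord]]  # placed in the reference frame

    @property
    def reference(self) -> SequenceSet:
        return self.pair.reference

    def iso_to_ref_map(self, isolate: str) -> np.ndarray:
        return _compose_iso2ref(self.truth.isolates[isolate], self.pair)

    def reads_in_isolate_frame(self, frame_isolate: str) -> dict[str, list[ReadAlignmentRecord]]:
        """Re-place every read set against one isolate's genome (the frame
        used by reference-free calling when that isolate's assembly serves
        as the reference). The frame genome must be a single contig to act
        as a drop-in reference, so this helper is for unfragmented use."""
        frame = self.truth.isolates[frame_isolate]
        out = {}
        for name, raw in self.raw_reads.items():
            iso = self.truth.isolates[name]
            m = np.where(iso.iso2root >= 0, frame.root2iso[iso.iso2root], -1)
            out[name] = place_reads(raw, m, frame_isolate)
        return out


def simulate(params: SimParams) -> SimOutput:
    """Run the full generator: pair, tree, relocation, reads, contigs."""
    streams = _streams(params.seed)
    pair = make_reference_root_pair(params, streams["pair"])
    evo = evolve_isolates(
        pair.root_codes, params, streams["tree"], streams["variants"]
    )
    o2o = pair_one_to_one(pair, params.min_region_len)
    truth = relocate_substitutions(
        evo, pair, o2o, params.min_region_len, streams["relocation"]
    )
    raw = simulate_reads(truth.isolates, params, streams["reads"])
    reads = {
        name: place_reads(r, _compose_iso2ref(truth.isolates[name], pair), "ref")
        for name, r in raw.items()
    }
    contigs = fragment_contigs(truth.isolates, params, streams["fragmentation"])
    return SimOutput(params, pair, truth, contigs, raw, reads)


def _compose_iso2ref(iso: IsolateTruth, pair: RefRootPair) -> np.ndarray:
    return np.where(iso.iso2root >= 0, pair.root2ref[np.maximum(iso.iso2root, 0)], -1)
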