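"""Reading and writing of every external representation the pipeline touches.

Standard formats (FASTA, SAM) are handled through Biopython and pysam; the
module adds the pipeline's own tabular dialects: the SNP TSV, the
Gubbins-compatible alignment FASTA, the nucmer ``show-coords -T`` table, and
an internal read truth-placement TSV that allows mapper-free pileups in
simulation-driven runs.

Coordinate conventions: everything in memory is 0-based half-open; every
human-facing file is 1-based inclusive.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from ._seq import decode, encode, normalize


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _opener(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An ordered collection of named DNA sequences.

    Sequences are normalized on construction: uppercased, and every
    non-ACGT symbol (IUPAC ambiguity codes included) collapsed to N so an
    ambiguous input base can never surface as a SNP allele.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        cleaned = []
        for name, seq in self.records:
            if name in seen:
                raise FormatError(f"duplicate sequence id {name!r}")
            if not seq:
                raise FormatError(f"empty sequence for id {name!r}")
            seen.add(name)
            cleaned.append((name, normalize(seq)))
        self.records = cleaned

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return any(n == name for n, _ in self.records)

    def __getitem__(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)

    def codes(self, name: str) -> np.ndarray:
        return encode(self[name])

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.records}

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


def read_fasta(path) -> SequenceSet:
    """Read a (possibly gzipped) FASTA file into a :class:`SequenceSet`."""
    with _opener(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        bad = text.splitlines().index(stripped.splitlines()[0]) + 1
        raise FormatError(f"{path}: line {bad}: expected FASTA header '>'")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        if len(rec.seq) == 0:
            lineno = _find_header_line(text, rec.id)
            raise FormatError(f"{path}: line {lineno}: record {rec.id!r} is empty")
    try:
        return SequenceSet([(rec.id, str(rec.seq)) for rec in records])
    except FormatError as err:  # duplicate ids: attach a line number
        raise FormatError(f"{path}: {err}") from err


def _find_header_line(text: str, rec_id: str) -> int:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
            return i
    return 0


def write_fasta(seqs: SequenceSet | Mapping[str, str], path, width: int = 70) -> None:
    items = seqs.records if isinstance(seqs, SequenceSet) else list(seqs.items())
    with _opener(path, "wt") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path, qual_char: str = "I") -> None:
    """Write (id, sequence) pairs as FASTQ with a constant quality string."""
    with _opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# read alignments
# ---------------------------------------------------------------------------

_QUERY_OPS = frozenset("MIS")
_REF_OPS = frozenset("MD")


@dataclass
class ReadAlignmentRecord:
    """One aligned read: placement plus a CIGAR-style operation list.

    ``ops`` is a list of ``(op, length)`` with op in {M, I, D, S}: M consumes
    read and reference (matches and mismatches alike), I the read only, D the
    reference only, S a terminal soft-clip. Base qualities are deliberately
    not carried: the masking conditions downstream use depth only.
    """

    read_id: str
    ref_id: str
    ref_start: int
    ops: list[tuple[str, int]]
    seq: str
    mapq: int = 60
    is_duplicate: bool = False
    is_secondary_or_supplementary: bool = False
    is_reverse: bool = False

    def __post_init__(self):
        qlen = sum(n for op, n in self.ops if op in _QUERY_OPS)
        if qlen != len(self.seq):
            raise FormatError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.seq)}"
            )
        for i, (op, n) in enumerate(self.ops):
            if n <= 0 or op not in "MIDS":
                raise FormatError(f"read {self.read_id}: bad op {op}{n}")
            if op == "S" and i not in (0, len(self.ops) - 1):
                raise FormatError(f"read {self.read_id}: internal soft-clip")

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in _REF_OPS)

    @property
    def leading_clip(self) -> int:
        return self.ops[0][1] if self.ops and self.ops[0][0] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.ops[-1][1] if len(self.ops) > 1 and self.ops[-1][0] == "S" else 0

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"bad CIGAR {cigar!r}")
            op = "M" if ch in "=X" else ch
            if ch not in "MIDS=X":
                raise FormatError(f"unsupported CIGAR op {ch!r} in {cigar!r}")
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + int(num))
            else:
                ops.append((op, int(num)))
            num = ""
    if num:
        raise FormatError(f"bad CIGAR {cigar!r}")
    return ops


def read_sam(
    path,
    reference: SequenceSet,
    drop_secondary: bool = True,
) -> list[ReadAlignmentRecord]:
    """Read a SAM file into :class:`ReadAlignmentRecord` objects.

    Unmapped records are skipped; secondary/supplementary records are dropped
    when ``drop_secondary`` (default) or flagged otherwise. Duplicate-flagged
    records are kept flagged so :func:`pseudosnp.read_support.dedupe` stays
    the single point of duplicate policy.
    """
    ref_ids = set(reference.ids)
    out: list[ReadAlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            secondary = rec.is_secondary or rec.is_supplementary
            if secondary and drop_secondary:
                continue
            if rec.reference_name not in ref_ids:
                raise FormatError(
                    f"{path}: read {rec.query_name} mapped to unknown "
                    f"reference {rec.reference_name!r}"
                )
            ops = []
            for code, n in rec.cigartuples or []:
                # 0=M,1=I,2=D,4=S,7==,8=X; hard clips (5) consume nothing
                if code in (0, 7, 8):
                    op = "M"
                elif code == 1:
                    op = "I"
                elif code == 2:
                    op = "D"
                elif code == 4:
                    op = "S"
                elif code == 5:
                    continue
                else:
                    raise FormatError(
                        f"{path}: read {rec.query_name}: unsupported CIGAR op"
                    )
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + n)
                else:
                    ops.append((op, n))
            out.append(
                ReadAlignmentRecord(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    ops=ops,
                    seq=normalize(rec.query_sequence or ""),
                    mapq=rec.mapping_quality,
                    is_duplicate=rec.is_duplicate,
                    is_secondary_or_supplementary=secondary,
                    is_reverse=rec.is_reverse,
                )
            )
    return out


_FLAG_REVERSE = 0x10
_FLAG_SECONDARY = 0x100
_FLAG_DUP = 0x400
_FLAG_SUPPLEMENTARY = 0x800

_PLACEMENT_HEADER = ["read_id", "ref_id", "ref_start", "cigar", "seq", "mapq", "flags"]


def write_placements(records: Iterable[ReadAlignmentRecord], path) -> None:
    """Write records in the internal truth-placement TSV dialect (0-based)."""
    with _opener(path, "wt") as fh:
        fh.write("\t".join(_PLACEMENT_HEADER) + "\n")
        for r in records:
            flags = (
                (_FLAG_REVERSE if r.is_reverse else 0)
                | (_FLAG_DUP if r.is_duplicate else 0)
                | (_FLAG_SECONDARY if r.is_secondary_or_supplementary else 0)
            )
            fh.write(
                f"{r.read_id}\t{r.ref_id}\t{r.ref_start}\t{r.cigar_string()}"
                f"\t{r.seq}\t{r.mapq}\t{flags}\n"
            )


def read_placements(path, reference: SequenceSet | None = None) -> list[ReadAlignmentRecord]:
    ref_ids = set(reference.ids) if reference is not None else None
    out: list[ReadAlignmentRecord] = []
    with _opener(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PLACEMENT_HEADER:
            raise FormatError(f"{path}: line 1: bad placement header")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}: line {lineno}: expected 7 fields")
            rid, ref_id, start, cigar, seq, mapq, flags = fields
            if ref_ids is not None and ref_id not in ref_ids:
                raise FormatError(
                    f"{path}: line {lineno}: unknown reference {ref_id!r}"
                )
            try:
                start_i, mapq_i, flags_i = int(start), int(mapq), int(flags)
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: {err}") from err
            out.append(
                ReadAlignmentRecord(
                    read_id=rid,
                    ref_id=ref_id,
                    ref_start=start_i,
                    ops=parse_cigar(cigar),
                    seq=normalize(seq),
                    mapq=mapq_i,
                    is_duplicate=bool(flags_i & _FLAG_DUP),
                    is_secondary_or_supplementary=bool(
                        flags_i & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY)
                    ),
                    is_reverse=bool(flags_i & _FLAG_REVERSE),
                )
            )
    return out


# ---------------------------------------------------------------------------
# nucmer show-coords -T tables
# ---------------------------------------------------------------------------

class CoordsInterval(NamedTuple):
    """One raw contig-reference alignment interval, 0-based half-open."""

    ref_id: str
    ref_start: int
    ref_end: int
    ctg_id: str
    ctg_start: int
    ctg_end: int
    pct_identity: float
    strand: str


def read_coords(path) -> list[CoordsInterval]:
    """Parse a nucmer ``show-coords -T``-style tab-separated table.

    Input rows are 1-based inclusive with columns S1 E1 S2 E2 LEN1 LEN2 %IDY
    followed by the reference and contig names; header/separator lines are
    skipped. Reverse-strand rows (S2 > E2) are normalized to forward contig
    intervals with strand '-'.
    """
    out: list[CoordsInterval] = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                if lineno <= 4 and "\t" not in line or set(line) <= {"=", "-", " "}:
                    continue  # nucmer banner/header lines
                raise FormatError(f"{path}: line {lineno}: expected >=9 columns")
            try:
                s1, e1, s2, e2 = (int(x) for x in fields[:4])
                idy = float(fields[6])
            except ValueError:
                if lineno <= 4:
                    continue  # show-coords column header
                raise FormatError(f"{path}: line {lineno}: non-numeric coordinate")
            ref_id, ctg_id = fields[-2], fields[-1]
            if s2 <= e2:
                strand, cs, ce = "+", s2 - 1, e2
            else:
                strand, cs, ce = "-", e2 - 1, s2
            out.append(
                CoordsInterval(ref_id, s1 - 1, e1, ctg_id, cs, ce, idy / 100.0, strand)
            )
    return out


# ---------------------------------------------------------------------------
# SNP TSV and alignment FASTA
# ---------------------------------------------------------------------------

def write_snp_tsv(table, path) -> None:
    """Write a SnpTable as TSV: contig, 1-based pos, reference allele, one
    column per isolate. A zero-SNP table yields a header-only file."""
    with _opener(path, "wt") as fh:
        fh.write("\t".join(["contig", "pos", "ref"] + list(table.isolates)) + "\n")
        for contig, pos, ref_allele, alleles in table.iter_rows():
            fh.write(f"{contig}\t{pos + 1}\t{ref_allele}\t" + "\t".join(alleles) + "\n")


def read_snp_tsv(path):
    from .snp_caller import SnpTable  # local import: io sits below snp_caller

    rows = []
    with _opener(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["contig", "pos", "ref"]:
            raise FormatError(f"{path}: line 1: bad SNP TSV header")
        isolates = header[3:]
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + len(isolates):
                raise FormatError(f"{path}: line {lineno}: wrong column count")
            try:
                pos = int(fields[1]) - 1
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: {err}") from err
            rows.append((fields[0], pos, fields[2], tuple(fields[3:])))
    return SnpTable.from_rows(isolates, rows)


def _contig_strings(pseudo) -> dict[str, str]:
    if hasattr(pseudo, "contig_strings"):
        return pseudo.contig_strings()
    if isinstance(pseudo, Mapping):
        return {k: (decode(v) if isinstance(v, np.ndarray) else v) for k, v in pseudo.items()}
    raise TypeError(f"cannot interpret {type(pseudo)!r} as a pseudogenome")


def write_alignment_fasta(
    pseudogenomes: Mapping[str, object],
    path,
    contig_order: Sequence[str] | None = None,
    width: int = 70,
) -> None:
    """Write one equal-length record per isolate: pseudogenome contigs
    concatenated in reference order (the input Gubbins expects)."""
    per_iso = {name: _contig_strings(p) for name, p in pseudogenomes.items()}
    if not per_iso:
        raise ValueError("no pseudogenomes to write")
    first = next(iter(per_iso.values()))
    order = list(contig_order) if contig_order is not None else list(first)
    lengths = {c: len(first[c]) for c in order}
    for name, contigs in per_iso.items():
        if set(contigs) != set(order) or any(len(contigs[c]) != lengths[c] for c in order):
            raise ValueError(f"pseudogenome {name!r} does not match reference layout")
    write_fasta({name: "".join(contigs[c] for c in order) for name, contigs in per_iso.items()},
                path, width=width)
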