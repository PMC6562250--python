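"""Cross-isolate SNP determination and the end-to-end calling pipeline.

SNPs are defined *among isolates*: a reference site is a SNP site iff the
isolate pseudogenome alleles at that site contain at least two distinct
non-N values. The reference allele is reported for orientation but a site
where every isolate agrees against the reference is not a SNP.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterator, Mapping

import numpy as np

from . import __version__
from ._seq import BASES
from .alignment import LocalAlignment
from .io_formats import ReadAlignmentRecord, SequenceSet
from .pseudogenome import MaskMode, Pseudogenome, SupportTable, build_pseudogenome

_ALPHABET = BASES + "N"


@dataclass
class SnpTable:
    """Cross-isolate SNP sites with per-isolate alleles.

    Rows are sorted by (contig, 0-based site) and each row carries >= 2
    distinct non-N isolate alleles; isolate column order is fixed.
    """

    isolates: list[str]
    contigs: list[str] = field(default_factory=list)
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ref_alleles: list[str] = field(default_factory=list)
    alleles: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype="U1"))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.size == 0:
            self.alleles = np.empty((0, len(self.isolates)), dtype="U1")
        n = len(self.contigs)
        if not (len(self.positions) == len(self.ref_alleles) == self.alleles.shape[0] == n):
            raise ValueError("inconsistent SnpTable row arrays")
        if self.alleles.shape[1] != len(self.isolates):
            raise ValueError("allele matrix does not match isolate list")
        order = sorted(range(n), key=lambda i: (self.contigs[i], int(self.positions[i])))
        if order != list(range(n)):
            self.contigs = [self.contigs[i] for i in order]
            self.positions = self.positions[order]
            self.ref_alleles = [self.ref_alleles[i] for i in order]
            self.alleles = self.alleles[order]
        keys = list(zip(self.contigs, self.positions.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicate SNP sites")
        for i in range(n):
            vals = {a for a in self.alleles[i] if a != "N"}
            if len(vals) < 2:
                raise ValueError(
                    f"row {self.contigs[i]}:{int(self.positions[i]) + 1} is not "
                    "polymorphic among isolates"
                )
            if any(a not in _ALPHABET for a in self.alleles[i]):
                raise ValueError("allele outside {A,C,G,T,N}")

    @classmethod
    def from_rows(cls, isolates, rows) -> "SnpTable":
        rows = list(rows)
        return cls(
            isolates=list(isolates),
            contigs=[r[0] for r in rows],
            positions=np.array([r[1] for r in rows], dtype=np.int64),
            ref_alleles=[r[2] for r in rows],
            alleles=np.array([list(r[3]) for r in rows], dtype="U1").reshape(
                len(rows), len(list(isolates))
            ),
        )

    @property
    def n_sites(self) -> int:
        return len(self.contigs)

    def sites(self) -> list[tuple[str, int]]:
        return list(zip(self.contigs, self.positions.tolist()))

    def iter_rows(self) -> Iterator[tuple[str, int, str, tuple[str, ...]]]:
        for i in range(self.n_sites):
            yield (
                self.contigs[i],
                int(self.positions[i]),
                self.ref_alleles[i],
                tuple(self.alleles[i]),
            )

    def reorder_isolates(self, isolates: list[str]) -> "SnpTable":
        idx = [self.isolates.index(name) for name in isolates]
        return SnpTable(
            isolates=list(isolates),
            contigs=list(self.contigs),
            positions=self.positions.copy(),
            ref_alleles=list(self.ref_alleles),
            alleles=self.alleles[:, idx],
        )

    def to_dataframe(self):
        import pandas as pd

        data = {"contig": self.contigs, "pos": self.positions, "ref": self.ref_alleles}
        for j, name in enumerate(self.isolates):
            data[name] = self.alleles[:, j] if self.n_sites else []
        return pd.DataFrame(data)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SnpTable)
            and self.isolates == other.isolates
            and self.contigs == other.contigs
            and np.array_equal(self.positions, other.positions)
            and self.ref_alleles == other.ref_alleles
            and np.array_equal(self.alleles, other.alleles)
        )


def call_snps(
    pseudogenomes: Mapping[str, Pseudogenome],
    reference: SequenceSet,
    require_complete: bool = False,
) -> SnpTable:
    """Derive the SNP table from reference-conformant pseudogenomes.

    With ``require_complete`` every site where any isolate is masked (N) is
    excluded; by default such sites are reported with N cells as long as two
    isolates still disagree.
    """
    isolates = list(pseudogenomes)
    if len(isolates) < 2:
        raise ValueError("SNP calling requires at least 2 isolates")
    ref_lengths = reference.lengths()
    for name, p in pseudogenomes.items():
        if p.lengths() != ref_lengths:
            raise ValueError(f"pseudogenome {name!r} does not match reference layout")
    rows = []
    for contig, ref_seq in reference:
        stack = np.stack([pseudogenomes[iso].contigs[contig] for iso in isolates])
        present = np.stack([(stack == b).any(axis=0) for b in range(4)])
        distinct = present.sum(axis=0)
        is_snp = distinct >= 2
        if require_complete:
            is_snp &= ~(stack == 4).any(axis=0)
        for pos in np.flatnonzero(is_snp):
            rows.append(
                (
                    contig,
                    int(pos),
                    ref_seq[pos],
                    tuple(_ALPHABET[min(c, 4)] for c in stack[:, pos]),
                )
            )
    return SnpTable.from_rows(isolates, rows)


@dataclass
class PipelineParams:
    """All calling-path thresholds with their defaults."""

    min_depth: int = 10
    min_frac: float = 0.9
    indel_margin: int = 5
    min_align_len: int = 0
    mask_mode: MaskMode = "both"
    min_mapq: int = 0
    require_complete: bool = False
    # aligner knobs
    k: int = 17
    min_anchor_chain: int = 1
    max_occ: int = 8
    max_gap_ctg: int = 300
    max_gap_ref: int = 6000
    min_chain_bases: int = 100

    def aligner_kwargs(self) -> dict:
        return dict(
            k=self.k,
            min_anchor_chain=self.min_anchor_chain,
            max_occ=self.max_occ,
            max_gap_ctg=self.max_gap_ctg,
            max_gap_ref=self.max_gap_ref,
            min_chain_bases=self.min_chain_bases,
        )


@dataclass
class PipelineResult:
    snps: SnpTable
    pseudogenomes: dict[str, Pseudogenome]
    supports: dict[str, SupportTable]
    reference: SequenceSet
    report: dict


def run_pipeline(
    contigs: Mapping[str, SequenceSet],
    reads: Mapping[str, list[ReadAlignmentRecord]],
    reference: SequenceSet | None = None,
    pseudo_ref_isolate: str | None = None,
    params: PipelineParams | None = None,
    alignments: Mapping[str, list[LocalAlignment]] | None = None,
) -> PipelineResult:
    """Run contig alignment -> pseudogenome -> SNP calling for all isolates.

    In reference-free mode (``reference is None``) the contigs of
    ``pseudo_ref_isolate`` become the reference; that isolate is still
    processed as a target against its own contigs, and its reads still mask
    its low-support sites. Read alignments must be in the frame of whichever
    reference is in effect.
    """
    params = params or PipelineParams()
    isolates = list(contigs)
    if len(isolates) < 2:
        raise ValueError("at least 2 isolates are required")
    if set(reads) != set(isolates):
        raise ValueError(
            "isolate names differ between contig and read inputs: "
            f"{sorted(set(reads) ^ set(isolates))}"
        )
    if reference is None:
        if pseudo_ref_isolate is None:
            raise ValueError("either a reference or a pseudo-reference isolate is required")
        if pseudo_ref_isolate not in contigs:
            raise ValueError(f"unknown pseudo-reference isolate {pseudo_ref_isolate!r}")
        reference = contigs[pseudo_ref_isolate]

    pseudos: dict[str, Pseudogenome] = {}
    supports: dict[str, SupportTable] = {}
    per_isolate_report = {}
    for iso in isolates:
        iso_contigs = contigs[iso]
        if set(iso_contigs.ids) & set(reference.ids):
            # self-alignment in reference-free mode: rename the query copies
            iso_contigs = SequenceSet(
                [(f"{n}|ctg", s) for n, s in iso_contigs.records]
            )
        iso_alns = alignments.get(iso) if alignments else None
        pseudo, table = build_pseudogenome(
            reference,
            iso_contigs,
            reads[iso],
            alignments=iso_alns,
            min_depth=params.min_depth,
            min_frac=params.min_frac,
            indel_margin=params.indel_margin,
            min_align_len=params.min_align_len,
            mask_mode=params.mask_mode,
            min_mapq=params.min_mapq,
            aligner_kwargs=params.aligner_kwargs(),
        )
        pseudos[iso] = pseudo
        supports[iso] = table
        per_isolate_report[iso] = {
            "n_alignments_selected": len(table.o2o.alignments),
            "called_sites": int(
                sum((codes < 4).sum() for codes in pseudo.contigs.values())
            ),
        }

    snps = call_snps(pseudos, reference, require_complete=params.require_complete)
    report = {
        "version": __version__,
        "params": asdict(params),
        "reference_contigs": reference.lengths(),
        "pseudo_ref_isolate": pseudo_ref_isolate,
        "isolates": per_isolate_report,
        "n_snp_sites": snps.n_sites,
    }
    return PipelineResult(snps, pseudos, supports, reference, report)
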