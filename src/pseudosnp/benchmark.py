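"""Benchmark metrics: PPV, sensitivity, called-sites ratio, common-region PPV.

Definitions follow the benchmark convention for SNP callers evaluated
against a simulated truth: PPV is the ratio of true-positive detected SNP
sites to all detected SNP sites; sensitivity the ratio of true-positive
detected sites to all true SNP sites; the called-sites ratio the fraction
of reference sites whose nucleotide was determined unambiguously in all
isolates; the common-region PPV restricts PPV to sites where every compared
tool determined alleles for all isolates without masking.

True-positive matching is position-level by default (a detected reference
coordinate that equals a true SNP coordinate); ``match_alleles=True``
additionally requires every non-N detected isolate allele to equal the
truth allele.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceSet
from .pseudogenome import Pseudogenome
from .read_support import render_fraction
from .simulator import TruthSet
from .snp_caller import SnpTable

Site = tuple[str, int]


@dataclass
class BenchmarkResult:
    tp: int
    detected: int
    truth_total: int
    ppv: float | None  # None when nothing was detected (0/0)
    sensitivity: float | None
    called_sites_ratio: float | None = None
    common_region_ppv: float | None = None

    def as_percent_rows(self) -> list[tuple[str, str]]:
        return [
            ("PPV", render_fraction(self.ppv)),
            ("Common-region PPV", render_fraction(self.common_region_ppv)),
            ("Sensitivity", render_fraction(self.sensitivity)),
            ("Called-sites", render_fraction(self.called_sites_ratio)),
        ]


def _truth_table(truth) -> dict[Site, dict[str, str]]:
    """Normalize a TruthSet / truth TSV DataFrame to site -> isolate alleles."""
    if isinstance(truth, TruthSet):
        df = truth.snp_sites
    elif isinstance(truth, pd.DataFrame):
        df = truth
    else:  # bare site collection
        return {(c, int(p)): {} for c, p in truth}
    iso_cols = [c for c in df.columns if c not in ("root_pos", "ref_contig", "ref_pos")]
    out = {}
    for row in df.itertuples(index=False):
        site = (getattr(row, "ref_contig"), int(getattr(row, "ref_pos")))
        out[site] = {c: getattr(row, c) for c in iso_cols}
    return out


def _detected_sites(detected) -> tuple[list[Site], SnpTable | None]:
    if isinstance(detected, SnpTable):
        return detected.sites(), detected
    return sorted({(c, int(p)) for c, p in detected}), None


def score(detected, truth, match_alleles: bool = False) -> BenchmarkResult:
    """Score detected SNP sites against the simulated truth.

    ``detected`` is a SnpTable or any iterable of (contig, position) sites
    (duplicates counted once); ``truth`` a TruthSet, its site table, or a
    site collection.
    """
    sites, table = _detected_sites(detected)
    truth_map = _truth_table(truth)
    tp = 0
    for i, site in enumerate(sites):
        hit = truth_map.get(site)
        if hit is None:
            continue
        if match_alleles and table is not None and hit:
            called = dict(zip(table.isolates, table.alleles[i]))
            if any(
                name in hit and a != "N" and a != hit[name]
                for name, a in called.items()
            ):
                continue
        tp += 1
    detected_n = len(sites)
    truth_n = len(truth_map)
    return BenchmarkResult(
        tp=tp,
        detected=detected_n,
        truth_total=truth_n,
        ppv=(tp / detected_n) if detected_n else None,
        sensitivity=(tp / truth_n) if truth_n else None,
    )


def called_sites_ratio(
    pseudogenomes: Mapping[str, Pseudogenome], reference: SequenceSet
) -> float:
    """Fraction of reference sites called (non-N) in *all* isolates."""
    total = reference.total_length()
    if not pseudogenomes:
        raise ValueError("no pseudogenomes given")
    called = None
    for p in pseudogenomes.values():
        mask = p.called_mask()
        flat = np.concatenate([mask[name] for name in reference.ids])
        called = flat if called is None else (called & flat)
    return int(called.sum()) / total


def common_region_ppv(
    per_tool: Sequence[tuple[object, Mapping[str, np.ndarray]]],
    truth,
) -> list[float | None]:
    """PPV per tool restricted to the region all tools called everywhere.

    Each entry is (detected sites or SnpTable, per-contig boolean mask of
    sites that tool determined for all isolates). The common region is the
    intersection of the masks; each tool's detected sites are filtered to it
    and re-scored. An empty common region yields None for every tool.
    """
    if not per_tool:
        raise ValueError("at least one tool required")
    common: dict[str, np.ndarray] = {}
    for _, mask in per_tool:
        for contig, arr in mask.items():
            common[contig] = arr.copy() if contig not in common else (common[contig] & arr)
    if not any(arr.any() for arr in common.values()):
        return [None] * len(per_tool)
    out = []
    for detected, _ in per_tool:
        sites, _tbl = _detected_sites(detected)
        inside = [
            s for s in sites if s[0] in common and common[s[0]][s[1]]
        ]
        res = score(inside, truth)
        out.append(res.ppv)
    return out


def all_isolate_called_mask(
    pseudogenomes: Mapping[str, Pseudogenome], reference: SequenceSet
) -> dict[str, np.ndarray]:
    """Per-contig mask of sites every isolate called (helper for
    common-region comparisons)."""
    out = {}
    for name in reference.ids:
        masks = [p.called_mask()[name] for p in pseudogenomes.values()]
        out[name] = np.logical_and.reduce(masks)
    return out


def write_metrics_tsv(result: BenchmarkResult, path) -> None:
    """Write the four metrics as percentages with two decimals (undefined
    ratios rendered as '–')."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in result.as_percent_rows():
            fh.write(f"{name}\t{value}\n")
        fh.write(f"tp\t{result.tp}\n")
        fh.write(f"detected\t{result.detected}\n")
        fh.write(f"truth_total\t{result.truth_total}\n")
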