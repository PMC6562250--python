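import numpy as np
import pytest

from pseudosnp import SequenceSet, SimParams, SVSpec, run_pipeline, simulate
from pseudosnp.io_formats import ReadAlignmentRecord


def small_params(seed: int = 7, **overrides) -> SimParams:
    """Desk-scale study conditions used by the unit/property tests: a 30 kbp
    genome with proportionally scaled structural events."""
    kwargs = dict(
        genome_size=30_000,
        identity=0.98,
        n_breaks=4,
        min_region_len=500,
        sv=SVSpec(dup_len=(800, 1500), del_len=(800, 1500), ins_len=(800, 1500)),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_params())


@pytest.fixture(scope="session")
def small_result(small_sim):
    return run_pipeline(small_sim.contigs, small_sim.reads, reference=small_sim.reference)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tiling_reads(
    seqs: SequenceSet,
    read_len: int = 100,
    step: int = 10,
    prefix: str = "t",
) -> list[ReadAlignmentRecord]:
    """Perfect, evenly tiled all-M reads over every contig (depth =
    read_len/step), for deterministic toy pipelines without the simulator."""
    out = []
    for name, seq in seqs:
        for i, start in enumerate(range(0, len(seq) - read_len + 1, step)):
            out.append(
                ReadAlignmentRecord(
                    read_id=f"{prefix}_{name}_{i}",
                    ref_id=name,
                    ref_start=start,
                    ops=[("M", read_len)],
                    seq=seq[start : start + read_len],
                )
            )
    return out
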