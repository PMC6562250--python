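import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudosnp import (
    SequenceSet,
    SiteSupport,
    assembly_allele,
    build_pseudogenome,
    read_mask,
)

from conftest import random_seq, tiling_reads


def sup(n_allele=1, allele="G", d_indel=math.inf, c_all=20, c_allele=20):
    return SiteSupport(n_allele, allele, d_indel, c_all, c_allele)


class TestAssemblyAllele:
    def test_clean_site_determined(self):
        assert assembly_allele(sup(d_indel=7)) == "G"

    def test_two_alleles_masked(self):
        assert assembly_allele(sup(n_allele=2)) is None

    def test_d_indel_boundary_is_strict(self):
        assert assembly_allele(sup(d_indel=5)) is None
        assert assembly_allele(sup(d_indel=6)) == "G"

    def test_unaligned_masked(self):
        assert assembly_allele(sup(n_allele=0, allele=None)) is None


class TestReadMask:
    @pytest.mark.parametrize(
        "c_allele,c_all,kept",
        [
            (10, 11, True),   # 10 >= 10 and 10/11 ~ 0.909 >= 0.9
            (9, 9, False),    # fails depth despite fraction 1.0
            (18, 20, True),   # fraction exactly 0.9
            (17, 20, False),  # 0.85 < 0.9
            (0, 0, False),    # no coverage
        ],
    )
    def test_both_required(self, c_allele, c_all, kept):
        out = read_mask("G", c_all, c_allele)
        assert (out == "G") is kept

    def test_any_mode_keeps_either_condition(self):
        assert read_mask("G", 9, 9, mask_mode="any") == "G"  # fraction 1.0
        assert read_mask("G", 40, 12, mask_mode="any") == "G"  # depth only
        assert read_mask("G", 40, 8, mask_mode="any") is None

    def test_masked_stays_masked(self):
        assert read_mask(None, 100, 100) is None

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40))
    def test_monotone_in_support(self, c_allele, extra):
        """Adding allele-supporting reads can never turn a kept site into a
        masked one."""
        c_all = c_allele + extra
        if read_mask("G", c_all, c_allele) == "G":
            assert read_mask("G", c_all + 1, c_allele + 1) == "G"


def _toy_inputs(rng_seed=0, n=6000, sub_at=None, deletion=None):
    rng = np.random.default_rng(rng_seed)
    ref = random_seq(rng, n)
    genome = list(ref)
    if sub_at is not None:
        genome[sub_at] = "ACGT"[("ACGT".index(genome[sub_at]) + 1) % 4]
    genome = "".join(genome)
    reads = tiling_reads(SequenceSet([("chr", genome)]), read_len=100, step=5)
    if deletion is not None:
        # the isolate lacks ref[deletion); its reads cover everything else
        genome = genome[: deletion[0]] + genome[deletion[1] :]
        reads = [
            r
            for r in reads
            if r.ref_end <= deletion[0] or r.ref_start >= deletion[1]
        ]
    reference = SequenceSet([("chr", ref)])
    contigs = SequenceSet([("iso_c0", genome)])
    return reference, contigs, reads


class TestBuildPseudogenome:
    def test_identity_case(self):
        reference, contigs, reads = _toy_inputs()
        pseudo, table = build_pseudogenome(reference, contigs, reads)
        codes = pseudo.contigs["chr"]
        ref_codes = reference.codes("chr")
        called = codes < 4
        assert (codes[called] == ref_codes[called]).all()
        # depth is 20 away from the ends, so interior sites are all called
        assert called[100:-100].all()

    def test_single_substitution_detected(self):
        reference, contigs, reads = _toy_inputs(sub_at=3000)
        pseudo, _ = build_pseudogenome(reference, contigs, reads)
        codes = pseudo.contigs["chr"]
        ref_codes = reference.codes("chr")
        called = codes < 4
        diffs = np.flatnonzero(called & (codes != ref_codes))
        assert diffs.tolist() == [3000]

    def test_deleted_region_masked(self):
        reference, contigs, reads = _toy_inputs(deletion=(2000, 3000))
        pseudo, _ = build_pseudogenome(reference, contigs, reads)
        codes = pseudo.contigs["chr"]
        assert (codes[2010:2990] == 4).all()

    def test_conflicting_duplicate_masks(self):
        """Two contigs covering the same reference interval with different
        bases mask the disputed site even though only one wins the
        one-to-one contest."""
        rng = np.random.default_rng(9)
        ref = random_seq(rng, 4000)
        copy = list(ref[500:1500])
        copy[500] = "ACGT"[("ACGT".index(copy[500]) + 1) % 4]
        reference = SequenceSet([("chr", ref)])
        contigs = SequenceSet([("iso_c0", ref), ("iso_c1", "".join(copy))])
        reads = tiling_reads(SequenceSet([("chr", ref)]), read_len=100, step=5)
        pseudo, table = build_pseudogenome(reference, contigs, reads)
        assert pseudo.contigs["chr"][1000] == 4  # the conflicting site
        assert table.n_allele("chr")[1000] == 2
        assert pseudo.contigs["chr"][900] < 4  # agreeing sites stay callable

    def test_id_collision_rejected(self):
        reference, contigs, reads = _toy_inputs()
        bad = SequenceSet([("chr", contigs["iso_c0"])])
        with pytest.raises(ValueError, match="collision"):
            build_pseudogenome(reference, bad, reads)

    def test_determinism(self):
        reference, contigs, reads = _toy_inputs(sub_at=1234)
        a, _ = build_pseudogenome(reference, contigs, reads)
        b, _ = build_pseudogenome(reference, contigs, reads)
        assert all(
            np.array_equal(a.contigs[k], b.contigs[k]) for k in a.contigs
        )

    def test_masking_monotonicity(self, small_sim):
        """Raising any masking threshold never converts N into a base."""
        iso = "A1"
        base, _ = build_pseudogenome(
            small_sim.reference, small_sim.contigs[iso], small_sim.reads[iso]
        )
        for kwargs in (
            dict(min_depth=15),
            dict(min_frac=0.95),
            dict(indel_margin=10),
            dict(min_align_len=1000),
        ):
            stricter, _ = build_pseudogenome(
                small_sim.reference, small_sim.contigs[iso], small_sim.reads[iso],
                **kwargs,
            )
            for contig in base.contigs:
                was_n = base.contigs[contig] == 4
                assert (stricter.contigs[contig][was_n] == 4).all()

    def test_support_accessor_consistent(self, small_sim):
        iso = "A2"
        pseudo, table = build_pseudogenome(
            small_sim.reference, small_sim.contigs[iso], small_sim.reads[iso]
        )
        rng = np.random.default_rng(1)
        for pos in rng.integers(0, small_sim.reference.total_length(), 60).tolist():
            s = table.support_at("ref", int(pos))
            decision = read_mask(assembly_allele(s), s.c_all, s.c_allele)
            called = pseudo.contigs["ref"][pos]
            assert ("ACGT"[called] if called < 4 else None) == decision
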