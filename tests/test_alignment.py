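import itertools

import numpy as np
import pytest

from pseudosnp import SequenceSet, align_contigs, liftover, select_one_to_one
from pseudosnp.alignment import LocalAlignment, alignments_from_coords
from pseudosnp.io_formats import CoordsInterval
from pseudosnp._seq import revcomp

from conftest import random_seq


def _single(alns):
    assert len(alns) == 1, [a.ops for a in alns]
    return alns[0]


class TestAlignContigs:
    def test_identical_contig_full_cover(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 10_000)
        alns = align_contigs(
            SequenceSet([("c", ref)]), SequenceSet([("r", ref)])
        )
        a = _single(alns)
        assert (a.ref_start, a.ref_end) == (0, 10_000)
        assert (a.ctg_start, a.ctg_end) == (0, 10_000)
        assert a.identity == 1.0 and a.strand == "+"

    def test_single_substitution(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 4000)
        ctg = ref[:500] + ("A" if ref[500] != "A" else "C") + ref[501:]
        a = _single(
            align_contigs(SequenceSet([("c", ctg)]), SequenceSet([("r", ref)]))
        )
        assert a.identity == pytest.approx((4000 - 1) / 4000)
        # the mismatch column sits exactly at offset 500
        ref_pos, q_pos = a.aligned_pairs
        mism = [int(r) for r, q in zip(ref_pos, q_pos) if ref[r] != ctg[q]]
        assert mism == [500]

    def test_reverse_complement_column_map(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 6000)
        seg = ref[1000:4000]
        ctg = revcomp(seg)
        a = _single(
            align_contigs(SequenceSet([("c", ctg)]), SequenceSet([("r", ref)]))
        )
        assert a.strand == "-"
        assert (a.ref_start, a.ref_end) == (1000, 4000)
        # brute-force oracle: position j of the segment must map to the
        # reverse-complement coordinate len(ctg)-1-j
        for ref_pos in (1000, 1777, 2500, 3999):
            fwd = a.liftover_ref(ref_pos)
            assert fwd == len(ctg) - 1 - (ref_pos - 1000)

    def test_substitution_set_recovered(self):
        """On sequences differing only by substitutions, the mismatch columns
        equal the introduced substitution set exactly."""
        rng = np.random.default_rng(3)
        ref = random_seq(rng, 20_000)
        positions = sorted(rng.choice(20_000, size=200, replace=False).tolist())
        ctg = list(ref)
        for p in positions:
            ctg[p] = "ACGT"[("ACGT".index(ctg[p]) + 2) % 4]
        ctg = "".join(ctg)
        a = _single(
            align_contigs(SequenceSet([("c", ctg)]), SequenceSet([("r", ref)]))
        )
        ref_pos, q_pos = a.aligned_pairs
        mism = [int(r) for r, q in zip(ref_pos, q_pos) if ref[r] != ctg[q]]
        assert mism == positions
        assert not any(op in "ID" for op, _ in a.ops)

    def test_adjacent_substitution_pair_not_gapped(self):
        """A swapped adjacent base pair (ref TC vs contig CT) must align as
        two mismatches, not as an insertion-deletion pair that would trip
        the indel-distance mask."""
        rng = np.random.default_rng(4)
        ref = random_seq(rng, 3000)
        i = 1500
        while ref[i] == ref[i + 1]:
            i += 7
        ctg = ref[:i] + ref[i + 1] + ref[i] + ref[i + 2 :]
        a = _single(
            align_contigs(SequenceSet([("c", ctg)]), SequenceSet([("r", ref)]))
        )
        assert not any(op in "ID" for op, _ in a.ops)

    def test_k_validation(self):
        s = SequenceSet([("a", "ACGT" * 100)])
        with pytest.raises(ValueError, match="k must be"):
            align_contigs(s, s, k=7)


def _stub(ref_start, ref_end, ctg_id="c", ctg_start=None, ctg_len=100_000,
          ref_id="r", matches=None):
    n = ref_end - ref_start
    if ctg_start is None:
        ctg_start = ref_start
    ops = [("=", n)] if matches is None else [("=", matches), ("X", n - matches)]
    return LocalAlignment(
        ref_id=ref_id, ref_start=ref_start, ref_end=ref_end,
        ctg_id=ctg_id, ctg_start=ctg_start, ctg_end=ctg_start + n,
        strand="+", ops=ops, ctg_len=ctg_len,
    )


class TestSelectOneToOne:
    def test_disjoint_both_kept(self):
        m = select_one_to_one([_stub(0, 1000), _stub(2000, 3000, ctg_start=5000)])
        assert len(m.alignments) == 2

    def test_duplication_contest_higher_score_wins(self):
        winner = _stub(0, 2000, ctg_id="c1", matches=1990)
        loser = _stub(0, 2000, ctg_id="c2", matches=1800)
        m = select_one_to_one([loser, winner])
        assert [a.ctg_id for a in m.alignments] == ["c1"]

    def test_min_align_len_filter(self):
        m = select_one_to_one([_stub(0, 900)], min_align_len=1000)
        assert m.alignments == []
        m = select_one_to_one([_stub(0, 1000)], min_align_len=1000)
        assert len(m.alignments) == 1

    def test_disjointness_invariant(self, small_sim):
        alns = align_contigs(small_sim.contigs["A1"], small_sim.reference)
        m = select_one_to_one(alns, 0)
        ref_iv = sorted((a.ref_start, a.ref_end) for a in m.alignments)
        for (s1, e1), (s2, e2) in zip(ref_iv, ref_iv[1:]):
            assert e1 <= s2
        by_ctg = {}
        for a in m.alignments:
            by_ctg.setdefault(a.ctg_id, []).append((a.ctg_start, a.ctg_end))
        for ivs in by_ctg.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_greedy_against_bruteforce_enumeration(self):
        """Compare score-ordered greedy selection against exhaustive subset
        enumeration on small random instances.

        Greedy is not guaranteed to reach the global optimum on conflict
        chains (and this test quantifies the divergence rather than hiding
        it), but it must always produce a maximal disjoint set in which
        every rejected alignment conflicts with a kept alignment of equal
        or higher score - the property that makes a duplicated region
        resolve to its single best placement."""

        def conflicts(x, y):
            return (
                x.ref_id == y.ref_id
                and x.ref_start < y.ref_end
                and y.ref_start < x.ref_end
            ) or (
                x.ctg_id == y.ctg_id
                and x.ctg_start < y.ctg_end
                and y.ctg_start < x.ctg_end
            )

        rng = np.random.default_rng(11)
        divergent = 0
        for _ in range(25):
            alns = []
            for i in range(6):
                start = int(rng.integers(0, 16)) * 1800
                length = int(rng.integers(2, 5)) * 400
                matches = length - int(rng.integers(0, length // 10))
                alns.append(
                    _stub(start, start + length, ctg_id=f"c{rng.integers(0, 3)}",
                          ctg_start=int(rng.integers(0, 16)) * 1800, matches=matches)
                )
            greedy = select_one_to_one(alns, 0, boundary_slop=0)
            kept = greedy.alignments
            rejected = [a for a in alns if a not in kept]
            for a in rejected:
                blockers = [k for k in kept if conflicts(a, k)]
                assert blockers, "rejected alignment conflicts with nothing kept"
                assert max(k.score for k in blockers) >= a.score
            for a in kept:
                assert not any(conflicts(a, k) for k in kept if k is not a)

            best = max(
                sum(a.score for a in sub)
                for k in range(len(alns) + 1)
                for sub in itertools.combinations(alns, k)
                if not any(conflicts(x, y) for x, y in itertools.combinations(sub, 2))
            )
            greedy_score = sum(a.score for a in kept)
            assert greedy_score <= best + 1e-9
            if greedy_score < best - 1e-9:
                divergent += 1
        # greedy reaches the exhaustive optimum on the vast majority of
        # instances; a systematic failure would show up here
        assert divergent <= 5

    def test_boundary_overlap_trimmed_not_rejected(self):
        big = _stub(0, 5000, ctg_id="c1", matches=4999)
        # a second, lower-scoring alignment overlapping the first by 3 bp
        small = _stub(4997, 7000, ctg_id="c2", ctg_start=0, matches=1900)
        m = select_one_to_one([big, small])
        kept = {a.ctg_id: a for a in m.alignments}
        assert set(kept) == {"c1", "c2"}
        assert kept["c2"].ref_start == 5000  # trimmed to abut, not rejected


class TestLiftover:
    def test_identity_alignment(self):
        a = _stub(0, 100)
        assert liftover(a, "ref", 42) == 42

    def test_deletion_gap_returns_none(self):
        a = LocalAlignment(
            ref_id="r", ref_start=0, ref_end=13, ctg_id="c", ctg_start=0,
            ctg_end=10, strand="+", ops=[("=", 5), ("D", 3), ("=", 5)],
            ctg_len=10,
        )
        assert liftover(a, "ref", 6) is None
        assert liftover(a, "ref", 8) == 5

    def test_round_trip_and_injectivity(self, small_sim):
        alns = align_contigs(small_sim.contigs["A2"], small_sim.reference)
        m = select_one_to_one(alns, 0)
        rng = np.random.default_rng(5)
        seen = set()
        ref_len = small_sim.reference.total_length()
        hits = 0
        for pos in rng.choice(ref_len, size=400, replace=False).tolist():
            fwd = liftover(m, "ref", int(pos), seq_id="ref")
            if fwd is None:
                continue
            hits += 1
            assert fwd not in seen  # injectivity
            seen.add(fwd)
            back = liftover(m, "ctg", fwd[1], seq_id=fwd[0])
            assert back == ("ref", int(pos))
        assert hits > 100


class TestCoordsReconstruction:
    def test_forward_and_reverse(self):
        rng = np.random.default_rng(6)
        ref = random_seq(rng, 5000)
        refs = SequenceSet([("r", ref)])
        ctgs = SequenceSet(
            [("cf", ref[1000:2000]), ("cr", revcomp(ref[3000:4000]))]
        )
        coords = [
            CoordsInterval("r", 1000, 2000, "cf", 0, 1000, 1.0, "+"),
            CoordsInterval("r", 3000, 4000, "cr", 0, 1000, 1.0, "-"),
        ]
        alns = alignments_from_coords(coords, ctgs, refs)
        assert all(a.identity == 1.0 for a in alns)
        fwd, rev = alns
        assert fwd.liftover_ref(1500) == 500
        assert rev.liftover_ref(3000) == 999
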