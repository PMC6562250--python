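import numpy as np
import pytest

from pseudosnp import (
    SimParams,
    SVSpec,
    evolve_isolates,
    fragment_contigs,
    make_reference_root_pair,
    simulate,
    simulate_reads,
)
from pseudosnp.simulator import _streams

from conftest import small_params

NO_SV = SVSpec(n_duplications=0, n_deletions=0, n_insertions=0)


class TestReferenceRootPair:
    def test_identity_one_no_svs(self):
        p = SimParams(genome_size=5000, identity=1.0, sv=NO_SV, seed=0)
        pair = make_reference_root_pair(p)
        assert pair.reference["ref"] == pair.root["root"]
        assert (pair.root2ref == np.arange(5000)).all()

    def test_substitution_count_binomial(self):
        L, rate = 100_000, 0.01
        counts = []
        for seed in range(4):
            p = SimParams(genome_size=L, identity=1 - rate, sv=NO_SV, seed=seed)
            pair = make_reference_root_pair(p)
            diff = sum(
                a != b for a, b in zip(pair.reference["ref"], pair.root["root"])
            )
            counts.append(diff)
        mean, sd = L * rate, np.sqrt(L * rate * (1 - rate))
        for c in counts:
            assert abs(c - mean) < 4 * sd

    def test_duplication_extends_reference(self):
        sv = SVSpec(n_duplications=1, dup_len=(5000, 5000), n_deletions=0,
                    n_insertions=0)
        p = SimParams(genome_size=50_000, identity=0.99, sv=sv, seed=1)
        pair = make_reference_root_pair(p)
        assert len(pair.reference["ref"]) == 55_000

    def test_oversized_events_rejected(self):
        sv = SVSpec(n_deletions=3, del_len=(2000, 2000), n_duplications=0,
                    n_insertions=0)
        p = SimParams(genome_size=5000, identity=0.99, sv=sv, seed=0)
        with pytest.raises(ValueError):
            make_reference_root_pair(p)

    def test_identity_validation(self):
        with pytest.raises(ValueError, match="identity"):
            SimParams(identity=0.8)


class TestEvolveIsolates:
    def test_zero_means_identical_leaves(self):
        p = SimParams(genome_size=3000, sub_mean=0, ins_mean=0, del_mean=0,
                      sv=NO_SV, seed=2)
        pair = make_reference_root_pair(p)
        evo = evolve_isolates(pair.root_codes, p)
        for iso in evo.isolates.values():
            assert np.array_equal(iso.codes, pair.root_codes)

    def test_edge_count_and_tree_shape(self):
        p = SimParams(genome_size=2000, sv=NO_SV, seed=3)
        pair = make_reference_root_pair(p)
        evo = evolve_isolates(pair.root_codes, p)
        assert len(evo.edges) == 2 * p.n_isolates - 2
        assert evo.tree_newick.endswith(";")
        import dendropy

        tree = dendropy.Tree.get(data=evo.tree_newick, schema="newick")
        leaves = sorted(t.taxon.label for t in tree.leaf_node_iter())
        assert leaves == sorted(f"A{i + 1}" for i in range(p.n_isolates))

    def test_per_edge_means(self):
        """Pooled per-edge variant counts match the configured means
        (~10 substitutions, ~1 insertion, ~0.25 deletions)."""
        p = SimParams(genome_size=2000, sv=NO_SV, seed=4)
        subs, ins, dels = [], [], []
        rng_tree = np.random.default_rng(100)
        rng_var = np.random.default_rng(200)
        for _ in range(60):  # 60 trees x 18 edges = 1080 edges
            root = np.random.default_rng(1).integers(0, 4, 2000).astype(np.uint8)
            evo = evolve_isolates(root, p, rng_tree, rng_var)
            for e in evo.edges:
                subs.append(e.n_sub)
                ins.append(e.n_ins)
                dels.append(e.n_del)
        n = len(subs)
        assert n >= 1000
        for values, mean in ((subs, 10.0), (ins, 1.0), (dels, 0.25)):
            sample = np.mean(values)
            se = np.std(values) / np.sqrt(n)
            assert abs(sample - mean) <= 4 * se


class TestRelocation:
    def test_sites_confined_to_qualifying_regions(self, small_sim):
        regions = small_sim.truth.regions
        for _, row in small_sim.truth.snp_sites.iterrows():
            rp = int(row.ref_pos)
            inside = (
                (regions.ref_start <= rp) & (rp < regions.ref_end)
            ).any()
            assert inside
            assert rp >= 0  # every site lifted to a reference coordinate

    def test_truth_sites_polymorphic(self, small_sim):
        names = small_sim.truth.isolate_names
        for _, row in small_sim.truth.snp_sites.iterrows():
            distinct = {row[n] for n in names if row[n] != "-"}
            assert len(distinct) >= 2

    def test_alleles_consistent_with_genomes(self, small_sim):
        names = small_sim.truth.isolate_names
        for _, row in small_sim.truth.snp_sites.head(40).iterrows():
            rp = int(row.root_pos)
            for n in names:
                iso = small_sim.truth.isolates[n]
                if row[n] == "-":
                    assert iso.deleted[rp]
                else:
                    ip = iso.root2iso[rp]
                    assert iso.sequence[ip] == row[n]


class TestReads:
    def _isolates(self, params):
        pair = make_reference_root_pair(params)
        return evolve_isolates(pair.root_codes, params).isolates

    def test_zero_error_reads_exact(self):
        p = SimParams(genome_size=4000, sv=NO_SV, error_rate=0.0, n_isolates=2,
                      seed=5)
        isolates = self._isolates(p)
        raws = simulate_reads(isolates, p)
        for name, raw in raws.items():
            doubled = np.concatenate([isolates[name].codes] * 2)
            for i in range(0, len(raw.r1_start), 31):
                s = raw.r1_start[i]
                assert np.array_equal(raw.r1_codes[i], doubled[s : s + p.read_len])

    def test_pair_count_arithmetic(self):
        p = SimParams(genome_size=100_000, sv=NO_SV, coverage=20.0, read_len=150,
                      n_isolates=2, seed=6)
        raws = simulate_reads(self._isolates(p), p)
        for raw in raws.values():
            assert len(raw.r1_start) == round(20.0 * 100_000 / 300)

    def test_error_rate_calibrated(self):
        p = SimParams(genome_size=50_000, sv=NO_SV, error_rate=0.01,
                      n_isolates=2, seed=7)
        isolates = self._isolates(p)
        raws = simulate_reads(isolates, p)
        raw = raws["A1"]
        doubled = np.concatenate([isolates["A1"].codes] * 2)
        window = np.arange(p.read_len)
        truth = doubled[raw.r1_start[:, None] + window]
        frac = (truth != raw.r1_codes).mean()
        n = raw.r1_codes.size
        sd = np.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) < 4 * sd

    def test_read_longer_than_fragment_rejected(self):
        with pytest.raises(ValueError, match="fragment"):
            SimParams(read_len=300, frag_mean=200.0)

    def test_placements_reproduce_isolate_bases(self, small_sim):
        """Reference-frame truth placements put each aligned read base at a
        reference site whose true isolate base equals the read base except
        for the ~0.5% sequencing errors."""
        from pseudosnp._seq import encode

        iso = "A4"
        m = small_sim.iso_to_ref_map(iso)
        truth = small_sim.truth.isolates[iso]
        inv = np.full(small_sim.reference.total_length(), -1, dtype=np.int64)
        src = np.flatnonzero(m >= 0)
        inv[m[src]] = src
        agree = total = 0
        for rec in small_sim.reads[iso][:500]:
            codes = encode(rec.seq)
            r, q = rec.ref_start, 0
            for op, n in rec.ops:
                if op == "M":
                    iso_pos = inv[r : r + n]
                    ok = iso_pos >= 0
                    total += int(ok.sum())
                    agree += int(
                        (truth.codes[iso_pos[ok]] == codes[q : q + n][ok]).sum()
                    )
                    r += n
                    q += n
                elif op == "D":
                    r += n
                else:
                    q += n
        assert total > 10_000
        assert agree / total > 0.985


class TestFragmentContigs:
    def _isolates(self, **kw):
        p = small_params(**kw)
        pair = make_reference_root_pair(p)
        return p, evolve_isolates(pair.root_codes, p).isolates

    def test_zero_breaks_identity(self):
        p, isolates = self._isolates(seed=8, n_breaks=0)
        contigs = fragment_contigs(isolates, p)
        for name, iso in isolates.items():
            assert contigs[name].records == [(f"{name}_c00", iso.sequence)]

    def test_concatenation_reconstructs_genome(self):
        p, isolates = self._isolates(seed=9, n_breaks=5)
        contigs = fragment_contigs(isolates, p)
        for name, iso in isolates.items():
            joined = "".join(s for _, s in contigs[name])
            assert joined == iso.sequence

    def test_min_length_respected(self):
        p, isolates = self._isolates(seed=10, n_breaks=40, min_contig_len=1000)
        contigs = fragment_contigs(isolates, p)
        for cs in contigs.values():
            assert all(len(s) >= 1000 for _, s in cs)


class TestDeterminism:
    def test_byte_reproducible(self):
        p = small_params(seed=12, genome_size=12000, n_isolates=4)
        a = simulate(p)
        b = simulate(p)
        assert a.reference["ref"] == b.reference["ref"]
        assert a.truth.tree_newick == b.truth.tree_newick
        assert a.truth.snp_sites.equals(b.truth.snp_sites)
        for iso in a.truth.isolates:
            assert a.truth.isolates[iso].sequence == b.truth.isolates[iso].sequence
            assert np.array_equal(a.raw_reads[iso].r1_codes, b.raw_reads[iso].r1_codes)
            assert a.contigs[iso].records == b.contigs[iso].records

    def test_substreams_are_named_and_stable(self):
        s = _streams(123)
        assert list(s) == ["pair", "tree", "variants", "relocation", "reads",
                           "fragmentation"]
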