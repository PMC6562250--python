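# Methods

This note documents the models, parameters and numerical choices behind
`pseudosnp`: the pseudogenome-based SNP caller, the contig–reference
aligner it relies on, and the benchmark simulator used to exercise both.

## The calling model

SNPs are defined among isolates, on the coordinate frame of a reference
genome (complete, draft, or one isolate's own assembly in reference-free
mode). Per isolate the pipeline is a composition of two decisions at every
reference site.

**Assembly-side allele determination.** The isolate's contigs are aligned
to the reference and reduced to a one-to-one map (disjoint intervals on
both sequences). A site receives the aligned contig base iff
(1) `n_allele = 1` — exactly one distinct contig base aligns there, counted
over *all* length-filtered alignments, not only the one-to-one winners, so
that ambiguity evidence from a duplicate placement still masks a site — and
(2) `d_indel > indel_margin` (default 5 bp), the distance to the nearest
gap column of the covering alignment, measured in reference coordinates;
contig-gap columns count at their own position and insertion columns at
the half-position between their flanking reference sites, with distances
rounded up. Sites that are unaligned, deleted in the isolate, or covered
only by an `N` contig base are masked. The 5 bp margin is deliberately
strict (`d_indel = 5` masks): alignment columns adjacent to gaps are where
gap-placement ambiguity puts wrong alleles.

**Read-support masking.** Reads mapped to the reference (duplicate
fragments removed, keeping the highest mapping quality per
(contig, start, end, orientation)) yield per-site depths. A determined
allele is kept iff (3) `c_allele >= min_depth` (default 10) and
(4) `c_allele / c_all >= min_frac` (default 0.9). Both conditions are
required by default; the sentence defining the masking rule admits an
"either suffices" reading, preserved as `mask_mode="any"`. Zero coverage
always masks. Base qualities are ignored — the conditions are depth
conditions — and `min_mapq` defaults to 0 (no mapping-quality filter),
exposed only to document the knob. The fraction test uses the literal
division `c_allele / c_all >= min_frac`, so the printed boundary cases
behave exactly as stated (10/11 passes, 18/20 passes, 17/20 fails).

A site is a SNP site iff the per-isolate alleles contain at least two
distinct non-`N` values; a site where all isolates agree against the
reference is not a SNP. By default sites with some `N` cells are reported
(`require_complete=False`); the alignment FASTA always contains every
site, leaving complete deletion to the downstream consumer.

## The aligner

A desk-scale seed-chain-extend aligner produces the gapped local
alignments. Exact k-mer anchors (default `k=17`, both strands, k-mers
occurring more than `max_occ=8` times in the reference dropped) are merged
along diagonals into maximal exact matches and chained by dynamic
programming under a collinearity constraint. The chain-gap limits are
asymmetric on purpose: the contig-side limit (300 bp) only needs to bridge
small isolate indels and anchor deserts, while the reference-side limit
(6 kbp) lets a chain jump reference-only content — an inserted segment or
a tandem duplicate copy — as a clean deletion op. Without the asymmetry, a
lower-identity "merged" chain through the homologous copy can win and
shift the coordinate frame for some isolates, which is exactly how
spurious between-isolate differences arise near duplications. Gaps between
chained anchors are closed by global edit-distance alignment (edlib);
chain ends are extended by an ungapped X-drop walk (mismatch −3, drop 12,
capped at 500 bp) that always terminates on a match.

Two post-processing details matter for correctness:

* **Gap-pair canonicalization.** Unit-cost edit alignment represents two
  adjacent substitutions such as reference `TC` against contig `CT` as a
  deletion plus an insertion at the same cost as two mismatches, and the
  spurious gap would then trip the `d_indel` mask at the very site of a
  real substitution. Between match runs of ≥ 6 bp, any short (≤ 30 bp
  reference span) segment whose insertions and deletions balance exactly
  is rewritten as direct base-to-base columns iff that does not increase
  the edit cost — genuine nearby indel pairs cost more when degapped and
  are left alone.
* **Boundary-slop selection.** One-to-one selection is greedy by score
  (aligned columns × identity, which equals the match count), ties broken
  by reference start then contig id. A candidate that overlaps an already
  kept alignment is rejected whole — the behavior that resolves a
  duplicated region to its single best placement — *except* when the
  overlap is a boundary overlap of at most 20 bp in total, in which case
  it is trimmed off the candidate. Where two correct alignments abut at a
  structural breakpoint their end columns are ambiguous by a few bases
  (the flanking base matches by chance), and rejecting a multi-kilobase
  alignment over a 1 bp overlap would mask kilobases of callable sequence.

Greedy selection is not guaranteed to maximize total score on adversarial
conflict chains; the test suite checks instead the properties the caller
relies on: disjointness on both sequences, maximality, and that every
rejected alignment conflicts with a kept alignment of equal or higher
score. `liftover` maps positions through an alignment or a one-to-one map
and returns nothing inside gap columns.

Externally computed alignments (nucmer `show-coords -T` tables) can
substitute for the internal aligner; each coordinate interval pair is
re-gapped by global edit alignment and canonicalized the same way.

## The simulator

The generator reproduces the benchmark situation end to end at desk scale.
Default problem sizes were chosen so a full four-identity, three-seed
benchmark runs in about two minutes on one CPU; all per-site logic is
scale-invariant.

* **Reference–root pair.** The root is a uniform-random sequence
  (default 200 kbp; the real genomes the benchmark emulates are ~2.8 Mbp).
  The reference carries substitutions at rate `1 − identity`
  (identities 0.97–0.999) plus explicit structural events: by default 2
  duplications (1–5 kbp, tandem with probability 0.5), 2 deletions and 2
  insertions (1–5 kbp each). Duplicate copies receive +3 % divergence on
  top of the pair rate, as for an aged paralog; this also keeps the
  original copy every isolate's unambiguous best alignment target, making
  the detected coordinate frame deterministic. Identical copies would make
  placement between copies a coin flip for real aligners too — the masking
  conditions handle that case, but a benchmark whose *truth coordinates*
  depend on the flip would be ill-posed.
* **Isolates.** Ten leaves of a random bifurcating tree (successive random
  joins; 2n−2 = 18 edges). Per edge, substitution/insertion/deletion
  counts are Poisson with means 10 / 1 / 0.25 and indel lengths are
  1–10 bp uniform. Only the means are calibrated; the event model is the
  package's own.
* **Substitution relocation.** Substitution positions are re-drawn
  uniformly (without within-edge collision) from root positions that lie
  on aligned columns of the root–reference one-to-one map — computed with
  the package's own aligner, alignments ≥ 1 kbp — at least 7 bp from any
  gap column, and whose column coordinate agrees with the true
  root-to-reference map. The last filter excludes homology-confused
  columns (a root site paired with a diverged duplicate copy), which would
  make the truth's reference coordinate ambiguous. Every true SNP site
  therefore lifts to a well-defined reference coordinate.
* **Reads.** Paired-end 150 bp, fragments Normal(400, 40), coverage 20×,
  flat substitution-only error rate 0.5 % (no indel errors, no quality
  profile — the masking conditions never read qualities). The chromosome
  is treated as circular, as bacterial chromosomes are: fragments may span
  the origin, and such reads are placed as split, soft-clipped records; on
  a linear desk-scale sequence the end-coverage ramp would be a ~14×
  inflated artifact relative to a 2.8 Mbp genome. Reads come with truth
  placements in the reference frame via the composed
  isolate→root→reference coordinate map (interior unmappable runs ≤ 50 bp
  become insertions; reference jumps > 100 bp and end-touching unmappable
  runs become soft-clips; fully unmappable reads are dropped). These
  placements stand in for a read mapper, which also means mapping is
  *easier* than in real data: every read sits at its true locus, so
  mapping-ambiguity false positives (e.g. reads from identical repeats)
  are under-represented; the assembly-side conditions, not the placements,
  carry the burden of rejecting duplication artifacts here.
* **Contigs.** Each isolate genome is cut at 15 random positions into
  contigs ≥ 1 kbp (optional end trimming, default off) — a stand-in for a
  fragmented de novo assembly with ideal per-contig sequence.

All randomness flows from one seed through six named substreams (pair,
tree, variants, relocation, reads, fragmentation); the whole truth set is
byte-reproducible.

**What passing the benchmark does and does not show.** The simulator
reproduces the structural-variant geometry that defeats mapping-only
callers and the depth/error statistics of the stated conditions, so zero
false positives and ≥ 97.7 % sensitivity on it exercise the masking logic
end to end. It does not model real mapper ambiguity, indel sequencing
errors, coverage bias, contamination, or recombination — results on it
bound real-data behavior from the favorable side.

## Evaluation metrics

PPV = true-positive detected SNP sites / all detected sites; sensitivity =
true positives / all true sites; called-sites ratio = sites non-`N` in all
isolates / reference length; common-region PPV = PPV recomputed inside the
intersection of all compared tools' fully-called regions. A detected site
is a true positive iff its reference coordinate is a truth coordinate
(position-level matching; `match_alleles=True` additionally requires every
non-`N` detected allele to equal the truth allele). Duplicate detected
sites count once. Ratios with zero denominator are undefined and rendered
as "–" in the metrics table.

Soft-clip regions — reference intervals where clipped reads are dense,
the classic footprint of structural variation and a known source of false
positives in mapping-based callers — are detected with explicit surrogate
parameters (breakpoint fraction ≥ 0.5 of overlapping reads, ≥ 5 clipped
reads, seeds merged within 10 bp). These thresholds are configuration, not
calibration: no published definition of the region-finding procedure was
available to match, so they must not be read as reproducing one.

## Degenerate inputs and tie-breaks

Non-ACGT input bases become `N` on read-in and can never be reported as an
allele. Empty alignments, empty SNP tables and zero-FP classifications are
well-defined (header-only TSV, "–" renderings). Greedy-selection ties
break deterministically (reference start, then contig id); simulator dict
orders are insertion orders; identical inputs give identical outputs, and
the test suite asserts byte-reproducibility of the simulator and
determinism of the pipeline.

## Problem sizes used by the checks

The packaged verification runs use 200 kbp genomes for the twelve-run
benchmark matrix (four identities × three seeds), 20–50 kbp instances for
the brute-force per-site oracle comparison, and 1 800 pooled tree edges
for the variant-rate calibration. These sizes are the package's own
defaults for desk-scale validation; every per-site rule is independent of
genome length.

## Known limitations

The aligner is a desk-scale tool: anchor chaining is quadratic in anchors
per contig with a bounded lookback, and chromosome-scale performance was
not a goal. Reference-free mode requires read alignments in the
pseudo-reference's frame. The simulator's read placements bypass a real
mapper (see above). Indels and larger variants are deliberately not
called — masked sites are the output's honesty mechanism, and the
called-sites ratio quantifies its cost.
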