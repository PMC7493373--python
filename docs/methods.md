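# Methods

## Model and data structures

The classifier operates on the extended Burrows–Wheeler transform of a joint
collection of r reads followed by g genomes. Each sequence S_j is terminated
by its own end-marker $_j; markers sort below every alphabet symbol and among
themselves by sequence index. This makes the suffix order total (ties between
otherwise-equal suffixes break by sequence index), so the index — eBWT string,
document array `da`, LCP array — is a deterministic function of the input
order. Positions are 1-based in the public contract (`ebwt[1..N]`,
`lcp[1..N+1]`, `lcp[1] = lcp[N+1] = 0`); the backing numpy arrays are 0-based,
and serialization (`.ebwt` raw bytes with markers as `#`, `.da`/`.lcp`
little-endian uint32, `.meta.json`) documents that layout. Users substituting
externally built indexes must match the distinct-marker convention.

Construction encodes the concatenated marker-terminated sequences as one
integer array (marker of sequence j ↦ j, base c ↦ m + ord(c)) and sorts
suffixes by prefix doubling (numpy lexsort, O(N log² N)), with LCPs by
Kasai's algorithm. Because markers are distinct, position-unique symbols,
suffix comparisons and LCPs of the concatenation coincide exactly with those
of the individual terminated sequences. The test suite verifies the builder
bit-for-bit against a naive sorted-suffix-list oracle on random collections;
N ≈ 10⁵ builds in well under a second, which covers the intended desk scale.
External-memory construction and dynamic insertion of sequences are out of
scope.

IUPAC ambiguity codes are first-class alphabet symbols, not placeholders:
they survive loading, reverse complementation (set-wise complement, an
involution), indexing, and take part in similarity scoring.

## α-clusters and similarity

Cluster detection is a single streaming pass over `lcp`/`da` with O(1) state
per open run (start, seen-read flag, seen-genome flag). Maximality is forced
by the boundary conditions `lcp[pS] < α`, `lcp[pE+1] < α`; blocks without
both a read and a genome color are dropped. No constraint is placed on
cluster size. End-marker suffixes have LCP 0 on both sides and therefore
never extend a run (asserted by a test).

The eBWT measure matches symbols per cluster in two phases: exact per-symbol
minima first (every symbol matches itself, ambiguity codes included — and all
end-markers count as one shared symbol here, so a read suffix and a genome
suffix that both sit immediately after their sequence starts match), then
δ_IUPAC on the residuals: the maximum number of one-to-one pairings between a
residual ambiguity code on one side and a residual concrete base of its code
set on the other. Code-to-different-code pairs are not compatible, and
markers are excluded from this phase. δ_IUPAC is computed as an integral
maximum flow on the small bipartite symbol graph (scipy); a greedy pairing
could undercount when two codes compete for the same bases, whereas maximum
matching is order-independent and deterministic. The DA measure uses per-color
position totals only (markers included — it never consults the eBWT string).

Raw scores satisfy 0 ≤ S^eBWT ≤ S^DA ≤ min(nᵢ, nⱼ) + 1 − α and are
normalized by that bound. When α exceeds min(nᵢ, nⱼ) the denominator is
non-positive; the matrix entry is then defined as 0 (no cluster can involve
that pair anyway). Matrix accumulation is order-independent, so identical
inputs give bit-identical matrices.

## Classification

Key parameters: α (minimum context length, default 16 — chosen for 100 bp
reads, long enough that random 16-mer sharing between unrelated sequences is
rare, short enough that a read retains ~85 informative contexts), β (minimum
normalized similarity, default 0.25), tolerance (absolute slack on normalized
scores, default 0.02), minimum rank (default species), lineage fallback
(default off).

Decisions made where the procedure is underdetermined:

* Mate pairing is fixed to FR orientation: 1F pairs with 2RC, 1RC with 2F;
  phase 2/3 scores take the better strand pairing, never the sum of all four.
* "Approximately equal to the maximum" is one-sided: score ≥ M − tolerance.
* M ≤ β (inclusive) yields not-classified.
* The 0.02 tolerance is applied uniformly in phases 1–3, including the
  uniqueness tests on the mate-sum maxima M′ and M″; exact-max behavior is
  available by setting tolerance to 0.
* Mate sums use normalized scores, consistent with M.
* "Same taxonomic unit at the minimum rank" resolves each candidate genome to
  its ancestor at exactly that rank; with fallback enabled, unresolved
  phase-3 ties walk the rank ladder upward (genus → … → phylum) and classify
  at the first rank where the tied genomes agree, else remain ambiguous.
* Ties surviving phase 3 with fallback off are reported ambiguous together
  with the tied taxid list.

The taxonomy is a parent-pointer tree over the fixed ladder genome < species
< genus < family < order < class < phylum; genomes are leaf taxa of rank
"genome" under their species. Nodes of rank "no_rank" are transparent during
lineage walks — how unranked intermediates should be treated is genuinely
open, and transparency keeps rank resolution independent of bookkeeping
nodes. β is monotone by construction: raising it can only shrink the
classified set.

## Synthetic data

The simulator emulates the structure of the data the method targets —
Illumina-style 100 bp paired-end reads in FR orientation — at desk scale:
i.i.d. uniform A/C/G/T genomes (default 5 × 10 kb), uniform source genome and
locus per pair, a fixed insert (default 300 bp), substitution-only errors
(default 1%; indels would only shorten shared contexts, and the similarity
computation is context-exact, so they add nothing to what the tests can
show), and negative controls built by uniformly permuting real reads —
composition preserved, all long contexts destroyed. A toy taxonomy places
each genome under its own species by default, with a parameter to force
same-species genome pairs; consecutive species share a genus so lineage
fallback is exercisable. The locus stream and the error stream use separate
seeded generators, so runs differing only in substitution rate produce
aligned reads.

What this does not emulate: real base-composition bias, repeat structure and
shared homology between genomes, coverage variation, quality-correlated
errors, indels, and chimeric fragments. Passing tests therefore demonstrate
correctness of the computation and the expected qualitative behavior
(recovery of source species, rejection of shuffled reads, β monotonicity) —
not field accuracy on real metagenomes.

The end-to-end recovery experiment uses 500 pairs from five distinct-species
10 kb genomes at 1% substitution plus 100 shuffled negative-control pairs;
with α = 16, β = 0.25 this classifies ≥ 95% of pairs to the correct species
and ≤ 1% of controls, running in seconds. These sizes keep the whole suite
fast while leaving the per-read signal-to-noise ratio (shared 16-mers vs
random collisions) in the same regime as full-scale data.

## Numerical and degenerate-input notes

* All randomness flows through seeded numpy generators; every pipeline stage
  is deterministic given its inputs.
* Scores are IEEE doubles derived from integer accumulators divided by
  integer denominators; tolerance comparisons use plain ≥ with the exact
  stored values.
* An empty cluster list yields a zero matrix, not an error; a collection with
  only reads or only genomes is rejected at detection time.
* Metrics with zero denominators (e.g., specificity with no negative
  controls) are reported as undefined (None), never as 0.

## Known limitations

* The naive-scale builder targets collections up to a few hundred kilobases;
  it is not a replacement for external-memory eBWT construction on
  gigabase-scale references.
* Similarity matrices are dense in memory (r × g doubles plus integer
  accumulators); streaming one-read-at-a-time operation is not implemented,
  though the per-cluster accumulation would permit it.
* Abundance estimation, confidence scores beyond the normalized similarity,
  and re-assignment of ambiguous reads by priors are out of scope.
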