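# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and canonical frame

All public coordinates are 1-based inclusive, matching GenBank flat
files and published repeat tables. Intervals crossing the origin of the
linearised circle carry an explicit `wraps` flag. Internally the code
converts to 0-based half-open indices; that conversion is never exposed.

Downstream analyses work in a **canonical frame**: the record rotated
and/or reverse-complemented so the traversal order is
LSC → IRb → SSC → IRa with the LSC starting at base 1 and, when *ycf1*
is annotated, its 5′ end inside IRa. Junction positions are reported as
the IR-side base at each boundary (J_LB = first base of IRb, J_SB = last
base of IRb, J_SA = first base of IRa, J_LA = last base of IRa in the
canonical frame), which is well defined for any deposited orientation.
Because every summary is computed in this frame, partition lengths,
junction profiles, J_SA types and gene statuses are invariant under
rotation and strand flip of the input — a property the tests assert
directly.

## IR detection

`detect_quadripartite` finds the longest pair of disjoint **exact**
inverted-repeat copies on the circle by seed-and-extend over shared
21-mers between the doubled sequence and its reverse complement,
followed by exact per-diagonal run extension. Hand-finished plastome
assemblies have identical IR copies by construction, so exact matching
is the right default; a record with slightly divergent copies yields the
largest identical core rather than a silently extended one. The
`min_ir_len` default of 1,000 bp sits far below real plastid IRs
(26–33 kb in the family this package grew out of) and above incidental
repeats. Ties between equally long maximal pairs break to the smallest
start coordinate, with a warning. Absence of any qualifying pair returns
`None` (the explicit no-IR result), not an exception. N bases never
match.

## Junction typing

The J_SA classes are defined by the 5′ portion of *ycf1* inside IRa:
roughly 1 kb in the ancestral arrangement (Type A), 2.6–2.7 kb after a
moderate expansion (Type B), and full containment — together with
formerly single-copy neighbours such as *rps15* and a pseudogenised
*ndhH* — after a large one (Type C). The A/B divide is set at
**2,000 bp**, bisecting the gap between the observed ranges; the raw bp
value is always reported alongside the label so a different cut costs
nothing. Type C is triggered solely by full containment. A record
without an annotated *ycf1* yields `unclassifiable` with a diagnostic.

## Expansion reconstruction

`diff_junctions` compares a derived genome to an ancestral-like
reference (taken as given; no phylogenetic polarisation is attempted).
The shared ancestral IR is the longest common suffix of the two
canonical IRa sequences — expansions prepend sequence at the J_SA end —
and the derived-only portion is decomposed by maximal exact-match
chaining (k = 16 seeds, greedy longest-first, overlaps trimmed) against
the reference genome, both strands. Pieces contiguous in both genomes
(gaps ≤ 10 bp) merge into one event; unmatched runs ≥ 16 bp become
events flagged as untraceable. Events are reported 5′→3′ along IRa,
newest first, each with the reference interval, the genes it overlaps,
and its size.

Mechanism labelling is a **hypothesis, not a proof**: for each event the
±500 bp neighbourhoods of its outer (new-junction) and inner
(old-junction) boundaries are scanned for shared repeats at the
junction-repeat settings (≥ 16 bp, ≤ 10 % mismatch, both directions);
any qualifying pair makes the event `repeat_mediated`, otherwise it is
`dsb_or_other` (double-strand-break copy-repair or an unresolved
mechanism). Note that ~1 kb windows of random sequence contain such a
pair a noticeable fraction of the time, so a chance repeat can
legitimately flip the label — the evidence list always accompanies it.

Exact-match chaining assumes recent events (near-identical copies),
which holds for within-genus comparisons; `map_segment_origin` covers
the diverged case with Smith–Waterman local alignment (match +1,
mismatch −1, gap open −2, gap extend −1, both strands), reporting the
best placement with its identity and feature context ("geneLeft-geneRight
spacer" for intergenic placements). Placements below 0.8 identity or
covering less than half the segment are "unplaced" — the coverage floor
exists because a bare identity cut would accept any chance
micro-homology a local aligner finds.

## Gene status

Presence is measured by **sequence**, not annotation: annotations of
degraded genes are unreliable. Maximal exact matches (≥ 30 bp) between
the reference CDS and both genome strands are collected via a 16-mer
genome index; loci whose exact coverage is patchy (< 95 % of the locus
span — a diverged copy rather than a clean truncation) are re-scored by
local alignment and accepted at identity ≥ 0.7 over ≥ 30 bases. Coverage
is the fraction of reference positions covered by the union of accepted
matches. The reference panel takes, per gene, the most common intact CDS
length across the supplied records (ties to the longest) with one
exemplar sequence.

Classification order: coverage < 0.30 → **lost** (strict `<`, so a copy
at exactly 30 % is not lost); else internal stop, missing terminal stop,
or a length differing from the reference by a non-multiple of three →
**pseudogene**; else N content → **uncertain**; else **intact**.
Accepted start codons are ATG and GTG, the latter flagged as
non-canonical evidence; a missing start is recorded as evidence but does
not by itself demote a gene. RNA editing is not modelled: a missing stop
is a pseudogene call even where C-to-U editing might create the stop in
vivo. The `uncertain` class exists for N-containing regions where a call
would be guesswork (scaffolded-contig artefacts). Seed-based matching
assumes locally ≥ ~95 % identity, typical of recently degraded plastid
genes; remnants below ~90 % identity may be under-covered and drift
toward "lost".

## Repeats

Dispersed repeats use an ungapped Hamming model (equal-length blocks,
forward or inverted, N never matches) with mismatch budget
`floor(frac · L)` — at the default 10 % this accepts 1 mismatch at
17–18 bp and rejects 2 at 17 bp. The scan reports every **single-step
maximal** window per comparison diagonal: a window such that neither
one-base extension (whose budget is `floor(frac · (L+1))`) stays valid
and in bounds. This definition is deliberately simple enough for an
independent brute-force oracle to mirror exactly; with cumulative
mismatches `c` and `B[i] = c[i] − frac·i`, validity and maximality are
O(1) comparisons on `B`. Budgets are computed with a 1e-9 epsilon so
`floor(0.1·30)` is 3, not a float-representation 2. Pairs are canonical
(pos1 < pos2, identical placements excluded); windowed scans restrict
both maximality and membership to the windows. The scan is exhaustive
per diagonal (no seeding), so whole-genome runs above ~50 kb are slow;
the intended whole-genome uses are windowed junction scans and the
reduced-scale synthetic genomes.

Tandem repeats are perfect arrays of a primitive unit (2–1,000 bp,
≥ 2 full copies), maximal in the sense that not even one further base of
a unit copy extends them; partial trailing copies extend the span and
make `copies` fractional. "Hidden" arrays — span-contained in another
reported array — are discarded, preferring the smaller unit at equal
span. Counts from this definition are intentionally not comparable to
scoring-based tools (which prune low-scoring micro-arrays); the
summary's value here is the planted-array recovery and the nesting/
maximality properties, both asserted in tests. The scan is linear in the
deposited-origin frame; arrays crossing the origin are not joined.

## The synthetic-data generator

`build_plastome` assembles LSC + IRb + SSC + IRa from a reduced-scale
but realistically ordered gene inventory (junction-spanning *ycf1*, the
*ndh* suite split between SSC and LSC, rRNA/tRNA blocks duplicated in
the IR), background sequence i.i.d. at the target GC (default 0.38,
matching the family's plastomes; CDS codons are drawn at the same base
composition, stops excluded), and IRb as the exact reverse complement of
IRa with mirrored annotations. Defaults are 20 kb LSC / 7.2 kb IR /
7.6 kb SSC (~42 kb total, about a quarter scale) so 50-seed
construct-and-recover loops run in minutes. Everything is deterministic
per seed, and gene sequences are drawn from their own substream so
lesioned and intact variants of the same seed share gene content (which
is what makes single-relative reference panels exact).

Planted elements: lesions (internal stop, single-base frameshift,
truncation to a coverage level, missing stop, missing start, 6 bp N
patch, whole-gene deletion), dispersed repeat pairs with exact planted
mismatch counts, and primitive tandem arrays — all placed in background
spacers with their realised coordinates recorded in the truth table.

Three kinds of boundary pinning keep recovery *exact* rather than
almost-exact: junction flanks are adjusted so a chance complementary
base cannot extend the detected IR by one (probability ~1/4 per junction
otherwise); truncation cut flanks are adjusted so the matched extent
equals the planted extent (same failure mode); and tandem flanks are
adjusted to break the unit period. All pinning happens in non-genic
background. `prepare_expansion` applies the same junction-flank pinning
to an ancestor before a planned expansion, because `apply_ir_expansion`
itself is pure duplication (it must conserve single-copy content
outside the moved segment, and does — a tested invariant).

What the generator does **not** emulate: substitution divergence along a
phylogeny (IR copies and gene copies are exact), full-scale 150 kb+
genomes, intron-rich multi-exon genes beyond a two-exon *ndhA*, SSC
orientation isomers, and read-level artefacts. Passing
construct-and-recover therefore demonstrates correctness of the
coordinate logic, classification rules and event reconstruction — not
robustness to assembly noise or deep divergence.

## Degenerate inputs and edge rules

Translation uses the plastid/bacterial code (table 11), stops as `*`;
any codon containing N is `X` even where the ambiguity would resolve
(e.g. CGN); partial trailing codons are ignored; empty input gives "".
GC% excludes N from the denominator and is reported to one decimal.
Records lacking annotations still get sequence-level summaries; a record
without a detectable IR gets a no-IR row with lengths absent.

## Limitations

* Exact-match IR detection reports the largest identical core of
  slightly divergent IR copies; a mismatch-tolerant refinement is out of
  scope for this version.
* Linear plastomes and SSC-orientation isomers are not modelled beyond
  the no-IR result.
* Event reconstruction assumes the reference is ancestral-like; IR
  contractions in the target relative to the reference yield no events
  rather than negative ones.
* Tandem and dispersed repeat scans ignore origin-crossing placements in
  the deposited frame.
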