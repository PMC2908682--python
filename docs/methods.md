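# Methods

## Duplex model

A mature miRNA (RNA, positions numbered 1-based from the 5' end) is aligned
globally and antiparallel against a candidate decoy site (DNA, 5'→3').
Admissible pair states are Watson–Crick (A:T, U:A, G:C, C:G), G:U wobble
(G:T and U:G, with T standing in for U on the DNA representation of the
site) and mismatch.

When the site is longer than the miRNA the surplus nucleotides form exactly
one contiguous site-side loop. Inside that loop, up to `max_unpaired_mirna`
(default 1) miRNA positions may additionally be left unpaired. This is the
geometry of the natural bulged decoy: a designed motif of length
`L − 1 + 3` aligns with three unpaired site nucleotides opposite one
unpaired miRNA position — a 3×1 internal loop, conventionally called a
"3-nt bulge". Equal-length duplexes are aligned strictly ungapped, so a
bulge is never invented where the arithmetic does not require one;
miRNA-side bulges and multiple loops are outside the model. Sites shorter
than the miRNA are rejected as unalignable.

### Scoring

Each column is priced and summed: Watson–Crick 0, wobble 0.5, mismatch 1.0,
bulged site nucleotide 1.0/nt. Columns whose miRNA position falls in the
core region (positions 2–13) are doubled; bulge columns inherit the weight
of their nearest flanking miRNA position; unpaired miRNA positions inside
the loop carry no penalty of their own (the loop is paid for through its
site nucleotides). These are the conventional plant target-prediction
weights; no single canonical formula exists, so all constants live in
`ScoringParams`, are configurable, and are echoed into every report.

The minimum-score alignment is found by exhaustive enumeration of loop
placements (the family is tiny: O(L) placements per skip count). Ties are
broken deterministically: **prefer the larger site bulge, then the smallest
gap index**. The first rule is a deliberate structural convention: when the
central residues can either pair badly or be drawn as loop at equal score —
which happens systematically for designed sites, because one extra bulged
nucleotide costs exactly one forgone central mismatch — the loop reading is
canonical, matching how bulged decoy sites are drawn in the field.

### Cleavability and capture

`is_cleavable` is true iff (a) no loop crosses the central window
(positions 9–12), (b) at most one non-Watson-Crick column sits at positions
9–11, and (c) the total score is ≤ 4.0. Rule (b) is deliberately tolerant:
a site with a single central mismatch but no bulge still presents an intact
scissile bond and is classified cleavable — which is exactly why such
single-mismatch sites make poor mimics.

`is_capturing` is true iff (a) a site bulge of ≥ 3 nt lies within the
central window, (b) positions 2–9 pair Watson–Crick or wobble, and (c) the
score excluding loop columns is ≤ 3.0. Wobble is allowed in (b) because
consensus mimics for subfamilies rely on wobble coverage. Rules (a) of the
two predicates negate each other on the central window, so no duplex is
ever both cleavable and capturing.

`validate_mimic` reduces the two predicates to a three-way call:
MIMIC_FUNCTIONAL (capturing), else CLEAVABLE, else INERT.

## Mimic design

The site is the per-position covering partner of the reverse complement
with the partner of miRNA position 11 removed and a 3-mer inserted in its
place, giving a motif of `L − 1 + 3` nt with the bulge at site positions
`L − 10 … L − 8` (11–13 for L = 21, 1-based). Position 11 — the 3' partner
of the scissile bond — is the removed position; this reconciles the
23-nt motif convention for a 21-nt miRNA with a bulge spanning the
cleavage site between positions 10 and 11.

The bulge 3-mer is screened over all 64 candidates in lexicographic order
(A<C<G<T); the first candidate passing three checks wins, making the design
a pure function of its inputs:

1. the assembled site must not be cleavable for any source miRNA (a 3-mer
   that re-pairs with the centre can reconstitute a cleavage site);
2. it must be capturing for every source, with the canonical minimum-score
   alignment placing a full-length bulge at the intended interval (a 3-mer
   whose ends pair or wobble with position 11 collapses the loop into a
   cheaper 2-nt bulge beside a restored central pair, and is rejected);
3. it must not create a homopolymer run longer than 3 nt together with its
   flanks.

The screen reports every rejected candidate with its reason. The chosen
3-mer is deterministic but not claimed unique or identical to any
historical construct; the guarantee is the pair of constraints
(non-cleavable, capturing), not a particular sequence.

## Family partitioning

At each aligned position the member bases are mapped to a single covering
DNA base when one exists (WC or wobble against every member base;
candidates with fewer wobbles preferred, remaining ties broken T > G > C >
A). Families whose members cannot all be covered are split by greedy set
cover: candidates are grown greedily from each uncovered seed in id order,
adding members while the subgroup stays designable and fully captured; each
round keeps the candidate covering the most uncovered members (ties: the
smallest seed id). Greedy rather than exact cover keeps large families
tractable; on families of ≤ 6 members the result is verified against
exhaustive partition search in the test suite. Subgroups with unequal
member lengths are designed against the longest member; shorter members are
validated with the site's 5' overhang left dangling at zero penalty,
reflecting 3'-end length variation among mature isoforms.

Mimics are named `MIM<family>` when one mimic serves the whole family and
`MIM<family><sorted variant tokens>` otherwise (e.g. `MIM169defg`,
`MIM161.1`).

## Constructs and primers

The mimic motif replaces the backbone's motif interval byte-for-byte; the
flanks are untouched. Mutagenic primers carry a fixed 20-nt anchor on one
side of the motif, the full motif, and a 3'-extended anchor on the other
side grown one base at a time until its Wallace-rule Tm (2·(A+T) + 4·(G+C)
°C) reaches 55 °C; outer primers anchor at the construct ends and are grown
the same way (their Tm lands in [55, 63] °C because each base adds at most
4 °C). The Wallace rule was chosen as the default because it is closed-form
and dependency-free, making every primer deterministic; nearest-neighbour
models can be plugged in but are not required. An in-silico
overlap-extension check verifies that the two primer-implied products
anchor exactly on the template and stitch back into the construct
byte-identically. Promoter and vector context are annotation placeholders
only. The GenBank writer uses a fixed LOCUS date so repeated runs are
byte-identical.

## Synthetic data generator

The generator emulates the family structure that drives the design
decisions, not real sequence composition. Family ancestors are uniform
random over {A,C,G,U} (so unrelated ancestors differ at ~3/4 of positions);
members derive from their ancestor by at most `within_family_subs`
(default 1) substitutions restricted to A→G and C→U at positions where the
ancestor has A or C. Under this restriction the covering base at a
substituted position keeps all non-substituted members Watson–Crick, so a
member accrues at most one wobble per own substitution and families remain
jointly capturable — the regime in which one mimic per family is the right
answer. Subfamily blocks are separated by `between_block_subs` (default 5)
substitutions from the non-coverable map A↔C, G↔U at disjoint position sets
outside the central window, so no covering base exists across blocks and
capture fails on at least the score budget; the partitioner must split
them. Backbones are uniform random DNA (default 300 nt) with a centred
motif interval.

What passing tests on this generator do **not** show: behaviour on real
catalogues with biased composition, 5'-isomiR variation, families whose
variants differ by transversions (which genuinely require splits — handled,
but not the common case here), or any statement about in-planta efficacy.

## Problem sizes and numerical choices

Scores are sums of 0.5 multiples, so float comparisons are exact; no
tolerances are needed. The default validation suites use 200 random
miRNAs for the three-way classification, 1000 random short duplexes
(miRNA ≤ 12 nt, site ≤ 15 nt) for the aligner-vs-enumeration check,
families of 6 members for exhaustive-optimal partition comparison, and 50
random backbones for the overlap-extension round trip — sizes at which the
exhaustive oracles are exact and the whole suite runs in well under a
minute.

## Known limitations

* No thermodynamic (ΔG) hybridisation model and no secondary-structure
  folding of the decoy transcript; penalties are positional, not
  energetic.
* Only one site-side loop with at most one skipped miRNA position is
  modelled; exotic geometries (multiple loops, miRNA-side bulges) are
  rejected rather than scored.
* Whether wobble pairs at positions 10–11 support slicing in vivo is not
  settled; the ≤1-non-WC rule at positions 9–11 is a pinned convention.
* Off-target capture is predicted with the same predicate as on-target
  capture; no expression, compartment or titration effects are modelled.
* Primer design screens neither dimers nor secondary structure.
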