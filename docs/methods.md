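# Methods

## Maximal repetitions

A maximal repetition (MR) of a text is a substring occurring at least
twice — overlapping occurrences counted, so `aaa` occurs twice in `aaaa` —
such that every one-symbol extension occurs strictly fewer times. Since
`occ(aPb) ≤ occ(aP) ≤ occ(P)`, checking the one-sided extensions suffices;
the two-sided condition is implied. Equivalently an MR is a substring that
is both right-maximal (its occurrence set is followed by at least two
distinct symbols, counting the text end) and left-maximal (preceded by at
least two distinct symbols, counting the text start). A sequence of length
n has at most n distinct MR patterns.

Detection uses the suffix array and LCP array of the text:

* **Suffix array** by prefix doubling, with one `numpy.lexsort` per
  doubling round — O(n log² n) worst case, comfortably fast at the scales
  this package targets (families up to a few hundred kilo-residues).
* **LCP array** by Kasai's algorithm (linear).
* **Right-maximal substrings** are exactly the representative strings of
  LCP intervals, enumerated with the standard stack sweep over the LCP
  array; **left-maximality** is an O(1) test per interval on prefix sums of
  the "same as previous" indicator over the Burrows–Wheeler column.

Family mode concatenates the members with separators. Separators must be
*pairwise different* symbols: with a single reused separator character, a
pattern whose occurrences all abut sequence ends (e.g. `AB` in
`XAB $ YAB $ Z`) would lose right-maximality to the spurious repeat `AB$`
and be missed. The implementation therefore encodes the text over an
integer alphabet in which every separator occurrence is a distinct
integer; sentinel-crossing patterns are then impossible by construction
and member order cannot matter. The character `$` is still reserved and
rejected in input sequences. Occurrences are reported 1-based per member
sequence; FASTA input is uppercased on ingestion (toy lowercase alphabets
are supported at the library level).

An independent brute-force oracle (`brute_force_mrs`) enumerates every
substring, counts overlapping occurrences, and applies the definition
literally. It is O(n³) and guarded at 500 total residues; the test-suite
checks exact agreement (patterns, counts, positions) on 1000 random
strings of lengths 2–200 over alphabets of 1–20 symbols, plus random
multi-sequence families.

## Coverage, profile, familiarity

`coverage(s, R)` is the fraction of positions of `s` inside at least one
occurrence of a pattern of `R`. All catalogue patterns are matched in one
pass with an Aho–Corasick automaton built in-package (dict-based trie,
BFS failure links). Only the longest match ending at each query position
matters: any shorter match ending at the same position covers a subset of
its span. From those per-end maxima a sweep produces `best_cover[j]`, the
length of the longest catalogue-MR occurrence covering position `j`; then

    c_i = |{ j : best_cover[j] ≥ i }| / |s|     for i ≥ 1,

so the entire profile costs one matching pass. The i = 0 level conceptually
uses *all blocks* of the family text; since length-1 blocks dominate, it
reduces to alphabet membership per position and is computed that way
(`all_blocks_alphabet`). A naive per-pattern `str.find` scanner provides
the cross-check oracle for the automaton.

Familiarity aggregates the profile with the unit-spacing trapezoidal rule

    familiarity(s, t) = Σ_{i=0}^{L} c_i − (c_0 + c_L)/2,

bounded by L. All four hand-checkable toy values (4.07, 4.5, 6.5, 1.21)
were re-derived on paper from this quadrature before implementation; plain
(untrapezoided) summation reproduces none of them. The cap defaults to
L = 10 — coverage by MRs longer than ~10 residues is negligible in natural
families — and is a flag everywhere. When |s| < L the extra terms are zero
automatically unless the whole query is itself a catalogue pattern, in
which case the endpoint half-weight sits at i = L rather than i = |s|;
this is documented behaviour, not special-cased. Self-familiarity (query
inside its own catalogue) is *not* corrected; leakage avoidance is the
hold-out pipeline's job.

Useful identities exercised by the tests: the profile is non-increasing
for i ≥ 1; familiarity is monotone under catalogue growth (adding members
can only add MR patterns — extension counts stay strictly dominated — so
no c_i can drop); and for a single-symbol run `a^n` against itself,
familiarity with L = n is exactly n − 0.5.

## Catalogues

A catalogue is the family MRSet plus metadata (alphabet, sizes, seed,
median member length). Sequences containing ambiguous residue codes
(X, B, Z, J) are excluded at build time by default — queries are not
filtered, only the family definition is. At least two members must remain.
All MRs are stored by default (`min_stored_length = 1`; familiarity needs
i ≥ 1 even though the long-MR regime starts around i ≥ 6); a storage floor
exists for very large families. Serialization is TSV with a `#` header
carrying a format version; occurrence positions are omitted unless
requested, since scoring external queries needs only the patterns.
`subsample_to_residues` equalizes dataset sizes across families (uniform
selection without replacement until the cumulative residue count first
reaches the target); `scramble_family` permutes each member's residues
independently as the null control.

## Hold-out classification

`holdout_experiment` splits each family with a per-family seed derived
from one master seed, builds catalogues from the training members only
(held-out queries never enter their home catalogue), scores every query
against every catalogue, and ranks families per query by descending
familiarity with ties broken by family id (deterministic reports).
Queries longer than 3× the family's median member length get a
multidomain note — only a segment of such a protein may belong to the
family, which depresses coverage — but no correction is applied.

## Synthetic families

The generator emulates a repeat-protein family as: flank + k mutated
copies of a consensus unit + flank. Defaults: 33-residue ankyrin-like
unit, k uniform in 4–8, flank lengths uniform in 0–20, i.i.d. per-site
substitution at rate 0.1 to a uniformly drawn *different* residue, no
indels, 20-letter amino-acid alphabet, 30 members. The substitution rate
0.1 leaves exact stretches of ~10 residues between mutations — the mosaic
regime where members share abundant medium-length exact blocks without
long perfect repeats, which is what makes the familiarity contrast
interesting; at rate 0 the generator reproduces the perfect tandem arrays
of designed consensus proteins, and at high rates the MR spectrum
collapses toward the scrambled control's. What the generator does *not*
model: phylogenetic correlation between members, indels, composition
bias, and multidomain architecture — so passing benchmarks show the
statistic separates families with distinct consensus units under i.i.d.
divergence, not that it resolves closely related natural families.

The packaged benchmark builds 5 such families (each on its own random
33-mer unit, master seed 2016, 30 members) and holds out 10 members per
family; the scrambling control uses three fixed replicate seeds (11, 23,
42). Problem sizes throughout the suite (strings ≤ 200 for oracle
equivalence, families of ≤ 30 × ~250 residues) are chosen so every check
runs in seconds while still exercising each code path at a scale where
the asymptotics are visible.

## Numerical and degenerate cases

Coverage values are exact binary rationals divided by |s| in double
precision; no tolerance issues arise at these magnitudes and the toy
values are asserted to the printed precision. Empty queries and empty
sequences raise; an empty pattern set covers nothing; a catalogue with a
disjoint alphabet yields an all-zero profile and familiarity 0. `min_len`
of 0 is reserved for the all-blocks level and rejected by the MR finders.
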