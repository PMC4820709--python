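# repfam

Parameter-free detection of **maximal repetitions** (MRs) in protein
sequences and protein families, and the **familiarity** statistic that
quantifies how likely a sequence is to belong to a family.

Repeat proteins (ankyrins, WD40s, …) are built from tandem copies of a
structural unit, yet the copies are so divergent in sequence that
alignment- and HMM-based repeat detectors need carefully tuned thresholds.
`repfam` takes the opposite route: it works only with *exact* repetitions,
which need no parameters at all. Individual proteins contain few long exact
repeats — but a protein family, taken as a whole, acts as a catalogue of
every variation its building blocks can adopt, and most of any member's
sequence can be tiled by exact stretches occurring elsewhere in the family.

## The model

**Maximal repetition.** A substring `r` of a text `s` is an MR if it occurs
at least twice in `s` (overlapping occurrences count) and every one-symbol
extension of `r` — to the left, to the right, or both — occurs strictly
fewer times. This is the classical *maximal repeat* of stringology; `repfam`
finds all of them with a suffix array + LCP array. For a family
`S = {s_1, …, s_n}` the MRs are those of the concatenation
`s_1 $_1 s_2 $_2 … $_{n-1} s_n` with pairwise-different separator symbols,
so no repetition crosses a sequence boundary and the result is independent
of member order.

**Coverage.** For a query `s` and a pattern set `R`,
`coverage(s, R)` is the fraction of positions of `s` that lie inside at
least one occurrence of at least one pattern of `R` — a rational in [0, 1].

**Familiarity.** Let `M(t, i)` be the MRs of the family text `t` with
length ≥ `i` (with `M(t, 0)` the set of all blocks of `t`, whose coverage
reduces to alphabet membership), and `c_i = coverage(s, M(t, i))`. Then

```
familiarity(s, t) = Σ_{i=0}^{L}  c_i  −  (c_0 + c_L) / 2        (L = 10 by default)
```

i.e. the unit-spacing trapezoidal aggregate of the coverage profile. It is
bounded by `L`, and larger values mean more of `s` can be reconstructed
from exact repetitions of the family — a continuous membership score. The
cap `L = 10` suffices in practice because coverage by MRs longer than ~10
residues is negligible in natural families.

## Worked example

```python
>>> import repfam as rf
>>> rf.find_mrs("abcdeabcdfbcdebcd").patterns
{'abcd', 'bcde', 'bcd'}
>>> cat = rf.sequence_catalogue(rf.Sequence("s1", "abcdeabcdfbcdebcd"))
>>> round(rf.coverage("abcdeabcdfbcdebcd", cat.patterns), 2)
0.94
>>> round(rf.familiarity("abcdbcd", cat, L=7).value, 2)
4.07
```

`abcd`, `bcde` and `bcd` are the only substrings of `s1` that repeat and
cannot be extended without losing occurrences; their occurrences cover 16
of the 17 positions of `s1` (only the lone `f` is missed, coverage 0.94).
The query `abcdbcd` is fully covered by MRs up to minimum length 3 and
4/7-covered at minimum length 4, giving familiarity
`1 + 1 + 1 + 1 + 4/7 − 1/2 ≈ 4.07` of a possible 7.

The same machinery scales to families:

```bash
repfam simulate --spec spec.json -o family.fasta      # synthetic repeat family
repfam build-catalogue family.fasta -o FAM.cat.tsv    # family MR catalogue
repfam familiarity query.fasta --catalogue FAM.cat.tsv --profile
repfam classify queries.fasta --catalogues catalogues/
repfam stats FAM.cat.tsv                              # per-length MR statistics
```

`classify` ranks the catalogues by familiarity for each query; on the
packaged synthetic benchmark (5 families × 30 sequences, 10 held out per
family) the held-out members' home family ranks first in every case, and
per-sequence residue scrambling collapses the long MRs of a repeat family
to near-random lengths — the two controls in `tests/test_acceptance.py`.

## Working with real families

Curated family datasets (e.g. Pfam full alignments or Uniref90 hits of a
family HMM) are not bundled. The intended recipe: collect members with
`hmmsearch` against Uniref90, de-duplicate with `cd-hit`, drop sequences
with ambiguous residues (X/B/Z/J — `build-catalogue` does this by
default), optionally equalize dataset sizes across families with
`--max-residues`, then build catalogues and score queries as above.
`repfam find-mrs --per-sequence` reproduces per-protein MR length spectra
for individual members (e.g. a single ankyrin-repeat protein chain).
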