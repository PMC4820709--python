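"""Maximal-repetition (MR) detection for sequences and sequence families.

A *maximal repetition* of a text is a substring that occurs at least twice
(overlapping occurrences counted) and whose every one-symbol extension —
to the left, to the right, or on both sides — occurs strictly fewer times.
This is the classical "maximal repeat" of stringology: right-maximality
corresponds to the substring being the representative string of an
LCP-interval of the suffix array, and left-maximality to the occurrence
set being preceded by at least two distinct symbols (a text boundary
counts as a symbol of its own).

For a family of sequences the MRs are those of the concatenation of the
members interleaved with pairwise-different separator symbols, so no
repetition can span a sequence boundary and the result is invariant under
reordering of the members.  The implementation realizes this directly by
encoding every separator occurrence as a distinct integer in the suffix
array's alphabet.

`brute_force_mrs` is an independent O(n^3) enumeration oracle used by the
test-suite to validate the suffix-array path.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence as PySequence

import numpy as np

#: Reserved separator character: never allowed inside a Sequence, so that
#: family concatenation can always use symbols outside the alphabet.
SENTINEL = "$"

#: Guard bound (total residues) for the brute-force oracle.
BRUTE_FORCE_GUARD = 500


class DegenerateSequenceError(ValueError):
    """Raised for inputs on which repeat detection is undefined (empty text)."""


@dataclass(frozen=True)
class Sequence:
    """An identified string over a finite alphabet.

    Positions are addressed 1-based in all user-facing coordinates.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise DegenerateSequenceError(f"sequence {self.id!r} is empty")
        if SENTINEL in self.residues:
            raise ValueError(
                f"sequence {self.id!r} contains the reserved separator {SENTINEL!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.residues)


SequenceLike = "Sequence | str"


def as_sequence(obj, default_id: str = "seq") -> Sequence:
    """Coerce a raw string to a :class:`Sequence` (identity on Sequence)."""
    if isinstance(obj, Sequence):
        return obj
    return Sequence(id=default_id, residues=str(obj))


def _as_sequences(objs: Iterable) -> list[Sequence]:
    seqs = []
    for i, obj in enumerate(objs):
        seqs.append(as_sequence(obj, default_id=f"seq{i + 1}"))
    return seqs


@dataclass(frozen=True)
class MR:
    """One maximal repetition with its occurrences.

    ``occurrences`` holds (sequence id, 1-based start) pairs; ``n_instances``
    counts every (overlapping) occurrence and ``n_proteins`` the distinct
    source sequences hit.
    """

    pattern: str
    occurrences: tuple[tuple[str, int], ...]
    n_instances: int
    n_proteins: int

    @property
    def length(self) -> int:
        return len(self.pattern)


class MRSet:
    """The set of MRs of a sequence or of a family of sequences."""

    def __init__(self, members: Mapping[str, MR], source_length: int, n_sequences: int):
        self._members = dict(members)
        self.source_length = int(source_length)
        self.n_sequences = int(n_sequences)

    @property
    def patterns(self) -> set[str]:
        return set(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[MR]:
        return iter(self._members.values())

    def __contains__(self, pattern: str) -> bool:
        return pattern in self._members

    def __getitem__(self, pattern: str) -> MR:
        return self._members[pattern]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MRSet):
            return NotImplemented
        return (
            self._members == other._members
            and self.source_length == other.source_length
            and self.n_sequences == other.n_sequences
        )

    def max_length(self) -> int:
        """Length of the longest MR (0 for an empty set)."""
        return max((m.length for m in self), default=0)

    def filter(self, min_len: int) -> "MRSet":
        """Sub-set of MRs with length >= ``min_len`` (same source metadata)."""
        kept = {p: m for p, m in self._members.items() if m.length >= min_len}
        return MRSet(kept, self.source_length, self.n_sequences)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MRSet({len(self)} patterns, source_length={self.source_length}, "
            f"n_sequences={self.n_sequences})"
        )


# ---------------------------------------------------------------------------
# Suffix array machinery (integer alphabet; separators are distinct integers)
# ---------------------------------------------------------------------------


def _encode(seqs: list[Sequence]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Concatenate ``seqs`` into an integer array with unique separators.

    Separator occurrences take values 0 .. n_sequences-2 (each value used
    exactly once, realizing pairwise-different separator symbols); residue
    characters are offset above them.  Returns (text, starts, symbols) where
    ``starts[i]`` is the offset of sequence i in the concatenation and
    ``symbols`` decodes residue codes back to characters.
    """
    n_sep = max(len(seqs) - 1, 0)
    symbols = sorted({c for s in seqs for c in s.residues})
    code = {c: n_sep + k for k, c in enumerate(symbols)}
    pieces: list[np.ndarray] = []
    starts = np.empty(len(seqs), dtype=np.int64)
    offset = 0
    for i, s in enumerate(seqs):
        if i > 0:
            pieces.append(np.array([i - 1], dtype=np.int64))
            offset += 1
        starts[i] = offset
        pieces.append(np.array([code[c] for c in s.residues], dtype=np.int64))
        offset += len(s)
    text = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int64)
    return text, starts, symbols


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort per round)."""
    n = text.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(text, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(bump)
        if new_rank[-1] == n - 1:
            return order
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        k <<= 1


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = lcp(suffix sa[i-1], suffix sa[i]), lcp[0]=0."""
    n = sa.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    txt = text.tolist()  # python list: faster scalar access in the loop below
    rk = rank.tolist()
    sal = sa.tolist()
    h = 0
    for i in range(n):
        r = rk[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and txt[i + h] == txt[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def _lcp_intervals(lcp: np.ndarray) -> list[tuple[int, int, int]]:
    """All LCP-intervals (depth, lb, rb) with depth >= 1, via the classic stack sweep."""
    n = lcp.size
    out: list[tuple[int, int, int]] = []
    stack: list[list[int]] = [[0, 0]]  # (lcp depth, left boundary)
    lcp_list = lcp.tolist()
    for i in range(1, n + 1):
        cur = lcp_list[i] if i < n else 0
        lb = i - 1
        while stack[-1][0] > cur:
            depth, ilb = stack.pop()
            if depth >= 1:
                out.append((depth, ilb, i - 1))
            lb = ilb
        if stack[-1][0] < cur:
            stack.append([cur, lb])
    return out


def _maximal_repeats(
    text: np.ndarray, sa: np.ndarray, lcp: np.ndarray
) -> list[tuple[int, int, int]]:
    """Left- and right-maximal repeats as (pattern_length, lb, rb) SA intervals."""
    n = sa.size
    # Burrows-Wheeler column; -1 marks the (unique) text start.
    bwt = np.where(sa > 0, text[np.maximum(sa - 1, 0)], -1)
    same = np.zeros(n, dtype=np.int64)
    if n > 1:
        same[1:] = bwt[1:] == bwt[:-1]
    csum = np.cumsum(same)
    out = []
    for depth, lb, rb in _lcp_intervals(lcp):
        # left-maximal iff the preceding symbols over sa[lb..rb] are not all equal
        if csum[rb] - csum[lb] != rb - lb:
            out.append((depth, lb, rb))
    return out


def _build_mrset(seqs: list[Sequence], min_len: int) -> MRSet:
    text, starts, symbols = _encode(seqs)
    sa = suffix_array(text)
    lcp = lcp_array(text, sa)
    n_sep = max(len(seqs) - 1, 0)
    decode = {n_sep + k: c for k, c in enumerate(symbols)}
    seq_ids = [s.id for s in seqs]
    members: dict[str, MR] = {}
    for depth, lb, rb in _maximal_repeats(text, sa, lcp):
        if depth < min_len:
            continue
        start = int(sa[lb])
        pattern = "".join(decode[int(v)] for v in text[start : start + depth])
        positions = np.sort(sa[lb : rb + 1])
        idx = np.searchsorted(starts, positions, side="right") - 1
        occurrences = tuple(
            (seq_ids[int(k)], int(p - starts[int(k)] + 1))
            for k, p in zip(idx, positions)
        )
        members[pattern] = MR(
            pattern=pattern,
            occurrences=occurrences,
            n_instances=len(occurrences),
            n_proteins=len(set(int(k) for k in idx)),
        )
    return MRSet(
        members,
        source_length=sum(len(s) for s in seqs),
        n_sequences=len(seqs),
    )


def find_mrs(seq, min_len: int = 1) -> MRSet:
    """All maximal repetitions of a single sequence with length >= ``min_len``.

    Runs in O(|s| log |s|) suffix-array time; occurrence positions are
    1-based and overlapping occurrences are counted.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1 (0 denotes the all-blocks set)")
    s = as_sequence(seq)
    return _build_mrset([s], min_len)


def find_mrs_multi(seqs: Iterable, min_len: int = 1) -> MRSet:
    """Maximal repetitions of a set of sequences (family mode).

    Equivalent to the MRs of the concatenation of the sequences interleaved
    with pairwise-different separator symbols: no pattern crosses a sequence
    boundary, and the result is invariant under permutation of the input.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1 (0 denotes the all-blocks set)")
    slist = _as_sequences(seqs)
    if not slist:
        raise ValueError("need at least one sequence")
    return _build_mrset(slist, min_len)


def all_blocks_alphabet(seq_or_seqs) -> set[str]:
    """Symbol set of a sequence or family (the "all blocks" shortcut).

    Covering a query with *all* blocks of a text reduces to covering with
    its length-1 blocks, so a query position is covered at minimum length 0
    exactly when its symbol occurs in the text.
    """
    if isinstance(seq_or_seqs, (Sequence, str)):
        return set(as_sequence(seq_or_seqs).residues)
    return {c for s in _as_sequences(seq_or_seqs) for c in s.residues}


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _unique_separators(k: int, used: set[str]) -> list[str]:
    seps: list[str] = []
    point = 0x2460  # arbitrary Unicode block far from residue alphabets
    while len(seps) < k:
        c = chr(point)
        if c not in used:
            seps.append(c)
        point += 1
    return seps


def brute_force_mrs(seq_or_seqs, min_len: int = 1, guard: int = BRUTE_FORCE_GUARD) -> MRSet:
    """Independent O(n^3) oracle: enumerate every substring, count overlapping
    occurrences, and keep those occurring >= 2 times whose every one-symbol
    extension occurs strictly fewer times.

    Family input is concatenated with pairwise-different separator characters.
    Guarded to ``guard`` total residues to keep the enumeration tractable.
    """
    if isinstance(seq_or_seqs, (Sequence, str)):
        seqs = [as_sequence(seq_or_seqs)]
    else:
        seqs = _as_sequences(seq_or_seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    total = sum(len(s) for s in seqs)
    if total > guard:
        raise ValueError(f"brute-force guard exceeded: {total} residues > {guard}")

    used = {c for s in seqs for c in s.residues}
    seps = _unique_separators(max(len(seqs) - 1, 0), used)
    parts: list[str] = []
    starts: list[int] = []
    offset = 0
    for i, s in enumerate(seqs):
        if i > 0:
            parts.append(seps[i - 1])
            offset += 1
        starts.append(offset)
        parts.append(s.residues)
        offset += len(s)
    text = "".join(parts)
    n = len(text)

    counts: dict[str, int] = defaultdict(int)
    where: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = text[i:j]
            counts[sub] += 1
            where[sub].append(i)

    symbols = set(text)
    sep_set = set(seps)
    starts_arr = np.asarray(starts, dtype=np.int64)
    members: dict[str, MR] = {}
    for sub, c in counts.items():
        if c < 2 or len(sub) < min_len:
            continue
        if sep_set & set(sub):
            continue  # separators are unique; cannot repeat anyway
        if any(counts.get(a + sub, 0) >= c for a in symbols):
            continue  # left-extendable with no loss of occurrences
        if any(counts.get(sub + a, 0) >= c for a in symbols):
            continue
        # two-sided extensions are implied: occ(aPb) <= occ(aP) < occ(P)
        positions = np.asarray(sorted(where[sub]), dtype=np.int64)
        idx = np.searchsorted(starts_arr, positions, side="right") - 1
        occurrences = tuple(
            (seqs[int(k)].id, int(p - starts_arr[int(k)] + 1))
            for k, p in zip(idx, positions)
        )
        members[sub] = MR(
            pattern=sub,
            occurrences=occurrences,
            n_instances=len(occurrences),
            n_proteins=len(set(int(k) for k in idx)),
        )
    return MRSet(members, source_length=total, n_sequences=len(seqs))
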