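"""Coverage of a query by an MR catalogue and the familiarity statistic.

*Coverage* of a sequence s by a pattern set R is the fraction of positions
of s that lie inside at least one occurrence of at least one pattern of R
(a rational between 0 and 1).  The *coverage profile* evaluates coverage
with the catalogue restricted to MRs of minimum length i, for i = 0..L;
the i = 0 term uses all blocks of the family text, which reduces to
alphabet membership.  *Familiarity* aggregates the profile with the
unit-spacing trapezoidal rule,

    familiarity = sum_{i=0}^{L} c_i - (c_0 + c_L) / 2,

a number between 0 and L that grows with how much of the query can be
reconstructed from exact repetitions of the family.  All profile values
for i >= 1 come from a single multi-pattern (Aho-Corasick) pass that
records, per query position, the length of the longest catalogue MR
occurrence covering it.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, TYPE_CHECKING

import numpy as np

from .mr_core import Sequence, as_sequence

if TYPE_CHECKING:  # pragma: no cover
    from .catalogue import Catalogue

#: Minimum-length cap used throughout unless overridden: coverage beyond
#: length-10 MRs is negligible for natural protein families.
DEFAULT_MAX_LEN = 10


class AhoCorasick:
    """Multi-pattern matcher reporting the longest match per end position."""

    def __init__(self, patterns: Iterable[str]):
        # goto is a list of dicts (trie); depth doubles as pattern length
        self._goto: list[dict[str, int]] = [{}]
        self._depth: list[int] = [0]
        self._terminal: list[bool] = [False]
        for p in patterns:
            if not p:
                continue
            node = 0
            for ch in p:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto[node][ch] = nxt
                    self._goto.append({})
                    self._depth.append(self._depth[node] + 1)
                    self._terminal.append(False)
                node = nxt
            self._terminal[node] = True
        self._build_links()

    def _build_links(self) -> None:
        n = len(self._goto)
        self._fail = [0] * n
        # longest terminal suffix length reachable from each node
        self._out_len = [d if t else 0 for d, t in zip(self._depth, self._terminal)]
        queue = deque(self._goto[0].values())
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                if not self._out_len[child]:
                    self._out_len[child] = self._out_len[self._fail[child]]
                queue.append(child)

    def longest_match_ends(self, text: str) -> np.ndarray:
        """For each position e of ``text`` (0-based), the length of the
        longest pattern ending at e (0 if none)."""
        ends = np.zeros(len(text), dtype=np.int64)
        node = 0
        for e, ch in enumerate(text):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            ends[e] = self._out_len[node]
        return ends


def best_cover_array(query, patterns: Iterable[str]) -> np.ndarray:
    """Per-position length of the longest pattern occurrence covering each
    position of ``query`` (0 where uncovered); one automaton pass.

    Only the longest match per end position matters: a shorter pattern
    ending at the same place covers a subset of the longer one's span.
    """
    q = as_sequence(query)
    text = q.residues
    best = np.zeros(len(text), dtype=np.int64)
    ac = AhoCorasick(patterns)
    ends = ac.longest_match_ends(text)
    for e in np.flatnonzero(ends):
        length = ends[e]
        lo = e - length + 1
        seg = best[lo : e + 1]
        np.maximum(seg, length, out=seg)
    return best


def naive_best_cover_array(query, patterns: Iterable[str]) -> np.ndarray:
    """Per-pattern ``str.find`` scan; independent cross-check of the automaton."""
    q = as_sequence(query)
    text = q.residues
    best = np.zeros(len(text), dtype=np.int64)
    for p in patterns:
        if not p:
            continue
        start = text.find(p)
        while start != -1:
            seg = best[start : start + len(p)]
            np.maximum(seg, len(p), out=seg)
            start = text.find(p, start + 1)
    return best


def coverage(query, patterns: Iterable[str]) -> float:
    """Fraction of query positions inside at least one pattern occurrence."""
    q = as_sequence(query)
    pats = list(patterns)
    if not pats:
        return 0.0
    best = best_cover_array(q, pats)
    return float(np.count_nonzero(best)) / len(q)


@dataclass(frozen=True)
class CoverageProfile:
    """Coverage values c_0..c_L of one query against one catalogue.

    ``best_cover[j]`` is the length of the longest catalogue-MR occurrence
    covering query position j (0-based internally; 0 where uncovered), so
    c_i = |{j : best_cover[j] >= i}| / |s| for i >= 1, while c_0 tests
    alphabet membership per position.
    """

    query_id: str
    family_id: str
    L: int
    c: np.ndarray
    best_cover: np.ndarray

    def trapezoid(self) -> float:
        return float(self.c.sum() - (self.c[0] + self.c[-1]) / 2.0)


@dataclass(frozen=True)
class FamiliarityValue:
    query_id: str
    family_id: str
    value: float
    L: int


def coverage_profile(query, catalogue: "Catalogue", L: int = DEFAULT_MAX_LEN) -> CoverageProfile:
    """Coverage of ``query`` by the catalogue's MRs of minimum length 0..L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    q = as_sequence(query)
    n = len(q)
    best = best_cover_array(q, catalogue.patterns)
    c = np.zeros(L + 1, dtype=np.float64)
    in_alpha = np.fromiter((ch in catalogue.alphabet for ch in q.residues), bool, n)
    c[0] = in_alpha.sum() / n
    for i in range(1, L + 1):
        c[i] = np.count_nonzero(best >= i) / n
    return CoverageProfile(
        query_id=q.id, family_id=catalogue.family_id, L=L, c=c, best_cover=best
    )


def familiarity(query, catalogue: "Catalogue", L: int = DEFAULT_MAX_LEN) -> FamiliarityValue:
    """Trapezoidal aggregate of the coverage profile: in [0, L], larger when
    more of the query is reconstructable from family repetitions."""
    profile = coverage_profile(query, catalogue, L=L)
    return FamiliarityValue(
        query_id=profile.query_id,
        family_id=profile.family_id,
        value=profile.trapezoid(),
        L=L,
    )
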