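"""Family MR catalogues: build, subsample, scramble, summarize.

A catalogue is the full set of maximal repetitions of a protein family —
the family text being the separator-interleaved concatenation of its
members — together with per-MR instance and protein counts and the family
metadata needed to score external queries (alphabet, sizes, build seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .mr_core import MRSet, Sequence, as_sequence, find_mrs, find_mrs_multi

logger = logging.getLogger(__name__)

#: Residue codes treated as undefined/ambiguous; member sequences containing
#: any of them are dropped at catalogue build time.
AMBIGUOUS_RESIDUES = frozenset("XBZJ")


@dataclass
class Catalogue:
    """A family's MR set plus the metadata needed to score queries."""

    family_id: str
    mrs: MRSet
    alphabet: frozenset[str]
    n_sequences: int
    total_residues: int
    build_seed: Optional[int] = None
    min_stored_length: int = 1
    median_length: Optional[float] = None

    @property
    def patterns(self) -> set[str]:
        return self.mrs.patterns

    def max_mr_length(self) -> int:
        return self.mrs.max_length()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Catalogue):
            return NotImplemented
        return (
            self.family_id == other.family_id
            and self.alphabet == other.alphabet
            and self.n_sequences == other.n_sequences
            and self.total_residues == other.total_residues
            and self.build_seed == other.build_seed
            and self.min_stored_length == other.min_stored_length
            and self.median_length == other.median_length
            and {
                (m.pattern, m.n_instances, m.n_proteins) for m in self.mrs
            }
            == {(m.pattern, m.n_instances, m.n_proteins) for m in other.mrs}
        )


def has_ambiguous(seq: Sequence) -> bool:
    return bool(AMBIGUOUS_RESIDUES & set(seq.residues))


def build_catalogue(
    family: Iterable,
    family_id: str = "family",
    min_stored_length: int = 1,
    exclude_ambiguous: bool = True,
    build_seed: Optional[int] = None,
) -> Catalogue:
    """Build the MR catalogue of a family.

    Sequences containing undefined or ambiguous residues (X, B, Z, J) are
    dropped when ``exclude_ambiguous`` is set; at least two sequences must
    remain, since no cross-family repetition exists in a family of one.
    """
    seqs = [as_sequence(s, default_id=f"seq{i + 1}") for i, s in enumerate(family)]
    if exclude_ambiguous:
        kept = [s for s in seqs if not has_ambiguous(s)]
        n_dropped = len(seqs) - len(kept)
        if n_dropped:
            logger.info(
                "family %s: excluded %d/%d sequences with ambiguous residues",
                family_id, n_dropped, len(seqs),
            )
        seqs = kept
    if len(seqs) < 2:
        raise ValueError(
            f"family {family_id!r}: need >= 2 sequences after exclusion, got {len(seqs)}"
        )
    mrs = find_mrs_multi(seqs, min_len=1).filter(max(min_stored_length, 1))
    return Catalogue(
        family_id=family_id,
        mrs=mrs,
        alphabet=frozenset(c for s in seqs for c in s.residues),
        n_sequences=len(seqs),
        total_residues=sum(len(s) for s in seqs),
        build_seed=build_seed,
        min_stored_length=max(min_stored_length, 1),
        median_length=float(median(len(s) for s in seqs)),
    )


def sequence_catalogue(seq, family_id: Optional[str] = None) -> Catalogue:
    """Catalogue of a single sequence (self-familiarity / per-protein spectra)."""
    s = as_sequence(seq)
    fid = family_id if family_id is not None else s.id
    return Catalogue(
        family_id=fid,
        mrs=find_mrs(s, min_len=1),
        alphabet=s.alphabet,
        n_sequences=1,
        total_residues=len(s),
        median_length=float(len(s)),
    )


def subsample_to_residues(
    family: list, target_residues: int, seed: int
) -> list:
    """Uniform selection without replacement until the cumulative residue
    count first reaches ``target_residues`` (size normalization across
    families).  Deterministic given ``seed``; selection order preserved as
    in the input family."""
    if target_residues <= 0:
        raise ValueError("target_residues must be > 0")
    seqs = [as_sequence(s, default_id=f"seq{i + 1}") for i, s in enumerate(family)]
    total = sum(len(s) for s in seqs)
    if total < target_residues:
        warnings.warn(
            f"family has only {total} residues < target {target_residues}; "
            "returning the whole family",
            stacklevel=2,
        )
        return seqs
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seqs))
    chosen: set[int] = set()
    cum = 0
    for i in order:
        chosen.add(int(i))
        cum += len(seqs[int(i)])
        if cum >= target_residues:
            break
    return [s for i, s in enumerate(seqs) if i in chosen]


def scramble_family(family: list, seed: int) -> list:
    """Independently permute the residues of each sequence (per-sequence
    composition preserved).  The scrambled family is the null control:
    long exact repetitions should essentially vanish."""
    rng = np.random.default_rng(seed)
    out = []
    for i, s in enumerate(family):
        s = as_sequence(s, default_id=f"seq{i + 1}")
        residues = "".join(rng.permutation(list(s.residues)))
        out.append(Sequence(id=s.id, residues=residues))
    return out


def catalogue_stats(cat: Catalogue) -> pd.DataFrame:
    """Per-MR-length summary: number of distinct patterns, total and mean
    instance and protein counts, and the instances-per-protein ratio."""
    rows = [
        {
            "length": m.length,
            "n_instances": m.n_instances,
            "n_proteins": m.n_proteins,
        }
        for m in cat.mrs
    ]
    if not rows:
        return pd.DataFrame(
            columns=[
                "n_patterns", "total_instances", "total_proteins",
                "mean_instances", "mean_proteins", "instances_per_protein",
            ]
        ).rename_axis("length")
    df = pd.DataFrame(rows)
    g = df.groupby("length")
    out = pd.DataFrame(
        {
            "n_patterns": g.size(),
            "total_instances": g["n_instances"].sum(),
            "total_proteins": g["n_proteins"].sum(),
            "mean_instances": g["n_instances"].mean(),
            "mean_proteins": g["n_proteins"].mean(),
        }
    )
    out["instances_per_protein"] = out["total_instances"] / out["total_proteins"]
    return out
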