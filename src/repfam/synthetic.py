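"""Toy fixtures and synthetic repeat-protein family generation.

The toy strings exercise every definition at hand-checkable scale.  The
family generator emulates the sequence structure of natural repeat-protein
families (ankyrin-like): each member is a tandem array of point-mutated
copies of a consensus repeat unit between short random flanks.  Members of
one family therefore share abundant exact stretches — a mosaic of maximal
repetitions — while scrambled or unrelated controls do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .mr_core import Sequence

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default consensus repeat unit: a 33-mer with ankyrin-like flavor
#: (the ankyrin structural unit is ~33 residues).
ANK_LIKE_UNIT = "DAAGHTPLHLAARNGHLEIVKLLLDAGADVNAK"

#: Seeds of the packaged scrambling-control replicates.
CONTROL_SEEDS = (11, 23, 42)

#: Seed of the packaged hold-out classification benchmark.
BENCHMARK_SEED = 2016


def toy_sequences() -> Mapping[str, object]:
    """Named hand-checkable fixtures: s1..s6 and the four-sequence family t1.

    These are small enough that MR sets, coverage and familiarity can be
    verified by enumeration on paper; they anchor the whole test-suite.
    """
    return {
        "s1": Sequence("s1", "abcdeabcdfbcdebcd"),
        "s2": Sequence("s2", "aaaa"),
        "s3": Sequence("s3", "ab"),
        "s4": Sequence("s4", "abcdbcd"),
        "s5": Sequence("s5", "abcabca"),
        "s6": Sequence("s6", "aaaaaaa"),
        "t1": [
            Sequence("t1a", "aa"),
            Sequence("t1b", "ab"),
            Sequence("t1c", "adddd"),
            Sequence("t1d", "bca"),
        ],
    }


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic repeat-protein family.

    Each member is flank + (mutated unit) * k + flank with k drawn from
    ``repeats_per_protein``; every unit copy is independently point-mutated
    at rate ``p_substitution`` per site (substitution to a uniformly drawn
    *different* symbol; no indels).
    """

    family_id: str = "synthetic"
    n_proteins: int = 30
    repeat_unit: str = ANK_LIKE_UNIT
    repeats_per_protein: tuple[int, int] = (4, 8)
    p_substitution: float = 0.1
    flank_range: tuple[int, int] = (0, 20)
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.repeat_unit:
            raise ValueError("repeat_unit must be non-empty")
        if not 0.0 <= self.p_substitution <= 1.0:
            raise ValueError("p_substitution must be in [0, 1]")
        lo, hi = self.repeats_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("repeats_per_protein must be a range of positive ints")
        flo, fhi = self.flank_range
        if not (0 <= flo <= fhi):
            raise ValueError("flank_range must be a non-negative range")
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet must have >= 2 symbols")
        if any(c not in self.alphabet for c in self.repeat_unit):
            raise ValueError("repeat_unit uses symbols outside the alphabet")


def _mutate(unit: str, p: float, alphabet: str, rng: np.random.Generator) -> str:
    out = list(unit)
    hit = np.flatnonzero(rng.random(len(unit)) < p)
    for i in hit:
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def generate_family(spec: FamilySpec) -> list[Sequence]:
    """Generate a synthetic family; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.repeats_per_protein
    flo, fhi = spec.flank_range
    alpha = list(spec.alphabet)
    members = []
    for i in range(spec.n_proteins):
        k = int(rng.integers(lo, hi + 1))
        units = [_mutate(spec.repeat_unit, spec.p_substitution, spec.alphabet, rng)
                 for _ in range(k)]
        flanks = []
        for _ in range(2):
            flen = int(rng.integers(flo, fhi + 1))
            flanks.append("".join(alpha[int(j)] for j in rng.integers(len(alpha), size=flen)))
        members.append(
            Sequence(
                id=f"{spec.family_id}_{i + 1:03d}",
                residues=flanks[0] + "".join(units) + flanks[1],
            )
        )
    return members


def random_repeat_unit(length: int, rng: np.random.Generator,
                       alphabet: str = AMINO_ACIDS) -> str:
    alpha = list(alphabet)
    return "".join(alpha[int(j)] for j in rng.integers(len(alpha), size=length))


def benchmark_families(
    n_families: int = 5,
    n_proteins: int = 30,
    seed: int = BENCHMARK_SEED,
    p_substitution: float = 0.1,
) -> dict[str, list[Sequence]]:
    """The packaged classification benchmark: ``n_families`` independent
    synthetic families, each built on its own random 33-mer consensus."""
    rng = np.random.default_rng(seed)
    families: dict[str, list[Sequence]] = {}
    for f in range(n_families):
        unit = random_repeat_unit(len(ANK_LIKE_UNIT), rng)
        spec = FamilySpec(
            family_id=f"fam{f + 1}",
            n_proteins=n_proteins,
            repeat_unit=unit,
            p_substitution=p_substitution,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        families[spec.family_id] = generate_family(spec)
    return families
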