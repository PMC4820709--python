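"""FASTA ingestion and TSV/catalogue persistence.

Residues are uppercased on FASTA ingestion (protein FASTA dialects mix
case); records containing the reserved separator '$' or no residues are
rejected.  Catalogue files are TSV with a '#'-prefixed metadata header
carrying a format version; occurrence positions are not serialized (they
are not needed to score external queries) unless explicitly requested.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .catalogue import Catalogue
from .mr_core import MR, MRSet, SENTINEL, Sequence

CATALOGUE_FORMAT = "repfam-catalogue-v1"

PathLike = Union[str, os.PathLike]


class FastaError(ValueError):
    """Malformed FASTA input."""


def read_fasta(path: PathLike) -> list[Sequence]:
    """Read a (multi-)FASTA file into Sequences, preserving record order."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected a '>' header before residues"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
    seqs: list[Sequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = str(record.seq).replace(" ", "").upper()
        if not residues:
            raise FastaError(f"{path}: record {record.id!r} has no residues")
        if SENTINEL in residues:
            raise FastaError(
                f"{path}: record {record.id!r} contains the reserved symbol {SENTINEL!r}"
            )
        seqs.append(Sequence(id=record.id, residues=residues))
    if not seqs:
        raise FastaError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as out:
        for s in seqs:
            out.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                out.write(s.residues[i : i + width] + "\n")


def _format_occurrences(mr: MR) -> str:
    return ";".join(f"{sid}:{start}" for sid, start in mr.occurrences)


def mrs_to_frame(mrs: MRSet, occurrences: bool = True) -> pd.DataFrame:
    """Tabular view of an MRSet, longest patterns first (ties: lexicographic)."""
    rows = [
        {
            "pattern": m.pattern,
            "length": m.length,
            "n_instances": m.n_instances,
            "n_proteins": m.n_proteins,
            **({"occurrences": _format_occurrences(m)} if occurrences else {}),
        }
        for m in mrs
    ]
    df = pd.DataFrame(
        rows,
        columns=["pattern", "length", "n_instances", "n_proteins"]
        + (["occurrences"] if occurrences else []),
    )
    if len(df):
        df = df.sort_values(
            ["length", "pattern"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_mrs_tsv(mrs: MRSet, path: PathLike, occurrences: bool = True) -> None:
    mrs_to_frame(mrs, occurrences=occurrences).to_csv(path, sep="\t", index=False)


def write_catalogue(cat: Catalogue, path: PathLike, occurrences: bool = False) -> None:
    """Serialize a catalogue: '#' metadata header, then per-MR rows."""
    with open(path, "w") as out:
        out.write(f"#format={CATALOGUE_FORMAT}\n")
        out.write(f"#family_id={cat.family_id}\n")
        out.write(f"#n_sequences={cat.n_sequences}\n")
        out.write(f"#total_residues={cat.total_residues}\n")
        out.write(f"#alphabet={''.join(sorted(cat.alphabet))}\n")
        out.write(f"#seed={'' if cat.build_seed is None else cat.build_seed}\n")
        out.write(f"#min_stored_length={cat.min_stored_length}\n")
        out.write(
            f"#median_length={'' if cat.median_length is None else cat.median_length}\n"
        )
        mrs_to_frame(cat.mrs, occurrences=occurrences).to_csv(
            out, sep="\t", index=False
        )


def read_catalogue(path: PathLike) -> Catalogue:
    """Load a serialized catalogue; errors on version mismatch or truncation."""
    meta: dict[str, str] = {}
    with open(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
            pos = handle.tell()
            line = handle.readline()
        if meta.get("format") != CATALOGUE_FORMAT:
            raise ValueError(
                f"{path}: not a {CATALOGUE_FORMAT} file (format={meta.get('format')!r})"
            )
        for key in ("family_id", "n_sequences", "total_residues", "alphabet"):
            if key not in meta:
                raise ValueError(f"{path}: truncated catalogue header (missing {key})")
        handle.seek(pos)
        try:
            df = pd.read_csv(handle, sep="\t", dtype={"pattern": str})
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: truncated catalogue: no MR table") from None
    required = {"pattern", "length", "n_instances", "n_proteins"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: truncated catalogue: missing columns {sorted(required - set(df.columns))}"
        )
    members = {}
    for row in df.itertuples(index=False):
        occ: tuple = ()
        if hasattr(row, "occurrences") and isinstance(row.occurrences, str):
            occ = tuple(
                (sid, int(start))
                for sid, _, start in (o.partition(":") for o in row.occurrences.split(";"))
            )
        members[row.pattern] = MR(
            pattern=row.pattern,
            occurrences=occ,
            n_instances=int(row.n_instances),
            n_proteins=int(row.n_proteins),
        )
    n_sequences = int(meta["n_sequences"])
    total_residues = int(meta["total_residues"])
    return Catalogue(
        family_id=meta["family_id"],
        mrs=MRSet(members, source_length=total_residues, n_sequences=n_sequences),
        alphabet=frozenset(meta["alphabet"]),
        n_sequences=n_sequences,
        total_residues=total_residues,
        build_seed=int(meta["seed"]) if meta.get("seed") else None,
        min_stored_length=int(meta.get("min_stored_length", 1) or 1),
        median_length=float(meta["median_length"]) if meta.get("median_length") else None,
    )
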