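"""Familiarity-based family membership ranking with hold-out evaluation.

Queries held out of catalogue construction are scored against every family
catalogue; per query, families are ranked by descending familiarity (ties
broken by family id).  When the highest-ranked family is the query's home
family the classification is counted correct.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence as PySequence

import numpy as np
import pandas as pd

from .catalogue import Catalogue, build_catalogue
from .coverage_familiarity import DEFAULT_MAX_LEN, familiarity
from .mr_core import Sequence, as_sequence

#: Queries longer than this multiple of the family's median sequence length
#: get a multidomain note: only a segment of them may belong to the family,
#: which depresses coverage. No correction is applied.
MULTIDOMAIN_LENGTH_RATIO = 3.0


def holdout_split(
    family: PySequence, n_test: int = 10, seed: int = 0
) -> tuple[list[Sequence], list[Sequence]]:
    """Uniform random train/test split without replacement; deterministic
    given ``seed``; train and test partition the family."""
    seqs = [as_sequence(s, default_id=f"seq{i + 1}") for i, s in enumerate(family)]
    if n_test < 0:
        raise ValueError("n_test must be >= 0")
    if len(seqs) <= n_test:
        raise ValueError(
            f"family of {len(seqs)} sequences is too small for n_test={n_test}"
        )
    rng = np.random.default_rng(seed)
    test_idx = set(map(int, rng.choice(len(seqs), size=n_test, replace=False)))
    train = [s for i, s in enumerate(seqs) if i not in test_idx]
    test = [s for i, s in enumerate(seqs) if i in test_idx]
    return train, test


def rank_families(
    queries: Iterable,
    catalogues: PySequence[Catalogue],
    L: int = DEFAULT_MAX_LEN,
    home: Optional[Mapping[str, str]] = None,
    multidomain_ratio: float = MULTIDOMAIN_LENGTH_RATIO,
) -> pd.DataFrame:
    """Full query x family familiarity matrix with per-query rankings.

    ``home`` optionally maps query ids to their true family ids; rows then
    carry an ``is_home_family`` flag.  Ranks are dense 1..n_families per
    query, descending familiarity, ties broken by family_id ascending.
    """
    cats = list(catalogues)
    if not cats:
        raise ValueError("need at least one catalogue")
    rows = []
    for qi, q in enumerate(queries):
        q = as_sequence(q, default_id=f"query{qi + 1}")
        for cat in cats:
            fam = familiarity(q, cat, L=L)
            note = ""
            if (
                cat.median_length
                and len(q) > multidomain_ratio * cat.median_length
            ):
                note = "query much longer than family median; possibly multidomain"
            rows.append(
                {
                    "query_id": q.id,
                    "family_id": cat.family_id,
                    "familiarity": fam.value,
                    "note": note,
                }
            )
    report = pd.DataFrame(rows)
    report = report.sort_values(
        ["query_id", "familiarity", "family_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    report["rank"] = report.groupby("query_id").cumcount() + 1
    if home is not None:
        report["is_home_family"] = [
            home.get(q) == f for q, f in zip(report["query_id"], report["family_id"])
        ]
    return report


def holdout_experiment(
    families: Mapping[str, PySequence],
    n_test: int = 10,
    L: int = DEFAULT_MAX_LEN,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Hold out ``n_test`` sequences per family, build catalogues from the
    remainder only (no leakage), score every held-out sequence against every
    catalogue, and return (report, home-family top-1 accuracy)."""
    catalogues: list[Catalogue] = []
    queries: list[Sequence] = []
    home: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for family_id in sorted(families):
        split_seed = int(rng.integers(0, 2**31 - 1))
        train, test = holdout_split(families[family_id], n_test=n_test, seed=split_seed)
        catalogues.append(build_catalogue(train, family_id=family_id, build_seed=split_seed))
        for s in test:
            queries.append(s)
            home[s.id] = family_id
    report = rank_families(queries, catalogues, L=L, home=home)
    top1 = report[report["rank"] == 1]
    accuracy = float(top1["is_home_family"].mean()) if len(top1) else float("nan")
    return report, accuracy
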