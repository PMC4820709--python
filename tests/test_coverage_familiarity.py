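"""Coverage, coverage profiles and the familiarity statistic on the
hand-checkable fixtures plus the monotonicity/equivalence properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repfam import (
    Catalogue,
    build_catalogue,
    coverage,
    coverage_profile,
    familiarity,
    find_mrs,
    sequence_catalogue,
)
from repfam.coverage_familiarity import best_cover_array, naive_best_cover_array
from repfam.mr_core import MRSet


def test_coverage_toy_example(toys, s1_catalogue):
    assert coverage(toys["s1"], s1_catalogue.patterns) == pytest.approx(16 / 17)


def test_coverage_empty_pattern_set(toys):
    assert coverage(toys["s1"], set()) == 0.0


def test_coverage_family_patterns_on_external_query(toys):
    # positions of the two 'c' in abcabca are the only ones missed by {a,b,d,dd,ddd}
    assert coverage(toys["s5"], {"a", "b", "d", "dd", "ddd"}) == pytest.approx(5 / 7)


def test_best_cover_records_longest_occurrence(toys, s1_catalogue):
    best = best_cover_array(toys["s4"], s1_catalogue.patterns)
    assert best.tolist() == [4, 4, 4, 4, 3, 3, 3]


def test_profile_against_family_catalogue(toys, t1_catalogue):
    prof = coverage_profile(toys["s5"], t1_catalogue, L=7)
    assert prof.c == pytest.approx([1, 5 / 7, 0, 0, 0, 0, 0, 0])


def test_profile_self_run_of_one_symbol(toys):
    prof = coverage_profile(toys["s6"], sequence_catalogue(toys["s6"]), L=7)
    assert prof.c == pytest.approx([1, 1, 1, 1, 1, 1, 1, 0])


def test_profile_disjoint_alphabet_is_zero(toys, t1_catalogue):
    prof = coverage_profile("WWWW", t1_catalogue, L=5)
    assert prof.c == pytest.approx(np.zeros(6))


@pytest.mark.parametrize(
    "query, catalogue_fixture, expected",
    [
        ("s4", "s1_catalogue", 4 + 4 / 7 - 0.5),
        ("s5", "t1_catalogue", 1 + 5 / 7 - 0.5),
    ],
)
def test_familiarity_cross_examples(toys, query, catalogue_fixture, expected, request):
    cat = request.getfixturevalue(catalogue_fixture)
    assert familiarity(toys[query], cat, L=7).value == pytest.approx(expected)


@pytest.mark.parametrize("name, expected", [("s5", 4.5), ("s6", 6.5)])
def test_self_familiarity_examples(toys, name, expected):
    cat = sequence_catalogue(toys[name])
    assert familiarity(toys[name], cat, L=7).value == expected


def test_familiarity_printed_roundings(toys, s1_catalogue, t1_catalogue):
    assert round(familiarity(toys["s4"], s1_catalogue, L=7).value, 2) == 4.07
    assert round(familiarity(toys["s5"], t1_catalogue, L=7).value, 2) == 1.21


def test_trapezoid_equals_per_level_coverage_sum(toys, s1_catalogue, t1_catalogue):
    # the one-pass profile must equal summing coverage(s, MRs of length >= i)
    # level by level with endpoint halving
    for query, cat in [
        (toys["s4"], s1_catalogue),
        (toys["s5"], t1_catalogue),
        (toys["s5"], sequence_catalogue(toys["s5"])),
        (toys["s6"], sequence_catalogue(toys["s6"])),
    ]:
        L = 7
        per_level = np.zeros(L + 1)
        per_level[0] = sum(ch in cat.alphabet for ch in query.residues) / len(query)
        for i in range(1, L + 1):
            pats = {p for p in cat.patterns if len(p) >= i}
            per_level[i] = coverage(query, pats)
        expected = per_level.sum() - (per_level[0] + per_level[-1]) / 2
        assert familiarity(query, cat, L=L).value == pytest.approx(expected)


@pytest.mark.parametrize("n", range(2, 51))
def test_self_familiarity_closed_form_single_symbol_run(n):
    # a run a^n against itself: c_0..c_{n-1} = 1, c_n = 0 => n - 0.5
    s = "a" * n
    val = familiarity(s, sequence_catalogue(s), L=n).value
    assert val == pytest.approx(n - 0.5)


@st.composite
def query_and_catalogue(draw):
    alpha = "ACDE"
    q = draw(st.text(alphabet=st.sampled_from(alpha), min_size=1, max_size=50))
    members = draw(
        st.lists(
            st.text(alphabet=st.sampled_from(alpha), min_size=1, max_size=30),
            min_size=2,
            max_size=4,
        )
    )
    return q, build_catalogue(members, family_id="rand")


@settings(max_examples=80, derandomize=True, deadline=None)
@given(query_and_catalogue())
def test_profile_monotone_nonincreasing(qc):
    q, cat = qc
    c = coverage_profile(q, cat, L=8).c
    assert np.all(c[1:-1] >= c[2:] - 1e-12)
    assert c[0] >= c[1] - 1e-12
    assert np.all((0 <= c) & (c <= 1))


def test_familiarity_monotone_under_catalogue_growth(toys, t1_catalogue):
    rng = np.random.default_rng(3)
    alpha = "abcd"
    base_patterns = sorted(t1_catalogue.patterns)
    for _ in range(25):
        q = "".join(alpha[i] for i in rng.integers(4, size=20))
        grown = set(base_patterns) | {
            "".join(alpha[i] for i in rng.integers(4, size=int(rng.integers(1, 5))))
            for _ in range(3)
        }
        small = _patterns_catalogue(base_patterns, t1_catalogue)
        big = _patterns_catalogue(grown, t1_catalogue)
        assert (
            familiarity(q, big, L=8).value
            >= familiarity(q, small, L=8).value - 1e-12
        )


def _patterns_catalogue(patterns, template):
    # catalogue with an explicit pattern list (coverage only needs patterns
    # and the alphabet; occurrence metadata is irrelevant here)
    from repfam.mr_core import MR

    mrs = MRSet(
        {p: MR(pattern=p, occurrences=(), n_instances=2, n_proteins=1) for p in patterns},
        source_length=template.total_residues,
        n_sequences=template.n_sequences,
    )
    return Catalogue(
        family_id="grown",
        mrs=mrs,
        alphabet=frozenset("".join(patterns)),
        n_sequences=template.n_sequences,
        total_residues=template.total_residues,
    )


def test_automaton_matches_naive_scanning():
    rng = np.random.default_rng(11)
    alpha = "ACDEFG"
    for _ in range(100):
        q = "".join(alpha[i] for i in rng.integers(6, size=int(rng.integers(1, 200))))
        pats = {
            "".join(alpha[i] for i in rng.integers(6, size=int(rng.integers(1, 7))))
            for _ in range(int(rng.integers(0, 15)))
        }
        assert (best_cover_array(q, pats) == naive_best_cover_array(q, pats)).all()


def test_L_must_be_positive(toys, t1_catalogue):
    with pytest.raises(ValueError):
        coverage_profile(toys["s5"], t1_catalogue, L=0)
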