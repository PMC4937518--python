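"""Candidate pair enumeration and the six pair features."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlpcp.features import (
    COAPEX_VALUES,
    candidate_pairs,
    coapex,
    join_db_scores,
    load_score_table,
    ncc,
    pcc,
    pearson,
)
from xlpcp.peaks import Peak


def make_peak(gid, apex, values=None, n=48, width=2, source="mean"):
    values_full = np.zeros(n)
    lo, hi = max(1, apex - width), min(n, apex + width)
    if values is None:
        values_full[lo - 1 : hi] = 1.0
    else:
        values_full[lo - 1 : lo - 1 + len(values)] = values
    return Peak(
        group_id=gid, source=source, apex_fraction=apex,
        lo_fraction=lo, hi_fraction=hi, values=values_full,
        amplitude=float(values_full.max()),
    )


# ---------------------------------------------------------------------------
# candidate pairs
# ---------------------------------------------------------------------------


def test_pairs_within_one_fraction_distinct_groups():
    peaks = [make_peak("A", 10), make_peak("B", 10), make_peak("C", 11)]
    got = candidate_pairs(peaks)
    assert {(p.group_a, p.group_b) for p in got} == {
        ("A", "B"), ("A", "C"), ("B", "C")
    }


def test_same_group_and_distant_apexes_yield_no_pairs():
    assert candidate_pairs([make_peak("A", 10), make_peak("A", 11)]) == []
    assert candidate_pairs([make_peak("A", 10), make_peak("B", 12)]) == []


def test_ordered_mode_emits_both_orientations():
    peaks = [make_peak("A", 10), make_peak("B", 10)]
    assert len(candidate_pairs(peaks, ordered=True)) == 2


def test_pair_count_matches_brute_force_enumeration():
    rng = np.random.default_rng(3)
    combos = {
        (int(g), int(a))
        for g, a in zip(rng.integers(0, 60, 150), rng.integers(5, 45, 150))
    }
    peaks = [make_peak(f"G{g}", a) for g, a in sorted(combos)]
    got = candidate_pairs(peaks)
    brute = sum(
        1
        for p, q in combinations(peaks, 2)
        if p.group_id != q.group_id and abs(p.apex_fraction - q.apex_fraction) <= 1
    )
    assert len(got) == brute
    assert len({p.key for p in got}) == len(got)  # deterministic & unique


# ---------------------------------------------------------------------------
# coapex
# ---------------------------------------------------------------------------


def _rep_peaks(gid, apexes_by_rep):
    return {
        r: [make_peak(gid, a, source=f"rep{r}") for a in apexes]
        for r, apexes in apexes_by_rep.items()
    }


@pytest.mark.parametrize(
    "apexes_a, apexes_b, expected",
    [
        ({1: [21], 2: [21], 3: [21]}, {1: [21], 2: [21], 3: [21]}, 1.0),
        ({1: [21], 2: [21], 3: [20]}, {1: [21], 2: [21], 3: [21]}, 0.6),
        ({1: [21], 2: [5], 3: [30]}, {1: [21], 2: [6], 3: [31]}, 0.3),
        ({1: [10], 2: [10], 3: [10]}, {1: [11], 2: [12], 3: [9]}, 0.0),
        ({1: [10, 30]}, {2: [10], 3: [30]}, 0.0),  # never in the same replicate
        ({1: [10, 30], 2: [30]}, {1: [30], 2: [30]}, 0.6),  # any shared apex counts
    ],
)
def test_coapex_counts_replicates_with_exactly_shared_apex(
    apexes_a, apexes_b, expected
):
    got = coapex(_rep_peaks("A", apexes_a), _rep_peaks("B", apexes_b))
    assert got == expected


def test_coapex_takes_only_the_four_mapped_values():
    assert set(COAPEX_VALUES.values()) == {0.0, 0.3, 0.6, 1.0}


# ---------------------------------------------------------------------------
# ncc
# ---------------------------------------------------------------------------


def brute_force_ncc(a, b):
    """Independent oracle: explicit loop over every integer lag."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def max_cross(x, y):
        best = 0.0
        n, m = len(x), len(y)
        for lag in range(-(m - 1), n):
            s = 0.0
            for j in range(m):
                i = lag + j
                if 0 <= i < n:
                    s += x[i] * y[j]
            best = max(best, s)
        return best

    e1, e2 = max_cross(a, a), max_cross(b, b)
    if e1 == 0 or e2 == 0:
        return 0.0
    return max_cross(a, b) / max(e1, e2)


def test_ncc_identical_peaks_is_one():
    p = make_peak("A", 10, values=[0.2, 0.9, 1.0, 0.5, 0.1])
    assert ncc(p, p) == pytest.approx(1.0)


def test_ncc_worked_example():
    assert ncc(np.array([2.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.5)


def test_ncc_zero_peak_is_zero():
    assert ncc(np.zeros(5), np.array([1.0, 2.0, 1.0, 0.0, 0.0])) == 0.0


def test_ncc_matches_brute_force_oracle_and_invariances():
    rng = np.random.default_rng(12)
    for _ in range(100):
        a = rng.uniform(0, 1, rng.integers(2, 12))
        b = rng.uniform(0, 1, rng.integers(2, 12))
        got = ncc(a, b)
        assert got == pytest.approx(brute_force_ncc(a, b), abs=1e-12)
        assert 0.0 <= got <= 1.0
        assert ncc(b, a) == pytest.approx(got, abs=1e-12)
        # rescaling the shared intensity scale never changes the score
        assert ncc(3.7 * a, 3.7 * b) == pytest.approx(got, abs=1e-12)


# ---------------------------------------------------------------------------
# pcc
# ---------------------------------------------------------------------------


def test_pcc_identical_reflected_and_proportional():
    p = make_peak("A", 10, values=[0.1, 0.5, 1.0, 0.5, 0.1])
    assert pcc(p, p) == pytest.approx(1.0)
    reflected = make_peak(
        "B", 10, values=list(2 * np.mean([0.1, 0.5, 1.0, 0.5, 0.1]) - np.array([0.1, 0.5, 1.0, 0.5, 0.1]))
    )
    assert pcc(p, reflected) == pytest.approx(-1.0)
    assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)


def test_pcc_zero_variance_is_zero():
    assert pearson([1.0, 1.0, 1.0], [0.0, 2.0, 5.0]) == 0.0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0, 1), min_size=3, max_size=10),
    st.lists(st.floats(0, 1), min_size=3, max_size=10),
)
def test_pcc_symmetric_and_bounded(a, b):
    n = min(len(a), len(b))
    x, y = np.array(a[:n]), np.array(b[:n])
    r = pearson(x, y)
    assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
    assert pearson(y, x) == pytest.approx(r, abs=1e-12)


def test_pcc_uses_union_of_windows():
    # disjoint windows: over the union each vector has variance, and the
    # two peaks are anti-correlated (one is high where the other is zero)
    a = make_peak("A", 10, values=[1.0, 1.0, 1.0])
    b = make_peak("B", 16, values=[1.0, 1.0, 1.0], width=2)
    assert pcc(a, b) < 0


# ---------------------------------------------------------------------------
# database scores
# ---------------------------------------------------------------------------


def test_load_score_table_string_scale_and_max_duplicate(tmp_path):
    path = tmp_path / "string.tsv"
    path.write_text(
        "acc_a\tacc_b\tcombined_score\n"
        "P1\tQ1\t800\nQ1\tP1\t300\nP2\tQ1\tbad\nP3\tQ2\t150\n"
    )
    table = load_score_table(path)
    assert table[frozenset(("P1", "Q1"))] == pytest.approx(0.8)
    assert table[frozenset(("P3", "Q2"))] == pytest.approx(0.15)
    assert frozenset(("P2", "Q1")) not in table  # malformed row skipped


def test_join_db_scores_max_over_accessions_and_default_zero():
    pair = candidate_pairs([make_peak("grpA", 10), make_peak("grpB", 10)])[0]
    string = {frozenset(("P1", "Q1")): 0.3, frozenset(("P2", "Q1")): 0.7}
    join_db_scores(
        [pair], string, {}, {},
        {"grpA": ["P1", "P2"], "grpB": ["Q1"]},
    )
    assert pair.string_score == pytest.approx(0.7)
    assert pair.hippie_score == 0.0 and pair.mentha_score == 0.0
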