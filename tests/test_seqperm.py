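"""Smith-Waterman local alignment and the scrambled-sequence null."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitofuse.seqperm import (
    ScoringScheme,
    exceedance_fraction,
    scramble,
    scramble_test,
    smith_waterman,
    sw_score,
)

SCHEME = ScoringScheme()


# -- brute-force oracle ----------------------------------------------------


def _global_enum(a, b, mat, open_pen, ext):
    """Max score over every gapped alignment of full a vs full b
    (exhaustive recursion, no dynamic programming)."""
    best = [-1e18]

    def rec(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + mat[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score - (ext if prev == "D" else open_pen + ext), "D")
        if j < len(b):
            rec(i, j + 1, score - (ext if prev == "I" else open_pen + ext), "I")

    rec(0, 0, 0.0, None)
    return best[0]


def sw_bruteforce(a, b, scheme=SCHEME):
    """Local score by enumerating every substring pair (empty pair -> 0)."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best,
                        _global_enum(
                            a[i1:i2],
                            b[j1:j2],
                            scheme.matrix,
                            scheme.gap_open,
                            scheme.gap_extend,
                        ),
                    )
    return best


# -- scores ----------------------------------------------------------------


def test_hand_computed_scores():
    assert sw_score("AAA", "AAA") == 12.0  # three A<->A matches at +4
    assert sw_score("KWK", "AWA") == 11.0  # the single W<->W pair
    res = smith_waterman("KWK", "AWA")
    assert (res.a_start, res.a_end, res.b_start, res.b_end) == (1, 2, 1, 2)


def test_empty_sequences_score_zero():
    res = smith_waterman("", "ACDE")
    assert res.score == 0.0
    assert (res.a_start, res.a_end) == (0, 0)
    assert sw_score("ACDE", "") == 0.0


def test_invalid_residue_rejected():
    with pytest.raises(ValueError, match="invalid"):
        smith_waterman("AC1E", "ACDE")


def test_x_scores_neutral():
    assert sw_score("X", "W") == 0.0
    assert sw_score("AXA", "AWA") == 8.0  # two A matches, X<->W contributes 0


def test_matches_bruteforce_on_short_pairs(rng):
    alpha = "ACGT"
    for a, b in itertools.product(
        ("".join(p) for p in itertools.product(alpha, repeat=2)), repeat=2
    ):
        assert sw_score(a, b) == sw_bruteforce(a, b)
    for _ in range(12):
        a = "".join(rng.choice(list(alpha), rng.integers(3, 6)))
        b = "".join(rng.choice(list(alpha), rng.integers(3, 6)))
        assert sw_score(a, b) == sw_bruteforce(a, b)


@settings(max_examples=40, deadline=None)
@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=25),
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=25),
)
def test_score_symmetry(a, b):
    assert sw_score(a, b) == sw_score(b, a)


# -- scramble test ---------------------------------------------------------


def test_scramble_preserves_composition(rng):
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    shuffled = scramble(seq, rng)
    assert sorted(shuffled) == sorted(seq)
    assert shuffled != seq  # astronomically unlikely to collide


def test_self_alignment_dominates_scrambles(rng):
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
    res = scramble_test(seq, seq, n_each=100, seed=5)
    assert res.observed_score > res.null_scores.max()
    assert res.exceed_fraction == 0.0
    assert res.null_scores.size == 200


def test_exceedance_fraction_arithmetic():
    # 17 of 200 null scores at or above the observed -> 8.5%
    null = np.concatenate([np.full(17, 60.0), np.full(183, 30.0)])
    assert exceedance_fraction(null, 55.0) == pytest.approx(0.085)
    with pytest.raises(ValueError):
        exceedance_fraction([], 1.0)


def test_single_residue_scrambles_are_degenerate(rng):
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
    res = scramble_test(seq, "W", n_each=10, seed=1)
    # scrambles of "W" are identical, and permuting seq cannot change its
    # best single-residue match either: the whole null is one value
    assert np.unique(res.null_scores).size == 1
    assert res.exceed_fraction in (0.0, 1.0)


def test_seeded_determinism():
    a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    b = "GDVEKGKKIFIMKCSQCHTVEKGGKHKTGPNLH"
    r1 = scramble_test(a, b, n_each=20, seed=9)
    r2 = scramble_test(a, b, n_each=20, seed=9)
    assert np.array_equal(r1.null_scores, r2.null_scores)
    assert r1.exceed_fraction == r2.exceed_fraction


def test_requires_positive_n_each():
    with pytest.raises(ValueError):
        scramble_test("AAA", "CCC", n_each=0)
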