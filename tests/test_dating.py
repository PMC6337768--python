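"""Insertion dating: alignment oracle, K2P closed form, age recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repeatscape.dating import (
    SaturatedDivergenceError,
    age_summary,
    align_ltrs,
    count_substitutions,
    date_ltr_pair,
    insertion_time,
    kimura2p,
)
from repeatscape.simulate import evolve_ltr_pair, generate_background


def _affine_nw_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-4.0, extend=-1.0):
    """Brute-force affine-gap global alignment score (independent oracle)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + extend * (j - 1)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0:
                X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                              Y[i - 1][j] + open_)
            if j > 0:
                Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                              X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignLtrs:
    def test_identical_sequences_align_gapless(self):
        seq = generate_background(200, 0.4, seed=1)
        aln = align_ltrs(seq, seq)
        assert str(aln[0]) == str(aln[1]) == seq

    def test_single_deletion_case(self):
        aln = align_ltrs("ACGT", "AGT")
        assert str(aln[0]) == "ACGT"
        assert str(aln[1]) in ("A-GT", "AG-T")  # C-deletion, 5'-most placement
        assert aln.score == _affine_nw_score("ACGT", "AGT")

    def test_score_matches_bruteforce_on_short_pairs(self):
        # exhaustive-ish oracle over a deterministic sample of pairs <= 6 nt
        rng = np.random.default_rng(5)
        bases = "ACGT"
        pairs = [("".join(rng.choice(list(bases), size=rng.integers(1, 7))),
                  "".join(rng.choice(list(bases), size=rng.integers(1, 7))))
                 for _ in range(60)]
        pairs += [(a, b) for a, b in itertools.product(
            ["A", "AC", "ACG", "ACGT"], ["T", "TG", "TGC", "TGCA"])]
        for a, b in pairs:
            assert align_ltrs(a, b).score == pytest.approx(_affine_nw_score(a, b)), (a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_ltrs("", "ACGT")


class _FakeAlignment:
    def __init__(self, row_a, row_b):
        self._rows = (row_a, row_b)

    def __getitem__(self, i):
        return self._rows[i]


class TestCountSubstitutions:
    def test_single_transition_hand_count(self):
        a = "A" * 99 + "A"
        b = "A" * 99 + "G"
        P, Q, sites = count_substitutions(_FakeAlignment(a, b))
        assert (P, Q, sites) == (0.01, 0.0, 100)

    def test_mixed_hand_count(self):
        a = "ACGT" * 25
        b = list(a)
        for i in range(5):  # five A->G transitions
            b[4 * i] = "G"
        b[1] = "A"  # C->A transversion
        b[5] = "A"
        P, Q, sites = count_substitutions(_FakeAlignment(a, "".join(b)))
        assert (P, Q, sites) == (0.05, 0.02, 100)

    def test_gap_and_ambiguous_columns_excluded(self):
        P, Q, sites = count_substitutions(_FakeAlignment("AT-GN" + "A" * 20,
                                                         "AC-CN" + "A" * 20))
        assert sites == 23
        assert P == pytest.approx(1 / 23)  # T<->C transition
        assert Q == pytest.approx(1 / 23)  # G<->C transversion

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError):
            count_substitutions(_FakeAlignment("AAA---", "---TTT"))


class TestKimura2P:
    def test_zero_divergence(self):
        assert kimura2p(0.0, 0.0) == 0.0

    def test_closed_form_values(self):
        assert kimura2p(0.01, 0.0) == pytest.approx(-0.5 * math.log(0.98), rel=1e-12)
        expected = -0.5 * math.log(1 - 0.10 - 0.02) - 0.25 * math.log(1 - 0.04)
        assert kimura2p(0.05, 0.02) == pytest.approx(expected, rel=1e-12)

    def test_saturation_flagged(self):
        with pytest.raises(SaturatedDivergenceError):
            kimura2p(0.45, 0.12)

    @given(st.floats(min_value=0.0, max_value=0.40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p_at_zero_q(self, p):
        if p + 1e-4 < 0.5:
            assert kimura2p(p + 1e-4, 0.0) > kimura2p(p, 0.0)

    def test_estimator_matches_simulated_process(self):
        # Monte-Carlo cross-check at a high divergence (k = 0.3)
        anc = generate_background(1000, 0.36, seed=3)
        rng = np.random.default_rng(31)
        ks = []
        for _ in range(100):
            a, b = evolve_ltr_pair(anc, 0.15 / 1.3e-8, 1.3e-8, 2.0, rng)
            est, _ = date_ltr_pair(a, b)
            if est.k is not None:
                ks.append(est.k)
        assert abs(np.mean(ks) - 0.3) / 0.3 < 0.05


class TestInsertionTime:
    def test_zero_k(self):
        assert insertion_time(0.0) == 0.0

    def test_arithmetic(self):
        assert insertion_time(0.0101013, 1.3e-8) == pytest.approx(388511.5, rel=1e-4)
        assert insertion_time(0.026) == pytest.approx(1.0e6)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            insertion_time(0.1, 0.0)


class TestSymmetryAndRecovery:
    def test_dating_symmetric_under_ltr_swap(self):
        anc = generate_background(600, 0.36, seed=8)
        rng = np.random.default_rng(9)
        a, b = evolve_ltr_pair(anc, 1.5e6, 1.3e-8, 2.0, rng)
        est_ab, _ = date_ltr_pair(a, b)
        est_ba, _ = date_ltr_pair(b, a)
        assert est_ab.k == pytest.approx(est_ba.k)

    def test_age_recovery_median_error(self):
        # ages 0.5-3 My, 800-bp LTRs: median relative error small
        rng = np.random.default_rng(12)
        errors = []
        for _ in range(60):
            age = rng.uniform(0.5e6, 3.0e6)
            anc = generate_background(800, 0.36, rng)
            a, b = evolve_ltr_pair(anc, age, 1.3e-8, 2.0, rng)
            _, est_age = date_ltr_pair(a, b)
            errors.append(abs(est_age.T - age) / age)
        assert np.median(errors) <= 0.15


class TestAgeSummary:
    def test_mean_and_median(self):
        frame = pd.DataFrame({"T": [1e6, 2e6, 3e6], "superfamily": ["Copia"] * 3})
        summary = age_summary(frame)
        row = summary.iloc[0]
        assert row["mean"] == pytest.approx(2e6)
        assert row["median"] == pytest.approx(2e6)

    def test_saturated_excluded(self):
        frame = pd.DataFrame({"T": [1e6, np.nan], "superfamily": ["Copia", "Copia"]})
        assert age_summary(frame).iloc[0]["n"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            age_summary(pd.DataFrame(columns=["T", "superfamily"]))
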