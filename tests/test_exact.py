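"""Exact HWE / excess-het / Fisher tests against enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    excess_het_one_sided_exact,
    fisher_two_sided_exact,
    hwe_two_sided_exact,
)
from seqfinemap.exact import excess_het_phred, fisher_exact_2x2, hwe_exact_p

counts = st.integers(min_value=0, max_value=50)


class TestHWE:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((1, 0, 1), 1 / 3),  # enumeration over h in {0,2}: masses 1/3, 2/3
            ((5, 0, 0), 1.0),  # monomorphic: single configuration
            ((0, 2, 0), 1.0),  # h in {0,2}: masses 1/3, 2/3; observed is modal
            ((0, 7, 0), hwe_two_sided_exact(0, 7, 0)),  # extreme het excess
            ((25, 50, 25), hwe_two_sided_exact(25, 50, 25)),
        ],
    )
    def test_known_values(self, triple, expected):
        assert hwe_exact_p(*triple) == pytest.approx(expected, abs=1e-12)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(counts, counts, counts)
    def test_matches_enumeration(self, aa, ab, bb):
        """Two-sided exact P equals full heterozygote-count enumeration."""
        if aa + ab + bb == 0:
            return
        assert hwe_exact_p(aa, ab, bb) == pytest.approx(
            hwe_two_sided_exact(aa, ab, bb), abs=1e-9
        )

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(counts, counts, counts)
    def test_symmetry_and_range(self, aa, ab, bb):
        """P is invariant under swapping the homozygote classes and lies in (0,1]."""
        if aa + ab + bb == 0:
            return
        p = hwe_exact_p(aa, ab, bb)
        assert p == pytest.approx(hwe_exact_p(bb, ab, aa), abs=1e-12)
        assert 0.0 < p <= 1.0


class TestExcessHet:
    def test_small_example(self):
        # h in {0, 2}: P(h >= 2) = 2/3, phred = -10 log10(2/3)
        assert excess_het_phred(0, 2, 0) == pytest.approx(-10 * math.log10(2 / 3), abs=1e-9)

    def test_monomorphic_scores_zero(self):
        assert excess_het_phred(9, 0, 0) == 0.0

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(counts, counts, counts)
    def test_matches_one_sided_enumeration(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        p = excess_het_one_sided_exact(aa, ab, bb)
        assert excess_het_phred(aa, ab, bb) == pytest.approx(-10 * math.log10(p), abs=1e-9)
        assert excess_het_phred(aa, ab, bb) >= 0.0


class TestFisher:
    def test_identical_rows(self):
        p, odds = fisher_exact_2x2([[10, 90], [10, 90]])
        assert p == 1.0 and odds == 1.0

    def test_diagonal_table(self):
        # margins (3,3)/(3,3): masses 1/20, 9/20, 9/20, 1/20 -> P = 2/20
        p, odds = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert odds == math.inf

    def test_zero_cells_and_errors(self):
        assert math.isnan(fisher_exact_2x2([[0, 5], [0, 5]])[1])
        assert fisher_exact_2x2([[0, 3], [3, 0]])[1] == 0.0
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_symmetries(self, a, b, c, d):
        """P is invariant under transposing and under swapping both labels;
        the OR inverts exactly when columns swap."""
        if a + b + c + d == 0:
            return
        t = np.array([[a, b], [c, d]])
        p, odds = fisher_exact_2x2(t)
        assert p == pytest.approx(fisher_exact_2x2(t.T)[0], abs=1e-12)
        assert p == pytest.approx(fisher_exact_2x2(t[::-1, ::-1])[0], abs=1e-12)
        p_sw, odds_sw = fisher_exact_2x2(t[:, ::-1])
        assert p_sw == pytest.approx(p, abs=1e-12)
        if np.isfinite(odds) and odds > 0:
            assert odds_sw == pytest.approx(1.0 / odds, rel=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_matches_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2([[a, b], [c, d]])[0] == pytest.approx(
            fisher_two_sided_exact(a, b, c, d), abs=1e-12
        )
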