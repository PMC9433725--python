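"""Independent brute-force oracles used only by the tests.

Everything here is computed by exact integer/rational arithmetic or naive
linear scans, deliberately sharing no code with the package implementation.
"""

from fractions import Fraction
from math import comb, factorial


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by full hypergeometric enumeration (exact integers)."""
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(k, r1)
    masses = [comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)]
    obs = comb(r1, a) * comb(r2, k - a)
    total = sum(masses)
    return float(Fraction(sum(m for m in masses if m <= obs), total))


def hwe_masses(n_hom_ref: int, n_het: int, n_hom_alt: int):
    """Exact conditional heterozygote-count distribution given allele margins.

    Returns (het counts, Fraction masses, observed index).
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    m = min(n_alt, 2 * n - n_alt)
    hs = list(range(m % 2, m + 1, 2))
    weights = []
    for h in hs:
        hom_min = (m - h) // 2
        hom_maj = n - h - hom_min
        weights.append(
            Fraction(factorial(n) * 2**h, factorial(hom_min) * factorial(hom_maj) * factorial(h))
        )
    total = sum(weights)
    masses = [w / total for w in weights]
    return hs, masses, hs.index(n_het)


def hwe_two_sided_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    hs, masses, obs = hwe_masses(n_hom_ref, n_het, n_hom_alt)
    p = sum(m for m in masses if m <= masses[obs])
    return float(p)


def excess_het_one_sided_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    hs, masses, obs = hwe_masses(n_hom_ref, n_het, n_hom_alt)
    return float(sum(masses[obs:]))


def interval_contains_linear(intervals, chrom: str, position: int) -> bool:
    """Naive per-interval scan over raw (possibly unmerged) intervals."""
    return any(c == chrom and s <= position < e for c, s, e in intervals)


def two_pass_mean_sd(values):
    """Plain two-pass population mean and SD."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var**0.5
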