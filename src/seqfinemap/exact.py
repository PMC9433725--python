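"""Exact tests on genotype and allele counts.

The Hardy-Weinberg test is the exact conditional test: condition on the total
sample size ``n`` and the minor-allele count ``m``, enumerate every
heterozygote count ``h`` compatible with those margins (``h`` shares the
parity of ``m``), and weight each by the multinomial genotype mass

    P(h | n, m)  proportional to  n! / (n_hom_min! * n_hom_maj! * h!) * 2**h

where ``n_hom_min = (m - h) / 2`` and ``n_hom_maj = n - h - n_hom_min``.
The two-sided P sums all configurations whose conditional mass does not
exceed the observed one; the one-sided excess-heterozygosity P sums
configurations with ``h`` at least the observed count and is reported
phred-scaled (-10 log10 P), matching the convention of site annotations used
as hard filters in variant calling.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = ["hwe_exact_p", "excess_het_phred", "fisher_exact_2x2"]

# relative slack when comparing conditional masses, so configurations that are
# exact rational ties (e.g. mirror-symmetric ones) are included despite
# floating-point rounding
_TIE_REL = 1e-12


def _het_distribution(n_hom_ref: int, n_het: int, n_hom_alt: int):
    """Return (het counts, normalized masses, observed index)."""
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("Hardy-Weinberg test undefined for zero genotyped samples")
    n_alt = 2 * n_hom_alt + n_het
    m = min(n_alt, 2 * n - n_alt)  # minor-allele count
    hs = np.arange(m % 2, m + 1, 2)
    hom_min = (m - hs) // 2
    hom_maj = n - hs - hom_min
    log_mass = (
        gammaln(n + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
        - gammaln(hs + 1)
        + hs * math.log(2.0)
    )
    log_mass -= log_mass.max()
    mass = np.exp(log_mass)
    mass /= mass.sum()
    obs = int(np.searchsorted(hs, n_het))
    if obs >= len(hs) or hs[obs] != n_het:  # impossible margins cannot occur
        raise ValueError("heterozygote count incompatible with allele counts")
    return hs, mass, obs


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg P for one site's genotype counts.

    Sums the conditional masses of every heterozygote configuration no more
    probable than the observed one (ties included). Monomorphic sites have a
    single configuration and return 1.
    """
    hs, mass, obs = _het_distribution(n_hom_ref, n_het, n_hom_alt)
    p = float(mass[mass <= mass[obs] * (1.0 + _TIE_REL)].sum())
    return min(p, 1.0)


def excess_het_phred(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Phred-scaled one-sided exact P for heterozygote *excess*.

    P = sum of conditional masses with het count >= observed; the returned
    score is -10 log10 P (0 when the observed count is the minimum).
    """
    hs, mass, obs = _het_distribution(n_hom_ref, n_het, n_hom_alt)
    p = min(float(mass[obs:].sum()), 1.0)
    # mass sums to 1 so p > 0 always; guard anyway for pathological rounding
    p = max(p, 5e-324)
    return -10.0 * math.log10(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact P and sample odds ratio for a 2x2 table.

    P follows the "sum of equally-or-less-probable tables" convention; the
    odds ratio is the unconditional cross-product ratio a*d/(b*c), reported
    as ``inf`` when only b*c = 0 and NaN when the ratio is 0/0.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    p = float(_scipy_fisher(t, alternative="two-sided")[1])
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan
    return min(p, 1.0), odds
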