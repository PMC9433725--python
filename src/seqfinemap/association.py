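"""Per-variant allelic association against case/control status.

Each diploid contributes two alleles; the test is a two-sided Fisher exact
test on the (alt, ref) x (case, control) allele-count table, with the sample
cross-product odds ratio. A variant is "informative" when its P falls below
the selection threshold (default 0.001, no multiplicity adjustment: the
panel targets regions with previously established association).
"""

from __future__ import annotations

import numpy as np

from .datatypes import CASE, CONTROL, MISSING, AssociationResult, CohortGenotypes, VariantSite
from .exact import fisher_exact_2x2

DEFAULT_INFORMATIVE_P = 1e-3


def allele_counts(dosages: np.ndarray, phenotype: np.ndarray) -> np.ndarray | None:
    """2x2 allele table [[alt_case, ref_case], [alt_control, ref_control]].

    Missing genotypes are excluded entirely; returns None (untestable) when a
    phenotype group has no called genotype.
    """
    dosages = np.asarray(dosages)
    phenotype = np.asarray(phenotype)
    table = np.zeros((2, 2), dtype=np.int64)
    for i, ph in enumerate((CASE, CONTROL)):
        d = dosages[phenotype == ph]
        d = d[d != MISSING]
        if d.size == 0:
            return None
        alt = int(d.sum())
        table[i] = (alt, 2 * d.size - alt)
    return table


def test_site(
    site: VariantSite,
    dosages: np.ndarray,
    phenotype: np.ndarray,
    threshold: float = DEFAULT_INFORMATIVE_P,
) -> AssociationResult:
    table = allele_counts(dosages, phenotype)
    if table is None:
        return AssociationResult(
            site_id=site.site_id,
            region_id=site.region_id,
            counts=np.zeros((2, 2), dtype=np.int64),
            p_value=float("nan"),
            odds_ratio=float("nan"),
            af_case=float("nan"),
            af_control=float("nan"),
            informative=False,
            testable=False,
        )
    p, odds = fisher_exact_2x2(table)
    af_case = table[0, 0] / table[0].sum()
    af_control = table[1, 0] / table[1].sum()
    return AssociationResult(
        site_id=site.site_id,
        region_id=site.region_id,
        counts=table,
        p_value=p,
        odds_ratio=odds,
        af_case=float(af_case),
        af_control=float(af_control),
        informative=bool(p < threshold),
    )


def run_association(
    geno: CohortGenotypes,
    sites: list[VariantSite],
    threshold: float = DEFAULT_INFORMATIVE_P,
) -> list[AssociationResult]:
    """Test every site; excluded samples take no part.

    Results are ordered deterministically by (region_id, ascending P,
    site_id); untestable sites sort last within their region.
    """
    ok = ~np.asarray(geno.excluded, bool)
    phen = np.asarray(geno.phenotype)[ok]
    results = []
    for site in sites:
        j = geno.site_index(site.site_id)
        results.append(test_site(site, geno.dosage[ok, j], phen, threshold))
    results.sort(
        key=lambda r: (
            r.region_id,
            r.p_value if np.isfinite(r.p_value) else 2.0,
            r.site_id,
        )
    )
    return results
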