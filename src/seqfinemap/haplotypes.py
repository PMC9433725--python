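"""Sequential conditional decomposition of a region's informative variants.

A "haplotype" here is a statistical signal cluster, not a phased segment: the
group of variants whose association with the phenotype is absorbed once the
group's most associated variant (the lead SNP) enters a logistic model. The
procedure:

1. the variant with the smallest marginal Fisher P becomes the first lead;
2. every remaining variant is tested by logistic regression of case status on
   additive dosage, conditioning on all current leads; its conditional P is
   the Wald P of its own term;
3. while any variant retains conditional P below the continuation threshold
   (default 0.1), the smallest such becomes the next lead and all remaining
   variants are re-tested against the enlarged conditioning set;
4. on exit each non-lead variant is assigned to the lead it is most
   correlated with (cohort genotypic r^2), yielding a partition of the
   informative set.

Variants exactly collinear with (or separated against) the conditioning set
get conditional P = 1: they are by construction fully explained by the leads.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    CASE,
    MISSING,
    AssociationResult,
    CohortGenotypes,
    Haplotype,
    HaplotypeAssignment,
)
from .logistic import logistic_fit

DEFAULT_COND_P = 0.1


def ld_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (genotypic, phase-free).

    Computed over pairwise-complete samples; NaN when fewer than two complete
    pairs remain or either vector is constant.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    ok = (d1 != MISSING) & (d2 != MISSING) & np.isfinite(d1) & np.isfinite(d2)
    a, b = d1[ok], d2[ok]
    if a.size < 2 or a.min() == a.max() or b.min() == b.max():
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _conditional_p(
    y: np.ndarray, lead_cols: list[np.ndarray], v_col: np.ndarray
) -> float:
    """Wald P of v's dosage term given the leads; 1.0 on collinearity/separation."""
    cols = lead_cols + [v_col]
    X = np.column_stack(cols)
    ok = np.all(X != MISSING, axis=1)
    Xc, yc = X[ok], y[ok]
    if yc.size == 0 or yc.min() == yc.max():
        return 1.0
    if Xc[:, -1].min() == Xc[:, -1].max():
        return 1.0  # degenerate: constant candidate
    fit = logistic_fit(yc, Xc)
    if not fit.converged:
        return 1.0
    return float(fit.wald_p[-1])


def stepwise_decompose(
    region_id: str,
    informative: list[AssociationResult],
    geno: CohortGenotypes,
    cond_threshold: float = DEFAULT_COND_P,
    assign_threshold: float = DEFAULT_COND_P,
) -> HaplotypeAssignment:
    """Partition a region's informative variants into lead-tagged haplotypes.

    Ties in lead selection break toward the higher minor-allele frequency,
    then the lexicographically smaller site_id. An empty ``informative`` list
    yields an empty assignment.
    """
    assignment = HaplotypeAssignment(region_id=region_id)
    cands = [r for r in informative if r.testable]
    if not cands:
        return assignment

    ok = ~np.asarray(geno.excluded, bool)
    y = (np.asarray(geno.phenotype)[ok] == CASE).astype(float)
    col = {
        r.site_id: geno.dosage[ok, geno.site_index(r.site_id)].astype(float)
        for r in cands
    }

    def maf(sid: str) -> float:
        d = col[sid][col[sid] != MISSING]
        if d.size == 0:
            return 0.0
        af = d.sum() / (2 * d.size)
        return float(min(af, 1.0 - af))

    order_key = {r.site_id: (r.p_value, -maf(r.site_id), r.site_id) for r in cands}
    site_ids = [r.site_id for r in cands]

    leads: list[str] = [min(site_ids, key=lambda s: order_key[s])]
    discovery_p = {leads[0]: next(r.p_value for r in cands if r.site_id == leads[0])}
    cond_p: dict[str, float] = {}
    while True:
        rest = [s for s in site_ids if s not in leads]
        if not rest:
            break
        lead_cols = [col[s] for s in leads]
        cond_p = {v: _conditional_p(y, lead_cols, col[v]) for v in rest}
        below = [v for v in rest if cond_p[v] < cond_threshold]
        if not below:
            break
        new_lead = min(below, key=lambda s: (cond_p[s], -maf(s), s))
        discovery_p[new_lead] = cond_p[new_lead]
        leads.append(new_lead)

    haps = {
        lead: Haplotype(
            lead_site_id=lead,
            member_site_ids=[lead],
            conditional_p={lead: discovery_p[lead]},
            r2_to_lead={lead: 1.0},
        )
        for lead in leads
    }
    for v in site_ids:
        if v in leads:
            continue
        r2s = {lead: ld_r2(col[v], col[lead]) for lead in leads}
        # highest-r2 lead wins; ties (and all-NaN) break toward discovery order
        best, best_r2 = leads[0], -1.0
        for lead in leads:
            r2 = r2s[lead]
            if np.isfinite(r2) and r2 > best_r2:
                best, best_r2 = lead, r2
        hap = haps[best]
        hap.member_site_ids.append(v)
        hap.conditional_p[v] = cond_p.get(v, 1.0)
        hap.r2_to_lead[v] = r2s[best]
    assignment.haplotypes = [haps[lead] for lead in leads]
    return assignment


def decompose_all(
    assoc: list[AssociationResult],
    geno: CohortGenotypes,
    cond_threshold: float = DEFAULT_COND_P,
    assign_threshold: float = DEFAULT_COND_P,
) -> list[HaplotypeAssignment]:
    """Run the decomposition in every region holding >= 1 informative variant."""
    regions: dict[str, list[AssociationResult]] = {}
    for r in assoc:
        if r.informative:
            regions.setdefault(r.region_id, []).append(r)
    return [
        stepwise_decompose(rid, members, geno, cond_threshold, assign_threshold)
        for rid, members in sorted(regions.items())
    ]
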