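"""Model/results surface over the association and decomposition stages.

``FineMapModel`` holds a QC'd cohort plus analysis thresholds; ``fit()``
runs per-site allelic Fisher tests and the sequential conditional
decomposition in every region, returning a ``FineMapResults`` carrying the
per-site estimates (odds ratios, P-values, allele frequencies), the
haplotype partition with conditional P-values and r^2 to each lead, and a
``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import DEFAULT_INFORMATIVE_P, run_association
from .datatypes import (
    CASE,
    CONTROL,
    AssociationResult,
    CohortGenotypes,
    HaplotypeAssignment,
    VariantSite,
)
from .haplotypes import DEFAULT_COND_P, decompose_all


class FineMapModel:
    """Case-control fine-mapping of targeted regions.

    Parameters
    ----------
    geno : cohort genotypes (post-QC; excluded samples are ignored).
    sites : the retained variant sites.
    informative_p : marginal Fisher threshold for the informative set.
    cond_p : continuation/assignment threshold of the stepwise conditional
        logistic regression.
    """

    def __init__(
        self,
        geno: CohortGenotypes,
        sites: list[VariantSite],
        informative_p: float = DEFAULT_INFORMATIVE_P,
        cond_p: float = DEFAULT_COND_P,
    ):
        missing = [s.site_id for s in sites if s.site_id not in set(geno.site_ids)]
        if missing:
            raise ValueError(f"sites absent from genotype matrix: {missing[:5]}")
        self.geno = geno
        self.sites = list(sites)
        self.informative_p = informative_p
        self.cond_p = cond_p

    @classmethod
    def from_files(
        cls,
        vcf_path,
        sample_table_path,
        regions_path=None,
        **kwargs,
    ) -> "FineMapModel":
        from . import io as io_mod

        table = io_mod.read_sample_table(sample_table_path)
        regions = io_mod.read_regions(regions_path) if regions_path else None
        sites, geno = io_mod.read_vcf(vcf_path, table, regions)
        return cls(geno, sites, **kwargs)

    def fit(self) -> "FineMapResults":
        assoc = run_association(self.geno, self.sites, self.informative_p)
        haps = decompose_all(assoc, self.geno, self.cond_p, self.cond_p)
        return FineMapResults(self, assoc, haps)


class FineMapResults:
    """Fitted association and haplotype-decomposition results."""

    def __init__(
        self,
        model: FineMapModel,
        association: list[AssociationResult],
        haplotypes: list[HaplotypeAssignment],
    ):
        self.model = model
        self.association = association
        self.haplotypes = haplotypes

    @property
    def informative(self) -> list[AssociationResult]:
        return [r for r in self.association if r.informative]

    @property
    def association_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.association:
            rows.append(
                {
                    "region_id": r.region_id,
                    "site_id": r.site_id,
                    "alt_case": int(r.counts[0, 0]),
                    "ref_case": int(r.counts[0, 1]),
                    "alt_control": int(r.counts[1, 0]),
                    "ref_control": int(r.counts[1, 1]),
                    "af_case": r.af_case,
                    "af_control": r.af_control,
                    "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                    "informative": r.informative,
                    "testable": r.testable,
                }
            )
        return pd.DataFrame(rows)

    @property
    def haplotype_frame(self) -> pd.DataFrame:
        rows = []
        for assignment in self.haplotypes:
            for idx, hap in enumerate(assignment.haplotypes, start=1):
                for member in hap.member_site_ids:
                    rows.append(
                        {
                            "region_id": assignment.region_id,
                            "haplotype_index": idx,
                            "lead_site_id": hap.lead_site_id,
                            "member_site_id": member,
                            "conditional_p": hap.conditional_p[member],
                            "r2_to_lead": hap.r2_to_lead[member],
                        }
                    )
        return pd.DataFrame(rows)

    def save(self, out_dir, qc_report=None):
        from . import io as io_mod
        from .datatypes import QCReport

        qc = qc_report if qc_report is not None else QCReport(n_input=len(self.model.sites))
        return io_mod.write_results(self.association, self.haplotypes, qc, out_dir)

    def summary(self) -> str:
        geno = self.model.geno
        ok = ~np.asarray(geno.excluded, bool)
        phen = np.asarray(geno.phenotype)[ok]
        n_case = int((phen == CASE).sum())
        n_ctrl = int((phen == CONTROL).sum())
        lines = [
            "Case-control fine-mapping results",
            "=" * 64,
            f"Samples: {n_case + n_ctrl} ({n_case} cases / {n_ctrl} controls)"
            f"    Sites tested: {len(self.association)}",
            f"Informative threshold: P < {self.model.informative_p:g}    "
            f"Conditional threshold: P < {self.model.cond_p:g}",
            f"Informative variants: {len(self.informative)}",
            "-" * 64,
        ]
        by_region: dict[str, list[AssociationResult]] = {}
        for r in self.association:
            by_region.setdefault(r.region_id, []).append(r)
        assignments = {h.region_id: h for h in self.haplotypes}
        for rid in sorted(by_region):
            rows = by_region[rid]
            n_info = sum(r.informative for r in rows)
            assignment = assignments.get(rid)
            n_hap = len(assignment.haplotypes) if assignment else 0
            lines.append(
                f"region {rid}: {len(rows)} sites, {n_info} informative, {n_hap} haplotypes"
            )
            if assignment:
                assoc_by_id = {r.site_id: r for r in rows}
                for idx, hap in enumerate(assignment.haplotypes, start=1):
                    lead = assoc_by_id[hap.lead_site_id]
                    odds = (
                        f"{lead.odds_ratio:.2f}"
                        if np.isfinite(lead.odds_ratio)
                        else str(lead.odds_ratio)
                    )
                    lines.append(
                        f"  haplotype {idx}: lead {hap.lead_site_id}  "
                        f"OR={odds}  P={lead.p_value:.2e}  "
                        f"members={len(hap.member_site_ids)}"
                    )
        lines.append("=" * 64)
        return "\n".join(lines)
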