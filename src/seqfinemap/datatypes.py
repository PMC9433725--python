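"""Core in-memory containers shared by every stage of the pipeline.

Conventions
-----------
* Genotypes are stored as additive alt-allele dosages in ``{0, 1, 2}`` with
  ``-1`` marking a missing call (half-calls count as missing).
* VCF positions are 1-based; interval sets (BED) are 0-based half-open. A
  variant at position ``pos`` overlaps an interval ``[start, end)`` iff
  ``pos - 1`` lies in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING = -1  # dosage sentinel for an uncalled / half-called genotype

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site on the target panel."""

    site_id: str  # "chrom:pos:ref:alt"
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    region_id: str
    external_pass: bool = True
    reference_af: Optional[float] = None  # e.g. gnomAD-NFE AF; None = absent

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"{self.site_id}: empty allele")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.site_id}: ref and alt alleles are identical")
        if self.reference_af is not None and not 0.0 <= self.reference_af <= 1.0:
            raise ValueError(f"{self.site_id}: reference_af outside [0, 1]")


@dataclass
class CohortGenotypes:
    """Samples x sites dosage matrix with genotype qualities and metadata.

    Attributes
    ----------
    dosage : (n_samples, n_sites) int8 array, values {0,1,2,MISSING}
    gq : (n_samples, n_sites) float array or None when GQ was unavailable;
        entries at missing dosages are NaN and never enter site means.
    phenotype : per-sample "case"/"control"
    batch : per-sample sequencing-batch label
    excluded : per-sample flag (e.g. ancestry exclusion); excluded samples
        take no part in any filter or test.
    """

    sample_ids: list[str]
    site_ids: list[str]
    dosage: np.ndarray
    gq: Optional[np.ndarray]
    phenotype: np.ndarray
    batch: np.ndarray
    excluded: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.site_ids)
        if self.dosage.shape != (n, m):
            raise ValueError(f"dosage shape {self.dosage.shape} != ({n}, {m})")
        if self.gq is not None and self.gq.shape != self.dosage.shape:
            raise ValueError("gq shape differs from dosage shape")
        for arr, name in [
            (self.phenotype, "phenotype"),
            (self.batch, "batch"),
            (self.excluded, "excluded"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length != n_samples")
        bad = set(np.asarray(self.phenotype)[~np.asarray(self.excluded, bool)]) - {
            CASE,
            CONTROL,
        }
        if bad:
            raise ValueError(f"phenotype values outside {{case, control}}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the genotype call is missing."""
        return self.dosage == MISSING

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise KeyError(site_id) from None

    def subset_sites(self, keep: list[str]) -> "CohortGenotypes":
        idx = [self.site_index(s) for s in keep]
        return CohortGenotypes(
            sample_ids=self.sample_ids,
            site_ids=list(keep),
            dosage=self.dosage[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            phenotype=self.phenotype,
            batch=self.batch,
            excluded=self.excluded,
        )


class IntervalSet:
    """Sorted, merged, 0-based half-open genomic intervals (BED semantics)."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
        merged: dict[str, list[tuple[int, int]]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[tuple[int, int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:  # abutting intervals merge too
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[chrom] = out
        self._starts = {c: np.array([s for s, _ in iv]) for c, iv in merged.items()}
        self._ends = {c: np.array([e for _, e in iv]) for c, iv in merged.items()}

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def contains(self, chrom: str, position: int) -> bool:
        """Membership of a 0-based position."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, position, side="right")) - 1
        return i >= 0 and position < self._ends[chrom][i]


@dataclass
class AssociationResult:
    """Allelic case-control test at one site.

    ``counts`` rows are (case, control), columns (alt, ref); the odds ratio is
    the cross-product ratio alt_case*ref_control / (ref_case*alt_control),
    with 0/inf sentinels for zero cells and NaN when undefined (0/0).
    """

    site_id: str
    region_id: str
    counts: np.ndarray  # 2x2 int, [[alt_case, ref_case], [alt_ctrl, ref_ctrl]]
    p_value: float
    odds_ratio: float
    af_case: float
    af_control: float
    informative: bool
    testable: bool = True


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept first, then dosage terms)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_p: np.ndarray
    converged: bool
    n_used: int


@dataclass
class Haplotype:
    """One statistical signal: a lead SNP plus the variants it explains."""

    lead_site_id: str
    member_site_ids: list[str]  # lead included
    conditional_p: dict[str, float]  # per member, at assignment time
    r2_to_lead: dict[str, float]


@dataclass
class HaplotypeAssignment:
    """Decomposition of one region's informative variants into haplotypes."""

    region_id: str
    haplotypes: list[Haplotype] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)

    @property
    def lead_site_ids(self) -> list[str]:
        return [h.lead_site_id for h in self.haplotypes]

    @property
    def n_members(self) -> int:
        return sum(len(h.member_site_ids) for h in self.haplotypes)


@dataclass
class QCReport:
    """Audit trail of the QC cascade.

    ``per_site_flags`` holds, for every removed site, the label of the filter
    that removed it (a site removed at step k is not re-evaluated later, so
    each removed site carries exactly one label; labels are from
    {hwe, mean_gq, missingness, not_in_all_batches, lcr, diff_missingness,
    excess_het, external_fail, af_zscore}).
    """

    n_input: int
    per_site_flags: dict[str, set[str]] = field(default_factory=dict)
    per_filter_counts: dict[str, int] = field(default_factory=dict)
    step_removed: dict[str, str] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.per_site_flags)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed
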