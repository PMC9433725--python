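"""Variant-level QC cascade for a two-batch case-control cohort.

The cascade applies hard site filters in a fixed order, mirroring common
practice for targeted resequencing panels:

1. ``hwe`` -- exact Hardy-Weinberg P < 0.001 in either control batch;
2. ``mean_gq`` -- mean genotype quality < 30 in any (batch x phenotype) group;
3. ``missingness`` -- missing-call fraction > 0.05 in any group;
4. ``not_in_all_batches`` -- batch consolidation: sites with no called
   genotype in an entire batch (batch-private sites) are dropped;
5. ``lcr`` -- overlap with a low-complexity region;
6. ``diff_missingness`` -- Fisher exact P < 0.05 for missingness differing
   between cases and controls;
7. ``excess_het`` -- phred-scaled one-sided excess-heterozygosity score at or
   above the score corresponding to P = 3.4e-6;
8. ``external_fail`` -- an externally supplied pass/fail flag (stand-in for
   recalibration tranches / external-database PASS status);
9. ``af_zscore`` -- |z| >= 9 for the control-vs-reference allele-frequency
   difference, standardized by the mean/SD of that difference across all
   sites carrying a reference AF.

A site removed at step k is never re-evaluated later, so the audit counts are
attributable: each removed site carries exactly one filter label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import CASE, CONTROL, MISSING, CohortGenotypes, IntervalSet, QCReport, VariantSite
from .exact import excess_het_phred, fisher_exact_2x2, hwe_exact_p

logger = logging.getLogger(__name__)

FILTER_ORDER = [
    "hwe",
    "mean_gq",
    "missingness",
    "not_in_all_batches",
    "lcr",
    "diff_missingness",
    "excess_het",
    "external_fail",
    "af_zscore",
]


@dataclass
class GroupSpec:
    """Partition of the non-excluded samples by (batch, phenotype)."""

    groups: dict[tuple[str, str], np.ndarray]  # (batch, phenotype) -> sample idx

    @classmethod
    def from_cohort(cls, geno: CohortGenotypes) -> "GroupSpec":
        ok = ~np.asarray(geno.excluded, bool)
        batches = np.asarray(geno.batch)
        phen = np.asarray(geno.phenotype)
        groups = {}
        for b in sorted(set(batches[ok])):
            for ph in (CASE, CONTROL):
                idx = np.flatnonzero(ok & (batches == b) & (phen == ph))
                if idx.size:
                    groups[(str(b), ph)] = idx
        return cls(groups)

    @property
    def control_groups(self) -> dict[tuple[str, str], np.ndarray]:
        return {k: v for k, v in self.groups.items() if k[1] == CONTROL}

    def batch_members(self) -> dict[str, np.ndarray]:
        out: dict[str, list[np.ndarray]] = {}
        for (b, _), idx in self.groups.items():
            out.setdefault(b, []).append(idx)
        return {b: np.concatenate(v) for b, v in out.items()}


@dataclass
class QCConfig:
    """Thresholds of the cascade; defaults are the pipeline's standard values."""

    hwe_p: float = 1e-3
    mean_gq_min: float = 30.0
    max_missing: float = 0.05
    diff_missing_p: float = 0.05
    excess_het_p: float = 3.4e-6
    af_z: float = 9.0
    disabled: set[str] = field(default_factory=set)


def _genotype_counts(dosage_col: np.ndarray, idx: np.ndarray) -> tuple[int, int, int]:
    d = dosage_col[idx]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def filter_hwe(
    geno: CohortGenotypes,
    groups: GroupSpec,
    threshold: float = 1e-3,
    site_ids: list[str] | None = None,
) -> set[str]:
    """Sites with exact HWE P < threshold in either control group (cases never enter)."""
    site_ids = site_ids if site_ids is not None else geno.site_ids
    flagged: set[str] = set()
    controls = groups.control_groups
    for sid in site_ids:
        j = geno.site_index(sid)
        col = geno.dosage[:, j]
        for idx in controls.values():
            counts = _genotype_counts(col, idx)
            if sum(counts) == 0:
                continue  # no genotyped control in this group: exempt here
            if hwe_exact_p(*counts) < threshold:
                flagged.add(sid)
                break
    return flagged


def filter_mean_gq(
    geno: CohortGenotypes,
    groups: GroupSpec,
    threshold: float = 30.0,
    site_ids: list[str] | None = None,
) -> set[str]:
    """Sites whose mean GQ over called genotypes falls below threshold in any group."""
    if geno.gq is None:
        logger.warning("GQ unavailable: mean-GQ filter skipped")
        return set()
    site_ids = site_ids if site_ids is not None else geno.site_ids
    flagged: set[str] = set()
    for sid in site_ids:
        j = geno.site_index(sid)
        called = geno.dosage[:, j] != MISSING
        for idx in groups.groups.values():
            vals = geno.gq[idx[called[idx]], j]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            if float(vals.mean()) < threshold:
                flagged.add(sid)
                break
    return flagged


def filter_missingness(
    geno: CohortGenotypes,
    groups: GroupSpec,
    threshold: float = 0.05,
    site_ids: list[str] | None = None,
) -> set[str]:
    """Sites with missing-genotype fraction strictly above threshold in any group."""
    site_ids = site_ids if site_ids is not None else geno.site_ids
    flagged: set[str] = set()
    for sid in site_ids:
        j = geno.site_index(sid)
        miss = geno.dosage[:, j] == MISSING
        for idx in groups.groups.values():
            if idx.size and miss[idx].mean() > threshold:
                flagged.add(sid)
                break
    return flagged


def intersect_batches(flags_by_group: dict[str, set[str]]) -> set[str]:
    """Union of per-group flag sets: a site failing in any group is not common to all."""
    out: set[str] = set()
    for flags in flags_by_group.values():
        out |= flags
    return out


def batch_private_sites(
    geno: CohortGenotypes, groups: GroupSpec, site_ids: list[str] | None = None
) -> set[str]:
    """Sites with zero called genotypes in an entire batch."""
    site_ids = site_ids if site_ids is not None else geno.site_ids
    flagged: set[str] = set()
    members = groups.batch_members()
    for sid in site_ids:
        j = geno.site_index(sid)
        called = geno.dosage[:, j] != MISSING
        for idx in members.values():
            if idx.size and not called[idx].any():
                flagged.add(sid)
                break
    return flagged


def filter_lcr(sites: list[VariantSite], lcr: IntervalSet | None) -> set[str]:
    """Sites overlapping a low-complexity interval (pos-1 in [start, end))."""
    if lcr is None:
        return set()
    return {s.site_id for s in sites if lcr.contains(s.chrom, s.pos - 1)}


def filter_diff_missingness(
    geno: CohortGenotypes,
    threshold: float = 0.05,
    site_ids: list[str] | None = None,
) -> set[str]:
    """Sites where missingness differs between cases and controls (Fisher P < threshold)."""
    site_ids = site_ids if site_ids is not None else geno.site_ids
    ok = ~np.asarray(geno.excluded, bool)
    phen = np.asarray(geno.phenotype)
    cases = np.flatnonzero(ok & (phen == CASE))
    ctrls = np.flatnonzero(ok & (phen == CONTROL))
    flagged: set[str] = set()
    for sid in site_ids:
        j = geno.site_index(sid)
        miss = geno.dosage[:, j] == MISSING
        mc, gc = int(miss[cases].sum()), int(cases.size - miss[cases].sum())
        mk, gk = int(miss[ctrls].sum()), int(ctrls.size - miss[ctrls].sum())
        if mc + mk == 0:
            continue  # no missingness anywhere: P = 1
        p, _ = fisher_exact_2x2([[mc, gc], [mk, gk]])
        if p < threshold:
            flagged.add(sid)
    return flagged


def filter_excess_het(
    geno: CohortGenotypes,
    threshold_p: float = 3.4e-6,
    site_ids: list[str] | None = None,
) -> set[str]:
    """Sites whose phred-scaled excess-het score reaches the score for threshold_p.

    Computed on all non-excluded samples; flag iff score >= -10 log10(threshold_p),
    equivalently one-sided P <= threshold_p.
    """
    site_ids = site_ids if site_ids is not None else geno.site_ids
    phred_cut = -10.0 * np.log10(threshold_p)
    ok = np.flatnonzero(~np.asarray(geno.excluded, bool))
    flagged: set[str] = set()
    for sid in site_ids:
        j = geno.site_index(sid)
        counts = _genotype_counts(geno.dosage[:, j], ok)
        if sum(counts) == 0:
            continue
        if excess_het_phred(*counts) >= phred_cut:
            flagged.add(sid)
    return flagged


def filter_external_flag(sites: list[VariantSite]) -> set[str]:
    """Sites carrying an external fail flag (absence from the flag table = pass)."""
    return {s.site_id for s in sites if not s.external_pass}


def control_allele_freq(
    geno: CohortGenotypes, site_ids: list[str] | None = None
) -> dict[str, float]:
    """Alt-allele frequency among called genotypes of non-excluded controls."""
    site_ids = site_ids if site_ids is not None else geno.site_ids
    ok = ~np.asarray(geno.excluded, bool)
    ctrl = np.flatnonzero(ok & (np.asarray(geno.phenotype) == CONTROL))
    out = {}
    for sid in site_ids:
        j = geno.site_index(sid)
        d = geno.dosage[ctrl, j]
        called = d != MISSING
        n = int(called.sum())
        out[sid] = float(d[called].sum() / (2 * n)) if n else float("nan")
    return out


def filter_af_zscore(
    sites: list[VariantSite],
    control_af: dict[str, float],
    threshold: float = 9.0,
) -> set[str]:
    """Reference-AF outlier filter.

    X_i = control AF - reference AF at each site carrying a reference AF;
    z_i = (X_i - mean(X)) / sd(X) with population (ddof=0) statistics over the
    eligible sites; flag iff |z_i| >= threshold. Sites without a reference AF
    are exempt.
    """
    eligible = [s for s in sites if s.reference_af is not None and np.isfinite(control_af.get(s.site_id, np.nan))]
    if len(eligible) < 2:
        logger.warning("fewer than 2 sites with reference AF: z-score filter skipped")
        return set()
    x = np.array([control_af[s.site_id] - s.reference_af for s in eligible])
    mu, sigma = float(x.mean()), float(x.std(ddof=0))
    if sigma == 0.0:
        logger.warning("zero spread in AF differences: z-score filter skipped")
        return set()
    z = (x - mu) / sigma
    return {s.site_id for s, zi in zip(eligible, z) if abs(zi) >= threshold}


def run_qc(
    geno: CohortGenotypes,
    sites: list[VariantSite],
    lcr: IntervalSet | None = None,
    config: QCConfig | None = None,
    groups: GroupSpec | None = None,
) -> tuple[list[VariantSite], QCReport]:
    """Apply the full cascade; return retained sites and the audit report.

    Sites removed at one step are not evaluated at later steps, so
    ``per_filter_counts`` attributes every removed site to exactly one filter.
    """
    config = config or QCConfig()
    groups = groups or GroupSpec.from_cohort(geno)
    by_id = {s.site_id: s for s in sites}
    if len(by_id) != len(sites):
        raise ValueError("duplicate site_id in input sites")
    alive: list[str] = [s.site_id for s in sites]
    report = QCReport(n_input=len(sites))
    report.per_filter_counts = {label: 0 for label in FILTER_ORDER}

    def apply(label: str, flagged: set[str]) -> None:
        nonlocal alive
        flagged &= set(alive)
        for sid in flagged:
            report.per_site_flags[sid] = {label}
            report.step_removed[sid] = label
        report.per_filter_counts[label] = len(flagged)
        alive = [sid for sid in alive if sid not in flagged]

    def enabled(label: str) -> bool:
        return label not in config.disabled

    if enabled("hwe"):
        apply("hwe", filter_hwe(geno, groups, config.hwe_p, alive))
    if enabled("mean_gq"):
        apply("mean_gq", filter_mean_gq(geno, groups, config.mean_gq_min, alive))
    if enabled("missingness"):
        apply("missingness", filter_missingness(geno, groups, config.max_missing, alive))
    if enabled("not_in_all_batches"):
        apply("not_in_all_batches", batch_private_sites(geno, groups, alive))
    if enabled("lcr"):
        apply("lcr", filter_lcr([by_id[s] for s in alive], lcr))
    if enabled("diff_missingness"):
        apply("diff_missingness", filter_diff_missingness(geno, config.diff_missing_p, alive))
    if enabled("excess_het"):
        apply("excess_het", filter_excess_het(geno, config.excess_het_p, alive))
    if enabled("external_fail"):
        apply("external_fail", filter_external_flag([by_id[s] for s in alive]))
    if enabled("af_zscore"):
        ctrl_af = control_allele_freq(geno, alive)
        apply("af_zscore", filter_af_zscore([by_id[s] for s in alive], ctrl_af, config.af_z))

    retained = [by_id[sid] for sid in alive]
    return retained, report
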