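"""Synthetic two-batch case-control cohorts with LD structure and QC artifacts.

Genotypes are composed from regional founder-haplotype pools by a mosaic
process: each individual haplotype starts on a founder drawn from the pool
frequencies and switches to a freshly drawn founder at each site with
probability ``mosaic_switch_rate``, producing block-wise linkage
disequilibrium that decays with distance. Disease status follows an additive
logistic model on the planted causal dosages,

    logit P(case) = logit(baseline_prevalence) + sum_j ln(OR_j) * dosage_j,

and the case-control design is ascertained by rejection sampling from that
population model until both quotas fill (when nothing is causal the draw is
a plain population sample with labels assigned by quota).

QC artifacts are injected on disjoint, configurable site sets so that every
filter of the cascade has attributable ground truth: Hardy-Weinberg
violations (inbreeding-like het deficit in controls), heterozygote excess
(in cases, so the controls-only HWE filter stays blind to it), degraded mean
GQ, uniform and phenotype-differential missingness, reference-AF shifts,
low-complexity-region overlap and external fail flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .datatypes import (
    CASE,
    CONTROL,
    MISSING,
    CohortGenotypes,
    IntervalSet,
    VariantSite,
)

SiteKey = tuple[str, int]  # (region_id, site index within region)

ARTIFACT_CLASSES = [
    "hwe_violation",
    "excess_het",
    "low_gq",
    "high_missingness",
    "differential_missingness",
    "af_shift",
    "lcr_overlap",
    "external_fail",
]


@dataclass
class RegionConfig:
    """One target region: founder pool plus coordinates."""

    region_id: str
    chrom: str
    start: int  # 1-based position of the first site
    founders: np.ndarray  # (K, n_sites) 0/1 founder haplotypes
    founder_freqs: np.ndarray  # (K,), sums to 1
    spacing: int = 100  # bp between adjacent sites

    def __post_init__(self) -> None:
        self.founders = np.asarray(self.founders, dtype=np.int8)
        self.founder_freqs = np.asarray(self.founder_freqs, dtype=float)
        if self.founders.ndim != 2:
            raise ValueError("founders must be a (K, n_sites) matrix")
        if len(self.founder_freqs) != self.founders.shape[0]:
            raise ValueError("founder_freqs length != number of founders")
        if abs(self.founder_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("founder frequencies must sum to 1")
        if ((self.founder_freqs < 0) | (self.founder_freqs > 1)).any():
            raise ValueError("founder frequencies outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.founders.shape[1]

    @property
    def pool_af(self) -> np.ndarray:
        return self.founder_freqs @ self.founders


@dataclass
class ArtifactPlan:
    """Planted QC-artifact site sets (disjoint) and their magnitudes."""

    hwe_violation: list[SiteKey] = field(default_factory=list)
    hwe_inbreeding: float = 1.0  # F in [0,1]; 1 = no heterozygotes at all
    excess_het: list[SiteKey] = field(default_factory=list)
    excess_het_coef: float = 1.0  # mix toward all-het; 1 = every case het
    low_gq: list[SiteKey] = field(default_factory=list)
    low_gq_mean: float = 15.0
    low_gq_sd: float = 3.0
    high_missingness: list[SiteKey] = field(default_factory=list)
    high_missing_rate: float = 0.3
    differential_missingness: list[SiteKey] = field(default_factory=list)
    diff_missing_case_rate: float = 0.02
    diff_missing_control_rate: float = 0.0
    af_shift: list[SiteKey] = field(default_factory=list)
    af_shift_delta: float = 0.7
    lcr_overlap: list[SiteKey] = field(default_factory=list)
    external_fail: list[SiteKey] = field(default_factory=list)

    def classes(self) -> dict[str, list[SiteKey]]:
        return {name: getattr(self, name) for name in ARTIFACT_CLASSES}

    def validate(self) -> None:
        seen: set[SiteKey] = set()
        for name, keys in self.classes().items():
            overlap = seen & set(keys)
            if overlap:
                raise ValueError(f"artifact classes overlap at {sorted(overlap)}")
            seen |= set(keys)


@dataclass
class SimulationConfig:
    regions: list[RegionConfig]
    n_cases: int
    n_controls: int
    mosaic_switch_rate: float = 0.05
    causal_plan: list[tuple[str, int, float]] = field(default_factory=list)
    baseline_prevalence: float = 0.02
    n_batches: int = 2
    background_missing_rate: float = 0.002
    gq_mean: float = 60.0
    gq_sd: float = 10.0
    reference_af_coverage: float = 1.0
    artifact_plan: ArtifactPlan = field(default_factory=ArtifactPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.mosaic_switch_rate,
            self.baseline_prevalence,
            self.background_missing_rate,
            self.reference_af_coverage,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for _, _, odds in self.causal_plan:
            if odds <= 0:
                raise ValueError("causal odds ratios must be positive")
        self.artifact_plan.validate()


@dataclass
class SimulatedCohort:
    sites: list[VariantSite]
    geno: CohortGenotypes
    reference_af: dict[str, float]
    lcr: IntervalSet
    external_flags: dict[str, bool]
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# founder-pool builders


def random_founder_pool(
    n_sites: int,
    rng: np.random.Generator,
    n_founders: int = 12,
    af_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Random polymorphic founder pool with pool MAF inside ``af_range``.

    Founder frequencies are Dirichlet(1); per-site founder alleles are
    Bernoulli at a target frequency drawn uniformly from ``af_range``,
    re-drawn until the frequency-weighted pool MAF lands inside the range.
    """
    freqs = rng.dirichlet(np.ones(n_founders))
    founders = np.zeros((n_founders, n_sites), dtype=np.int8)
    lo, hi = af_range
    for j in range(n_sites):
        for _ in range(200):
            f = rng.uniform(lo, hi)
            colv = (rng.random(n_founders) < f).astype(np.int8)
            af = float(freqs @ colv)
            if lo <= min(af, 1 - af):
                founders[:, j] = colv
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a polymorphic founder column")
    return founders, freqs


def _region(region_id, chrom, start, founders, freqs, spacing=100) -> RegionConfig:
    return RegionConfig(region_id, chrom, start, founders, freqs, spacing)


def null_cohort_config(
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_sites: int = 2000,
    sites_per_region: int = 20,
    seed: int = 0,
) -> SimulationConfig:
    """No planted effects, no artifacts: the calibration condition."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    regions = []
    n_regions = (n_sites + sites_per_region - 1) // sites_per_region
    for r in range(n_regions):
        m = min(sites_per_region, n_sites - r * sites_per_region)
        founders, freqs = random_founder_pool(m, rng)
        regions.append(
            _region(f"R{r:03d}", f"chr{(r % 20) + 1}", 10_000 + 1_000_000 * r, founders, freqs)
        )
    return SimulationConfig(
        regions=regions,
        n_cases=n_cases,
        n_controls=n_controls,
        mosaic_switch_rate=0.1,
        background_missing_rate=0.0,
        seed=seed,
    )


def qc_artifact_config(seed: int = 0, n_cases: int = 1000, n_controls: int = 1000) -> SimulationConfig:
    """Disjoint artifact classes at saturating magnitudes on a 150-site panel.

    The af_shift class has a single site: the z-score filter standardizes by
    the spread of the same AF-difference vector it screens, which caps the
    attainable |z| of k outliers among n eligible sites near sqrt((n-k)/k).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    regions = []
    for r in range(3):
        founders, freqs = random_founder_pool(50, rng, af_range=(0.1, 0.5))
        regions.append(_region(f"R{r}", f"chr{r + 1}", 50_000 + 500_000 * r, founders, freqs))
    keys = [(f"R{r}", i) for r in range(3) for i in range(50)]
    order = rng.permutation(len(keys))
    pick = [keys[i] for i in order]
    plan = ArtifactPlan(
        hwe_violation=pick[0:5],
        excess_het=pick[5:10],
        low_gq=pick[10:15],
        high_missingness=pick[15:20],
        differential_missingness=pick[20:25],
        af_shift=pick[25:26],
        lcr_overlap=pick[26:31],
        external_fail=pick[31:36],
    )
    return SimulationConfig(
        regions=regions,
        n_cases=n_cases,
        n_controls=n_controls,
        mosaic_switch_rate=0.1,
        background_missing_rate=0.0,
        artifact_plan=plan,
        seed=seed,
    )


def two_signal_region_config(
    seed: int = 0,
    n_cases: int = 2000,
    n_controls: int = 750,
    or_strong: float = 1.6,
    or_weak: float = 1.4,
) -> SimulationConfig:
    """One region with two independent planted causal variants.

    The founder pool has 400 equifrequent founders, large enough that every
    carrier-set overlap can be chosen so founder-level covariances vanish
    exactly: the causal carrier sets (60 founders at AF 0.15, 100 at AF 0.25)
    overlap in exactly 60*100/400 = 15 founders, and each null site's 80
    carriers (AF 0.20) overlap the causal sets in exactly 12 and 20 founders.
    The informative set is therefore expected to contain only the two
    causals, each recovering as its own haplotype lead.
    """
    K, m = 400, 12
    founders = np.zeros((K, m), dtype=np.int8)
    causal_idx = {"strong": 3, "weak": 8}
    s1 = np.arange(0, 60)  # AF 0.15
    s2 = np.r_[np.arange(0, 15), np.arange(60, 145)]  # AF 0.25, overlap 15
    founders[s1, causal_idx["strong"]] = 1
    founders[s2, causal_idx["weak"]] = 1
    both, only1, only2 = np.arange(0, 15), np.arange(15, 60), np.arange(60, 145)
    neither = np.arange(145, 400)
    j_null = 0
    for j in range(m):
        if j in causal_idx.values():
            continue
        # 80 carriers: 5 from s1&s2, 7 from s1 only, 15 from s2 only, 53 rest
        # => overlap 12 with s1 (= 0.2*0.15*400) and 20 with s2 (= 0.2*0.25*400)
        rot = lambda pool, k, n: pool[(j_null * 3 + np.arange(n)) % len(pool)]
        carriers = np.r_[
            rot(both, j_null, 5), rot(only1, j_null, 7),
            rot(only2, j_null, 15), rot(neither, j_null, 53),
        ]
        founders[carriers, j] = 1
        j_null += 1
    freqs = np.full(K, 1.0 / K)
    region = _region("SIG", "chr9", 21_800_000, founders, freqs)
    return SimulationConfig(
        regions=[region],
        n_cases=n_cases,
        n_controls=n_controls,
        mosaic_switch_rate=0.05,
        causal_plan=[
            ("SIG", causal_idx["strong"], or_strong),
            ("SIG", causal_idx["weak"], or_weak),
        ],
        background_missing_rate=0.0,
        seed=seed,
    )


def default_config(
    n_cases: int = 1959,
    n_controls: int = 737,
    seed: int = 0,
) -> SimulationConfig:
    """Study-scale default: a multi-region panel with planted signals and artifacts."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    regions = []
    for r in range(8):
        founders, freqs = random_founder_pool(40, rng)
        regions.append(_region(f"R{r}", f"chr{r + 1}", 100_000 + 2_000_000 * r, founders, freqs))
    plan = ArtifactPlan(
        hwe_violation=[("R5", 4), ("R6", 11)],
        excess_het=[("R5", 20)],
        low_gq=[("R6", 30), ("R7", 7)],
        high_missingness=[("R7", 18)],
        differential_missingness=[("R7", 25)],
        af_shift=[("R5", 33)],
        lcr_overlap=[("R6", 22)],
        external_fail=[("R7", 36)],
    )
    return SimulationConfig(
        regions=regions,
        n_cases=n_cases,
        n_controls=n_controls,
        causal_plan=[("R0", 12, 1.5), ("R0", 30, 1.3), ("R1", 8, 1.4)],
        artifact_plan=plan,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genotype composition


def _compose_dosage(
    regions: list[RegionConfig],
    n_individuals: int,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mosaic-composed dosage matrix (n_individuals, total sites)."""
    n_hap = 2 * n_individuals
    cols = []
    for reg in regions:
        K, m = reg.founders.shape
        # founder proposal at every site; kept only where a switch occurs
        draws = rng.choice(K, size=(n_hap, m), p=reg.founder_freqs)
        switch = rng.random((n_hap, m)) < switch_rate
        switch[:, 0] = True
        last = np.maximum.accumulate(
            np.where(switch, np.arange(m)[None, :], 0), axis=1
        )
        fidx = draws[np.arange(n_hap)[:, None], last]
        alleles = reg.founders[fidx, np.arange(m)[None, :]]
        cols.append((alleles[0::2] + alleles[1::2]).astype(np.int8))
    return np.concatenate(cols, axis=1)


def _site_catalog(config: SimulationConfig) -> tuple[list[tuple[str, str, int]], dict[SiteKey, int]]:
    """Flattened (region_id, chrom, pos) per site plus (region, idx) -> column map."""
    catalog = []
    colmap: dict[SiteKey, int] = {}
    for reg in config.regions:
        for i in range(reg.n_sites):
            colmap[(reg.region_id, i)] = len(catalog)
            catalog.append((reg.region_id, reg.chrom, reg.start + i * reg.spacing))
    return catalog, colmap


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generative model; bit-reproducible for a fixed config."""
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_phen, rng_art, rng_gq, rng_miss, rng_ref = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    catalog, colmap = _site_catalog(config)
    n_sites = len(catalog)
    pool_af = np.concatenate([reg.pool_af for reg in config.regions])

    causal_cols = np.array([colmap[(rid, i)] for rid, i, _ in config.causal_plan], dtype=int)
    log_or = np.array([np.log(o) for _, _, o in config.causal_plan])
    base = np.log(config.baseline_prevalence / (1.0 - config.baseline_prevalence))

    n_want_case, n_want_ctrl = config.n_cases, config.n_controls
    if len(causal_cols) == 0:
        # no genotype-phenotype link: a population sample relabelled by quota
        dosage = _compose_dosage(
            config.regions, n_want_case + n_want_ctrl, config.mosaic_switch_rate, rng_geno
        )
        order = rng_phen.permutation(n_want_case + n_want_ctrl)
        case_rows = np.sort(order[:n_want_case])
        is_case = np.zeros(n_want_case + n_want_ctrl, dtype=bool)
        is_case[case_rows] = True
        dosage = np.concatenate([dosage[is_case], dosage[~is_case]], axis=0)
    else:
        chunks_case, chunks_ctrl = [], []
        got_case = got_ctrl = 0
        drawn = 0
        chunk = max(8192, (n_want_case + n_want_ctrl) // 4)
        mean_p: Optional[float] = None
        while got_case < n_want_case or got_ctrl < n_want_ctrl:
            d = _compose_dosage(config.regions, chunk, config.mosaic_switch_rate, rng_geno)
            eta = base + d[:, causal_cols].astype(float) @ log_or
            p = 1.0 / (1.0 + np.exp(-eta))
            if mean_p is None:
                mean_p = float(p.mean())
                if n_want_case > 1e6 * mean_p or n_want_ctrl > 1e6 * (1.0 - mean_p):
                    raise ValueError(
                        "case/control accumulation infeasible at this prevalence and "
                        "odds-ratio plan; adjust baseline_prevalence or quotas"
                    )
            case = rng_phen.random(chunk) < p
            if got_case < n_want_case:
                take = d[case][: n_want_case - got_case]
                chunks_case.append(take)
                got_case += take.shape[0]
            if got_ctrl < n_want_ctrl:
                take = d[~case][: n_want_ctrl - got_ctrl]
                chunks_ctrl.append(take)
                got_ctrl += take.shape[0]
            drawn += chunk
            if drawn > 5e7:  # pragma: no cover - guarded by the mean_p check
                raise ValueError("rejection sampling exceeded its draw budget")
        dosage = np.concatenate(chunks_case + chunks_ctrl, axis=0)

    n_total = n_want_case + n_want_ctrl
    phenotype = np.array([CASE] * n_want_case + [CONTROL] * n_want_ctrl)
    # balanced deterministic batch assignment within each phenotype
    batch = np.empty(n_total, dtype=object)
    batch[:n_want_case] = [f"b{(i % config.n_batches) + 1}" for i in range(n_want_case)]
    batch[n_want_case:] = [f"b{(i % config.n_batches) + 1}" for i in range(n_want_ctrl)]
    batch = batch.astype(str)
    sample_ids = [f"case{i + 1:05d}" for i in range(n_want_case)] + [
        f"ctrl{i + 1:05d}" for i in range(n_want_ctrl)
    ]
    case_rows = np.arange(n_want_case)
    ctrl_rows = np.arange(n_want_case, n_total)

    plan = config.artifact_plan

    def _resample_genotypes(rows: np.ndarray, col: int, probs: np.ndarray) -> None:
        u = rng_art.random(rows.size)
        g = np.select(
            [u < probs[0], u < probs[0] + probs[1]], [0, 1], default=2
        ).astype(np.int8)
        dosage[rows, col] = g

    for key in plan.hwe_violation:
        col = colmap[key]
        p = pool_af[col]
        q = 1.0 - p
        fcoef = plan.hwe_inbreeding
        probs = np.array([q * q + fcoef * p * q, 2 * p * q * (1 - fcoef), p * p + fcoef * p * q])
        _resample_genotypes(ctrl_rows, col, probs / probs.sum())
    for key in plan.excess_het:
        col = colmap[key]
        p = pool_af[col]
        q = 1.0 - p
        het = (1 - plan.excess_het_coef) * 2 * p * q + plan.excess_het_coef
        rest = 1.0 - het
        denom = q * q + p * p
        probs = np.array([rest * q * q / denom, het, rest * p * p / denom])
        _resample_genotypes(case_rows, col, probs / probs.sum())

    # missingness: background everywhere, then planted class rates
    miss = rng_miss.random(dosage.shape) < config.background_missing_rate
    for key in plan.high_missingness:
        col = colmap[key]
        miss[:, col] = rng_miss.random(n_total) < plan.high_missing_rate
    for key in plan.differential_missingness:
        col = colmap[key]
        m = np.zeros(n_total, dtype=bool)
        m[case_rows] = rng_miss.random(case_rows.size) < plan.diff_missing_case_rate
        m[ctrl_rows] = rng_miss.random(ctrl_rows.size) < plan.diff_missing_control_rate
        miss[:, col] = m
    dosage[miss] = MISSING

    # genotype qualities (integers, truncated at 0); NaN where the call is missing
    gq = np.rint(np.clip(rng_gq.normal(config.gq_mean, config.gq_sd, dosage.shape), 0, None))
    for key in plan.low_gq:
        col = colmap[key]
        gq[:, col] = np.rint(
            np.clip(rng_gq.normal(plan.low_gq_mean, plan.low_gq_sd, n_total), 0, None)
        )
    gq = gq.astype(float)
    gq[dosage == MISSING] = np.nan

    # site metadata, reference AFs, LCR intervals, external flags
    shift_cols = {colmap[k]: plan.af_shift_delta for k in plan.af_shift}
    lcr_keys = {colmap[k] for k in plan.lcr_overlap}
    fail_keys = {colmap[k] for k in plan.external_fail}
    has_ref = rng_ref.random(n_sites) < config.reference_af_coverage
    sites: list[VariantSite] = []
    reference_af: dict[str, float] = {}
    lcr_intervals: list[tuple[str, int, int]] = []
    external_flags: dict[str, bool] = {}
    for col, (rid, chrom, pos) in enumerate(catalog):
        sid = f"{chrom}:{pos}:A:G"
        ref_af = None
        if has_ref[col]:
            ref_af = float(np.clip(pool_af[col] + shift_cols.get(col, 0.0), 0.0, 1.0))
            reference_af[sid] = ref_af
        ext_pass = col not in fail_keys
        if not ext_pass:
            external_flags[sid] = False
        sites.append(
            VariantSite(
                site_id=sid,
                chrom=chrom,
                pos=pos,
                ref_allele="A",
                alt_allele="G",
                region_id=rid,
                external_pass=ext_pass,
                reference_af=ref_af,
            )
        )
        if col in lcr_keys:
            lcr_intervals.append((chrom, pos - 1, pos))

    geno = CohortGenotypes(
        sample_ids=sample_ids,
        site_ids=[s.site_id for s in sites],
        dosage=dosage,
        gq=gq,
        phenotype=phenotype,
        batch=batch,
        excluded=np.zeros(n_total, dtype=bool),
    )
    truth = {
        "causal_site_ids": [sites[c].site_id for c in causal_cols],
        "causal_plan": [
            {"site_id": sites[colmap[(rid, i)]].site_id, "odds_ratio": o}
            for rid, i, o in config.causal_plan
        ],
        "artifacts": {
            name: [sites[colmap[k]].site_id for k in keys]
            for name, keys in plan.classes().items()
        },
        "pool_af": {s.site_id: float(a) for s, a in zip(sites, pool_af)},
        "n_cases": n_want_case,
        "n_controls": n_want_ctrl,
        "seed": config.seed,
    }
    return SimulatedCohort(
        sites=sites,
        geno=geno,
        reference_af=reference_af,
        lcr=IntervalSet(lcr_intervals),
        external_flags=external_flags,
        truth=truth,
        config=config,
    )


def emit_fixture(sim: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write the cohort as standards-compliant text files.

    Produces cohort.vcf (GT:GQ), samples.tsv, reference_af.tsv, lcr.bed,
    external_flags.tsv and truth.json; all are read back losslessly by
    :mod:`seqfinemap.io`.
    """
    from . import io as io_mod  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "samples": out / "samples.tsv",
        "reference_af": out / "reference_af.tsv",
        "lcr": out / "lcr.bed",
        "external_flags": out / "external_flags.tsv",
        "truth": out / "truth.json",
    }
    io_mod.write_vcf(paths["vcf"], sim.sites, sim.geno)
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tphenotype\tbatch\texcluded\n")
        for i, sid in enumerate(sim.geno.sample_ids):
            fh.write(
                f"{sid}\t{sim.geno.phenotype[i]}\t{sim.geno.batch[i]}\t"
                f"{int(sim.geno.excluded[i])}\n"
            )
    with open(paths["reference_af"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for s in sim.sites:
            if s.site_id in sim.reference_af:
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                    f"{sim.reference_af[s.site_id]:.6f}\n"
                )
    with open(paths["lcr"], "w") as fh:
        for chrom, start, end in sim.lcr.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    with open(paths["external_flags"], "w") as fh:
        fh.write("site_id\tpass\n")
        for sid in sorted(sim.external_flags):
            fh.write(f"{sid}\t{int(sim.external_flags[sid])}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
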