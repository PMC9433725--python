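"""Readers and writers for every external format the pipeline touches.

VCF access goes through cyvcf2; everything else is plain TSV/BED text.
Coordinate conventions: VCF positions are 1-based, BED intervals 0-based
half-open. Genotype separators "/" and "|" are treated identically; any
genotype containing an uncalled allele (including half-calls such as ``./1``)
is missing.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    CASE,
    CONTROL,
    MISSING,
    AssociationResult,
    CohortGenotypes,
    HaplotypeAssignment,
    IntervalSet,
    QCReport,
    VariantSite,
)

REQUIRED_SAMPLE_COLUMNS = ["sample_id", "phenotype", "batch", "excluded"]


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    df["excluded"] = df["excluded"].astype(bool)
    bad = set(df.loc[~df["excluded"], "phenotype"]) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"phenotype values outside {{case, control}}: {sorted(bad)}")
    return df


def read_regions(path) -> list[tuple[str, str, int, int]]:
    """Target-region table: region_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "chrom": str})
    for c in ["region_id", "chrom", "start", "end"]:
        if c not in df.columns:
            raise ValueError(f"region table missing column {c}")
    return [
        (r.region_id, r.chrom, int(r.start), int(r.end)) for r in df.itertuples()
    ]


def _assign_region(chrom: str, pos: int, regions) -> str:
    if regions:
        for rid, rchrom, start, end in regions:
            if rchrom == chrom and start <= pos <= end:
                return rid
    return chrom  # fallback: one region per chromosome


def read_vcf(
    path,
    sample_table: pd.DataFrame,
    regions: list[tuple[str, str, int, int]] | None = None,
) -> tuple[list[VariantSite], CohortGenotypes]:
    """Read a multi-sample VCF into the internal model.

    Multi-allelic records are rejected with an error instructing upstream
    splitting (silently splitting would change allele counts). Sample order
    follows the VCF header; every VCF sample must appear in the sample table.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta = sample_table.set_index("sample_id")
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValueError(f"samples present in VCF but not in sample table: {unknown}")

    sites: list[VariantSite] = []
    dosage_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    any_gq = False
    seen: set[str] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} "
                f"({v.REF}>{','.join(v.ALT)}): split into biallelic records "
                "upstream (e.g. bcftools norm -m-) before ingest"
            )
        sid = f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        if sid in seen:
            raise ValueError(f"duplicate site_id {sid}")
        seen.add(sid)
        sites.append(
            VariantSite(
                site_id=sid,
                chrom=v.CHROM,
                pos=int(v.POS),
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                region_id=_assign_region(v.CHROM, int(v.POS), regions),
            )
        )
        dos = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # trailing element is phasing
            if len(alleles) < 2 or any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = sum(1 for a in alleles if a == 1)
        dosage_rows.append(dos)
        try:
            gq = v.format("GQ")
        except KeyError:  # GQ not declared in the header at all
            gq = None
        if gq is None:
            gq_rows.append(np.full(len(samples), np.nan))
        else:
            any_gq = True
            g = gq.astype(float).reshape(len(samples))
            g[g < 0] = np.nan  # cyvcf2 encodes '.' as a large negative sentinel
            gq_rows.append(g)

    n, m = len(samples), len(sites)
    dosage = (
        np.stack(dosage_rows, axis=1) if sites else np.zeros((n, 0), dtype=np.int8)
    )
    gq_mat = None
    if any_gq:
        gq_mat = np.stack(gq_rows, axis=1) if sites else np.zeros((n, 0))
        gq_mat[dosage == MISSING] = np.nan
    geno = CohortGenotypes(
        sample_ids=samples,
        site_ids=[s.site_id for s in sites],
        dosage=dosage,
        gq=gq_mat,
        phenotype=meta.loc[samples, "phenotype"].to_numpy(),
        batch=meta.loc[samples, "batch"].to_numpy(),
        excluded=meta.loc[samples, "excluded"].to_numpy(bool),
    )
    return sites, geno


def write_vcf(path, sites: list[VariantSite], geno: CohortGenotypes) -> None:
    """Emit a minimal VCF v4.2 with GT (and GQ when available)."""
    has_gq = geno.gq is not None
    fmt = "GT:GQ" if has_gq else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seqfinemap\n")
        for chrom in dict.fromkeys(s.chrom for s in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gq:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for s in sites:
            j = geno.site_index(s.site_id)
            cells = []
            for i in range(geno.n_samples):
                d = int(geno.dosage[i, j])
                if has_gq:
                    g = geno.gq[i, j]
                    gq_txt = "." if not np.isfinite(g) else str(int(round(g)))
                    cells.append(f"{gt_str[d]}:{gq_txt}")
                else:
                    cells.append(gt_str[d])
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_bed(path) -> IntervalSet:
    """BED3+ reader; intervals are sorted and merged (abutting intervals join)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}: line {ln}: start >= end ({chrom}\t{start}\t{end})"
                )
            intervals.append((chrom, start, end))
    return IntervalSet(intervals)


def read_reference_af(path) -> dict[str, float]:
    """Reference-population AF table (chrom, pos, ref, alt, af) -> site_id map."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for c in ["chrom", "pos", "ref", "alt", "af"]:
        if c not in df.columns:
            raise ValueError(f"reference AF table missing column {c}")
    if ((df["af"] < 0) | (df["af"] > 1)).any():
        raise ValueError("reference AF outside [0, 1]")
    out: dict[str, float] = {}
    for r in df.itertuples():
        sid = f"{r.chrom}:{int(r.pos)}:{r.ref}:{r.alt}"
        if sid in out:
            raise ValueError(f"duplicated site {sid} in reference AF table")
        out[sid] = float(r.af)
    return out


def read_external_flags(path) -> dict[str, bool]:
    """External pass/fail table (site_id, pass); absent sites count as pass."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    for c in ["site_id", "pass"]:
        if c not in df.columns:
            raise ValueError(f"external flag table missing column {c}")
    truthy = {"1", "true", "yes", "pass"}
    out = {}
    for sid, val in zip(df["site_id"], df["pass"]):
        out[sid] = str(val).strip().lower() in truthy
    return out


def attach_site_annotations(
    sites: list[VariantSite],
    reference_af: dict[str, float] | None = None,
    external_flags: dict[str, bool] | None = None,
) -> list[VariantSite]:
    """Return sites with reference AF and external pass flags merged in."""
    out = []
    for s in sites:
        changes = {}
        if reference_af is not None and s.site_id in reference_af:
            changes["reference_af"] = reference_af[s.site_id]
        if external_flags is not None and s.site_id in external_flags:
            changes["external_pass"] = external_flags[s.site_id]
        out.append(dataclasses.replace(s, **changes) if changes else s)
    return out


# ---------------------------------------------------------------------------
# result serialization


def _fmt_p(p: float) -> str:
    return "NA" if not np.isfinite(p) else f"{p:.5e}"


def _fmt_or(o: float) -> str:
    if math.isnan(o):
        return "NA"
    if math.isinf(o):
        return "inf"
    return f"{o:.6g}"


ASSOCIATION_COLUMNS = [
    "region_id",
    "site_id",
    "a",
    "b",
    "c",
    "d",
    "af_case",
    "af_control",
    "odds_ratio",
    "p_value",
    "informative",
]
HAPLOTYPE_COLUMNS = [
    "region_id",
    "haplotype_index",
    "lead_site_id",
    "member_site_id",
    "conditional_p",
    "r2_to_lead",
]
QC_COLUMNS = ["site_id", "flags", "step_removed"]


def write_results(
    association: list[AssociationResult],
    haplotypes: list[HaplotypeAssignment],
    qc: QCReport,
    out_dir,
) -> dict[str, Path]:
    """Write association.tsv, haplotypes.tsv and qc_report.tsv.

    Row order is deterministic (region, then ascending P; haplotypes in
    discovery order; QC rows by site_id), and floats are serialized with
    fixed formats so identical runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "association": out / "association.tsv",
        "haplotypes": out / "haplotypes.tsv",
        "qc_report": out / "qc_report.tsv",
    }
    rows = sorted(
        association,
        key=lambda r: (r.region_id, r.p_value if np.isfinite(r.p_value) else 2.0, r.site_id),
    )
    with open(paths["association"], "w") as fh:
        fh.write("\t".join(ASSOCIATION_COLUMNS) + "\n")
        for r in rows:
            a, b = int(r.counts[0, 0]), int(r.counts[0, 1])
            c, d = int(r.counts[1, 0]), int(r.counts[1, 1])
            af1 = "NA" if not np.isfinite(r.af_case) else f"{r.af_case:.6f}"
            af0 = "NA" if not np.isfinite(r.af_control) else f"{r.af_control:.6f}"
            fh.write(
                f"{r.region_id}\t{r.site_id}\t{a}\t{b}\t{c}\t{d}\t{af1}\t{af0}\t"
                f"{_fmt_or(r.odds_ratio)}\t{_fmt_p(r.p_value)}\t{int(r.informative)}\n"
            )
    with open(paths["haplotypes"], "w") as fh:
        fh.write("\t".join(HAPLOTYPE_COLUMNS) + "\n")
        for assignment in sorted(haplotypes, key=lambda h: h.region_id):
            for idx, hap in enumerate(assignment.haplotypes, start=1):
                for member in hap.member_site_ids:
                    r2 = hap.r2_to_lead[member]
                    r2_txt = "NA" if not np.isfinite(r2) else f"{r2:.6f}"
                    fh.write(
                        f"{assignment.region_id}\t{idx}\t{hap.lead_site_id}\t{member}\t"
                        f"{_fmt_p(hap.conditional_p[member])}\t{r2_txt}\n"
                    )
    with open(paths["qc_report"], "w") as fh:
        fh.write("\t".join(QC_COLUMNS) + "\n")
        for sid in sorted(qc.per_site_flags):
            flags = ",".join(sorted(qc.per_site_flags[sid]))
            fh.write(f"{sid}\t{flags}\t{qc.step_removed[sid]}\n")
    return paths
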