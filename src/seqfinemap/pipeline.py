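"""End-to-end orchestration: ingest -> QC -> association -> decomposition -> reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as io_mod
from .association import DEFAULT_INFORMATIVE_P
from .datatypes import QCReport
from .haplotypes import DEFAULT_COND_P
from .model import FineMapModel
from .qc import QCConfig, run_qc

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    vcf: str
    samples: str
    out_dir: str
    regions: str | None = None
    lcr: str | None = None
    reference_af: str | None = None
    external_flags: str | None = None
    hwe_p: float = 1e-3
    mean_gq_min: float = 30.0
    max_missing: float = 0.05
    diff_missing_p: float = 0.05
    excess_het_p: float = 3.4e-6
    af_z: float = 9.0
    informative_p: float = DEFAULT_INFORMATIVE_P
    cond_p: float = DEFAULT_COND_P
    disabled_filters: list[str] = field(default_factory=list)
    skip_qc: bool = False
    seed: int = 0

    def qc_config(self) -> QCConfig:
        return QCConfig(
            hwe_p=self.hwe_p,
            mean_gq_min=self.mean_gq_min,
            max_missing=self.max_missing,
            diff_missing_p=self.diff_missing_p,
            excess_het_p=self.excess_het_p,
            af_z=self.af_z,
            disabled=set(self.disabled_filters),
        )

    @classmethod
    def from_dict(cls, d: dict, out_dir: str | None = None) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {unknown}")
        if out_dir is not None:
            d = {**d, "out_dir": out_dir}
        missing = [k for k in ("vcf", "samples", "out_dir") if k not in d]
        if missing:
            raise ValueError(f"pipeline config missing required keys: {missing}")
        return cls(**d)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run manifest.

    All computation happens in memory first; result files and the manifest
    are written only after every stage succeeded, so a failed run leaves no
    partial outputs. Any stage error is re-raised as :class:`StageError`.
    """
    t0 = time.time()
    manifest: dict = {"stages": {}, "inputs": {}, "config": dataclasses.asdict(config)}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                self.t = time.time()

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.time() - self.t, 3
                )

        return _Ctx()

    with stage("ingest"):
        table = io_mod.read_sample_table(config.samples)
        regions = io_mod.read_regions(config.regions) if config.regions else None
        sites, geno = io_mod.read_vcf(config.vcf, table, regions)
        lcr = io_mod.read_bed(config.lcr) if config.lcr else None
        ref_af = io_mod.read_reference_af(config.reference_af) if config.reference_af else None
        flags = io_mod.read_external_flags(config.external_flags) if config.external_flags else None
        sites = io_mod.attach_site_annotations(sites, ref_af, flags)
        for key in ("vcf", "samples", "regions", "lcr", "reference_af", "external_flags"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = {"path": str(path), "sha256": _checksum(path)}
        manifest["stages"]["ingest"] = {
            "n_sites": len(sites),
            "n_samples": geno.n_samples,
            "n_excluded_samples": int(geno.excluded.sum()),
        }

    with stage("qc"):
        if config.skip_qc:
            retained, qc_report = sites, QCReport(n_input=len(sites))
        else:
            retained, qc_report = run_qc(geno, sites, lcr, config.qc_config())
        manifest["stages"]["qc"] = {
            "n_input": qc_report.n_input,
            "n_retained": qc_report.n_retained,
            "per_filter_counts": qc_report.per_filter_counts,
            "skipped": config.skip_qc,
        }
        geno_kept = geno.subset_sites([s.site_id for s in retained])

    with stage("association"):
        model = FineMapModel(
            geno_kept, retained, informative_p=config.informative_p, cond_p=config.cond_p
        )
        results = model.fit()
        manifest["stages"]["association"] = {
            "n_tested": len(results.association),
            "n_testable": sum(r.testable for r in results.association),
            "n_informative": len(results.informative),
        }

    with stage("decomposition"):
        manifest["stages"]["decomposition"] = {
            "n_regions_with_signal": len(results.haplotypes),
            "n_haplotypes": {
                h.region_id: len(h.haplotypes) for h in results.haplotypes
            },
        }

    with stage("report"):
        out = Path(config.out_dir)
        paths = io_mod.write_results(results.association, results.haplotypes, qc_report, out)
        manifest["elapsed_seconds"] = round(time.time() - t0, 3)
        manifest["outputs"] = {k: str(v) for k, v in paths.items()}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return manifest
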