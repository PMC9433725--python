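import numpy as np
import pytest

from seqfinemap.datatypes import MISSING, CohortGenotypes


def make_cohort(
    dosage,
    phenotype,
    batch=None,
    gq=None,
    excluded=None,
    site_ids=None,
):
    """Hand-build a small CohortGenotypes from python lists."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    phenotype = np.asarray(phenotype)
    batch = np.asarray(batch if batch is not None else ["b1"] * n)
    excluded = np.asarray(excluded if excluded is not None else [False] * n, dtype=bool)
    site_ids = site_ids or [f"chr1:{100 + i}:A:G" for i in range(m)]
    if gq is not None:
        gq = np.asarray(gq, dtype=float)
        gq[dosage == MISSING] = np.nan
    return CohortGenotypes(
        sample_ids=[f"s{i}" for i in range(n)],
        site_ids=site_ids,
        dosage=dosage,
        gq=gq,
        phenotype=phenotype,
        batch=batch,
        excluded=excluded,
    )


@pytest.fixture
def tiny_fixture_dir(tmp_path):
    """Small simulated cohort emitted to disk (seed 7, 50 sites, 40 samples)."""
    from seqfinemap.simulate import emit_fixture, null_cohort_config, simulate_cohort

    cfg = null_cohort_config(n_cases=25, n_controls=15, n_sites=50, sites_per_region=10, seed=7)
    sim = simulate_cohort(cfg)
    paths = emit_fixture(sim, tmp_path / "fixture")
    return sim, paths
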