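"""LD r^2 and the sequential conditional haplotype decomposition."""

import numpy as np
import pytest

from conftest import make_cohort
from seqfinemap.association import run_association
from seqfinemap.datatypes import MISSING, VariantSite
from seqfinemap.haplotypes import decompose_all, ld_r2, stepwise_decompose
from seqfinemap.logistic import logistic_fit
from seqfinemap.simulate import simulate_cohort, two_signal_region_config


class TestLDr2:
    def test_identity_and_flip(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, 100).astype(float)
        assert ld_r2(d, d) == pytest.approx(1.0)
        assert ld_r2(d, 2 - d) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.binomial(2, 0.3, 80), rng.binomial(2, 0.5, 80)
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a), abs=1e-15)

    def test_matches_two_pass_correlation(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.3, 200).astype(float)
        b = rng.binomial(2, 0.4, 200).astype(float)
        am, bm = a.mean(), b.mean()
        cov = np.mean((a - am) * (b - bm))
        r = cov / np.sqrt(np.mean((a - am) ** 2) * np.mean((b - bm) ** 2))
        assert ld_r2(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(ld_r2(np.ones(10), np.arange(10.0)))

    def test_pairwise_complete(self):
        a = np.array([0, 1, 2, MISSING, 2, 0], dtype=float)
        b = np.array([0, 1, 2, 2, MISSING, 0], dtype=float)
        assert ld_r2(a, b) == pytest.approx(1.0)


def _fit_decomposition(sim, cond=0.1):
    res = run_association(sim.geno, sim.sites)
    return res, decompose_all(res, sim.geno, cond, cond)


class TestStepwise:
    def test_single_informative_variant_is_its_own_lead(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.3, 600)
        y_p = 1 / (1 + np.exp(-(-0.5 + 1.2 * x)))
        phen = np.where(rng.random(600) < y_p, "case", "control")
        geno = make_cohort(x[:, None], phen)
        sites = [VariantSite(geno.site_ids[0], "chr1", 100, "A", "G", "R0")]
        assoc = run_association(geno, sites)
        assert assoc[0].informative
        out = stepwise_decompose("R0", assoc, geno)
        assert len(out.haplotypes) == 1
        assert out.haplotypes[0].lead_site_id == geno.site_ids[0]
        assert out.unassigned == []

    def test_duplicate_variant_absorbed_with_conditional_p_one(self):
        rng = np.random.default_rng(9)
        x = rng.binomial(2, 0.3, 800)
        y_p = 1 / (1 + np.exp(-(-0.5 + 1.0 * x)))
        phen = np.where(rng.random(800) < y_p, "case", "control")
        geno = make_cohort(np.column_stack([x, x]), phen)
        sites = [
            VariantSite(sid, "chr1", 100 + i, "A", "G", "R0")
            for i, sid in enumerate(geno.site_ids)
        ]
        assoc = run_association(geno, sites)
        assert all(r.informative for r in assoc)
        out = stepwise_decompose("R0", assoc, geno)
        assert len(out.haplotypes) == 1
        hap = out.haplotypes[0]
        assert sorted(hap.member_site_ids) == sorted(geno.site_ids)
        dup = next(s for s in hap.member_site_ids if s != hap.lead_site_id)
        assert hap.conditional_p[dup] == 1.0  # exactly collinear with the lead
        assert hap.r2_to_lead[dup] == pytest.approx(1.0)

    def test_empty_region_empty_assignment(self):
        geno = make_cohort([[0], [1]], ["case", "control"])
        out = stepwise_decompose("R0", [], geno)
        assert out.haplotypes == [] and out.unassigned == []

    def test_partition_property(self):
        sim = simulate_cohort(two_signal_region_config(seed=11, n_cases=500, n_controls=300))
        assoc, haps = _fit_decomposition(sim)
        informative = {r.site_id for r in assoc if r.informative}
        if not informative:
            assert haps == []
            return
        members = [m for h in haps[0].haplotypes for m in h.member_site_ids]
        assert sorted(members) == sorted(informative)
        assert len(members) == len(set(members))

    def test_zero_threshold_yields_single_haplotype(self):
        sim = simulate_cohort(two_signal_region_config(seed=12))
        assoc, haps = _fit_decomposition(sim, cond=0.0)
        assert all(len(h.haplotypes) == 1 for h in haps)

    def test_leads_mutually_conditionally_significant(self):
        sim = simulate_cohort(two_signal_region_config(seed=13))
        assoc, haps = _fit_decomposition(sim)
        leads = haps[0].lead_site_ids
        assert len(leads) >= 2
        ok = ~np.asarray(sim.geno.excluded, bool)
        y = (np.asarray(sim.geno.phenotype)[ok] == "case").astype(float)
        X = np.column_stack(
            [sim.geno.dosage[ok, sim.geno.site_index(s)] for s in leads]
        ).astype(float)
        keep = np.all(X != MISSING, axis=1)
        fit = logistic_fit(y[keep], X[keep])
        assert fit.converged
        assert np.all(fit.wald_p[1:] < 0.1)
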