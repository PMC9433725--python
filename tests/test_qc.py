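"""Unit tests of the individual QC filters and the cascade."""

import numpy as np
import pytest

from conftest import make_cohort
from oracles import fisher_two_sided_exact, interval_contains_linear, two_pass_mean_sd
from seqfinemap.datatypes import MISSING, IntervalSet, VariantSite
from seqfinemap.qc import (
    GroupSpec,
    QCConfig,
    batch_private_sites,
    control_allele_freq,
    filter_af_zscore,
    filter_diff_missingness,
    filter_excess_het,
    filter_hwe,
    filter_lcr,
    filter_mean_gq,
    filter_missingness,
    intersect_batches,
    run_qc,
)
from seqfinemap.simulate import qc_artifact_config, simulate_cohort


def _site(sid, chrom="chr1", pos=100, **kw):
    return VariantSite(sid, chrom, pos, "A", "G", "R0", **kw)


class TestHWEFilter:
    def test_extreme_het_deficit_in_controls_flagged(self):
        dosage = [[0]] * 30 + [[2]] * 30
        geno = make_cohort(dosage, ["control"] * 60)
        flagged = filter_hwe(geno, GroupSpec.from_cohort(geno))
        assert flagged == set(geno.site_ids)

    def test_monomorphic_never_flagged(self):
        geno = make_cohort([[0]] * 40, ["control"] * 40)
        assert filter_hwe(geno, GroupSpec.from_cohort(geno)) == set()

    def test_cases_never_enter(self):
        # same extreme deficit but in cases only; controls are in equilibrium
        dosage = [[0]] * 15 + [[2]] * 15 + [[0], [1], [1], [2]]
        phen = ["case"] * 30 + ["control"] * 4
        geno = make_cohort(dosage, phen)
        assert filter_hwe(geno, GroupSpec.from_cohort(geno)) == set()


class TestMeanGQ:
    def test_boundary_is_strict(self):
        geno = make_cohort([[1]] * 3, ["case", "case", "control"], gq=[[30], [30], [30]])
        groups = GroupSpec.from_cohort(geno)
        assert filter_mean_gq(geno, groups, 30.0) == set()
        geno2 = make_cohort([[1]] * 3, ["case", "case", "control"], gq=[[10], [20], [30]])
        assert filter_mean_gq(geno2, GroupSpec.from_cohort(geno2), 30.0) == set(geno2.site_ids)

    def test_absent_gq_skips_filter(self, caplog):
        geno = make_cohort([[1]] * 4, ["case"] * 2 + ["control"] * 2, gq=None)
        with caplog.at_level("WARNING"):
            assert filter_mean_gq(geno, GroupSpec.from_cohort(geno)) == set()
        assert "skipped" in caplog.text

    def test_matches_two_pass_mean(self):
        rng = np.random.default_rng(5)
        gq = rng.uniform(10, 60, size=(40, 8))
        geno = make_cohort(
            rng.integers(0, 3, size=(40, 8)), ["case"] * 20 + ["control"] * 20, gq=gq.copy()
        )
        groups = GroupSpec.from_cohort(geno)
        flagged = filter_mean_gq(geno, groups, 30.0)
        for j, sid in enumerate(geno.site_ids):
            means = []
            for idx in groups.groups.values():
                vals = [gq[i, j] for i in idx if geno.dosage[i, j] != MISSING]
                if vals:
                    means.append(two_pass_mean_sd(vals)[0])
            assert (sid in flagged) == any(m < 30.0 for m in means)


class TestMissingness:
    def test_boundary_is_strict_greater(self):
        col = [[MISSING]] + [[1]] * 19  # 1/20 = 0.05 exactly
        geno = make_cohort(col, ["control"] * 20)
        assert filter_missingness(geno, GroupSpec.from_cohort(geno), 0.05) == set()
        col2 = [[MISSING]] * 2 + [[1]] * 18  # 0.10
        geno2 = make_cohort(col2, ["control"] * 20)
        assert filter_missingness(geno2, GroupSpec.from_cohort(geno2), 0.05) == set(
            geno2.site_ids
        )


class TestBatchConsolidation:
    def test_union_of_group_flags(self):
        rng = np.random.default_rng(9)
        sids = [f"s{i}" for i in range(50)]
        flags_by_group = {
            g: set(rng.choice(sids, size=rng.integers(0, 20), replace=False))
            for g in ["b1:case", "b1:control", "b2:case", "b2:control"]
        }
        out = intersect_batches(flags_by_group)
        assert out == set().union(*flags_by_group.values())

    def test_batch_private_site_detected(self):
        dosage = np.array([[1, 1], [0, 1], [MISSING, 0], [MISSING, 1]], dtype=np.int8)
        geno = make_cohort(
            dosage, ["case", "control"] * 2, batch=["b1", "b1", "b2", "b2"]
        )
        assert batch_private_sites(geno, GroupSpec.from_cohort(geno)) == {geno.site_ids[0]}


class TestLCR:
    def test_half_open_boundaries(self):
        lcr = IntervalSet([("chr1", 10, 20)])
        inside = _site("a", pos=11)  # 0-based 10 in [10,20)
        outside = _site("b", pos=21)  # 0-based 20 not in [10,20)
        assert filter_lcr([inside, outside], lcr) == {"a"}

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(11)
        raw = [
            (f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 50)))
            for s in rng.integers(0, 2000, size=200)
        ]
        iv = IntervalSet(raw)
        sites = [
            _site(f"s{i}", chrom=f"chr{rng.integers(1, 4)}", pos=int(rng.integers(1, 2100)))
            for i in range(500)
        ]
        flagged = filter_lcr(sites, iv)
        for s in sites:
            assert (s.site_id in flagged) == interval_contains_linear(raw, s.chrom, s.pos - 1)


class TestDiffMissingness:
    def test_symmetric_table_not_flagged(self):
        dosage = [[MISSING]] * 2 + [[1]] * 8 + [[MISSING]] * 2 + [[1]] * 8
        geno = make_cohort(dosage, ["case"] * 10 + ["control"] * 10)
        assert filter_diff_missingness(geno) == set()

    def test_enumeration_oracle_decision(self):
        # cases: 3 missing / 3 genotyped; controls: 0 / 3
        dosage = [[MISSING]] * 3 + [[1]] * 3 + [[1]] * 3
        geno = make_cohort(dosage, ["case"] * 6 + ["control"] * 3)
        p = fisher_two_sided_exact(3, 3, 0, 3)
        assert (filter_diff_missingness(geno, 0.05) == set(geno.site_ids)) == (p < 0.05)

    def test_no_missingness_no_flags(self):
        geno = make_cohort([[1]] * 12, ["case"] * 6 + ["control"] * 6)
        assert filter_diff_missingness(geno) == set()


class TestExcessHetFilter:
    def test_universal_heterozygosity_flagged(self):
        geno = make_cohort([[1]] * 400, ["case"] * 300 + ["control"] * 100)
        assert filter_excess_het(geno) == set(geno.site_ids)

    def test_het_deficit_not_flagged(self):
        geno = make_cohort([[0]] * 20 + [[2]] * 20, ["case"] * 20 + ["control"] * 20)
        assert filter_excess_het(geno) == set()


class TestAFZscore:
    def _sites_with_ref(self, xs):
        # reference AF fixed at 0.05; control AF = x + 0.05, so X_i = x_i
        sites, af = [], {}
        for i, x in enumerate(xs):
            s = _site(f"s{i}", pos=100 + i, reference_af=0.05)
            sites.append(s)
            af[s.site_id] = float(x + 0.05)
        return sites, af

    def test_center_retained_and_oracle_z(self):
        xs = [0.0, 0.0, 0.0, 0.0, 0.9]
        sites, af = self._sites_with_ref(xs)
        mu, sd = two_pass_mean_sd(xs)
        z_outlier = (0.9 - mu) / sd
        flagged = filter_af_zscore(sites, af, threshold=9.0)
        assert (sites[-1].site_id in flagged) == (abs(z_outlier) >= 9.0)
        assert sites[0].site_id not in flagged  # |z| of the bulk << 9

    def test_degenerate_sd_skips(self, caplog):
        sites, af = self._sites_with_ref([0.1] * 4)
        with caplog.at_level("WARNING"):
            assert filter_af_zscore(sites, af) == set()

    def test_sites_without_reference_exempt(self):
        sites, af = self._sites_with_ref([0.0] * 120 + [0.9])
        naked = _site("naked", pos=999)
        af["naked"] = 0.5
        flagged = filter_af_zscore(sites + [naked], af, threshold=9.0)
        assert "naked" not in flagged
        assert sites[-1].site_id in flagged  # 1 outlier in 121: |z| ~ sqrt(120)


class TestCascade:
    def test_no_artifacts_all_retained(self):
        cfg = qc_artifact_config(seed=3, n_cases=120, n_controls=80)
        cfg.artifact_plan = type(cfg.artifact_plan)()  # empty plan
        sim = simulate_cohort(cfg)
        retained, report = run_qc(sim.geno, sim.sites, lcr=sim.lcr)
        assert report.n_retained == report.n_input == len(sim.sites)
        assert len(retained) + report.n_removed == report.n_input

    def test_disabling_filters_is_monotone(self):
        sim = simulate_cohort(qc_artifact_config(seed=4, n_cases=150, n_controls=100))
        disabled: set[str] = set()
        previous = -1
        order = [
            "af_zscore",
            "external_fail",
            "excess_het",
            "diff_missingness",
            "lcr",
            "missingness",
            "mean_gq",
            "hwe",
        ]
        for label in [None] + order:
            if label:
                disabled.add(label)
            retained, report = run_qc(
                sim.geno, sim.sites, lcr=sim.lcr, config=QCConfig(disabled=set(disabled))
            )
            assert len(retained) >= previous
            assert report.n_input == report.n_retained + report.n_removed
            previous = len(retained)

    def test_each_removed_site_has_one_label(self):
        sim = simulate_cohort(qc_artifact_config(seed=5, n_cases=200, n_controls=150))
        _, report = run_qc(sim.geno, sim.sites, lcr=sim.lcr)
        assert all(len(v) == 1 for v in report.per_site_flags.values())
        assert sum(report.per_filter_counts.values()) == report.n_removed

    def test_control_af_ignores_excluded_and_missing(self):
        dosage = [[2], [1], [MISSING], [0], [2]]
        phen = ["control"] * 4 + ["case"]
        geno = make_cohort(dosage, phen, excluded=[False, False, False, True, False])
        af = control_allele_freq(geno)
        # controls used: dosages 2 and 1 over 2 samples -> 3/4
        assert af[geno.site_ids[0]] == pytest.approx(0.75)
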