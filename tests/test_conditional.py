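"""Carrier stratification, two-locus conditioning, subgroup exclusions."""

import math

import pytest

from hla2x2.cohort import Allele, Cohort, SeroGroup, Subject, allele_counts
from hla2x2.conditional import (carriers, conditional_scan, exclude_subjects,
                                is_se_carrier)
from hla2x2.fixtures import two_locus_cohort_dpb1_0501
from hla2x2.scan import ScanError, scan_locus
from hla2x2.simulate import SimSpec, simulate_cohort

A0803 = Allele("DRB1", "08:03")
A0601 = Allele("DQB1", "06:01")
A0501 = Allele("DPB1", "05:01")


class TestCarriers:
    def test_backcalculated_carrier_partition(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        with_, without = carriers(case, A0803)
        assert (with_.n, without.n) == (34, 147)
        assert with_.chromosomes == 68 and without.chromosomes == 294
        counts, _ = allele_counts(with_.subjects, "DRB1")
        assert counts[A0803] == 38  # 4 homozygotes among 34 carriers

    def test_absent_allele_gives_empty_with_stratum(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        with_, without = carriers(case, Allele("DRB1", "16:02"))
        assert with_.n == 0 and without.n == len(case)

    def test_homozygote_only_cohort(self):
        subjects = [
            Subject(id=f"h{i}", genotypes={"DRB1": (A0803, A0803)})
            for i in range(3)
        ]
        with_, _ = carriers(Cohort(subjects), A0803)
        counts, _ = allele_counts(with_.subjects, "DRB1")
        assert with_.n == 3 and counts[A0803] == 6


class TestConditionalScan:
    def test_dpb1_0501_in_drb1_0803_negatives(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = two_locus.group(SeroGroup.RO_NEG_LA_NEG)
        res = conditional_scan(case, ctrl, A0501, A0803, polarity="without")
        assert (res.case_count, res.case_total) == (143, 294)
        assert (res.control_count, res.control_total) == (456, 1306)
        assert round(res.test.or_point, 2) == 1.77

    def test_remaining_strata_rows(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = two_locus.group(SeroGroup.RO_NEG_LA_NEG)
        with_row = conditional_scan(case, ctrl, A0501, A0803, polarity="with")
        assert round(with_row.test.or_point, 2) == 0.84
        dq = conditional_scan(case, ctrl, A0601, A0803, polarity="without")
        assert round(dq.test.or_point, 2) == 1.16

    def test_strata_target_counts_sum_to_marginal(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = two_locus.group(SeroGroup.RO_NEG_LA_NEG)
        parts = [conditional_scan(case, ctrl, A0501, A0803, polarity=p)
                 for p in ("with", "without")]
        marginal, _ = allele_counts(case, "DPB1")
        assert sum(r.case_count for r in parts) == marginal[A0501]
        assert sum(r.case_total for r in parts) == 362

    def test_same_locus_conditioning_rejected(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = two_locus.group(SeroGroup.RO_NEG_LA_NEG)
        with pytest.raises(ScanError):
            conditional_scan(case, ctrl, A0803, Allele("DRB1", "01:01"))

    def test_empty_stratum_untestable_not_exception(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = two_locus.group(SeroGroup.RO_NEG_LA_NEG)
        # nobody carries DRB1*16:02 in this fixture -> 'with' stratum empty
        res = conditional_scan(case, ctrl, A0501, Allele("DRB1", "16:02"),
                               polarity="with")
        assert res is None

    def test_vacuous_conditioning_equals_unconditional(self, two_locus):
        case = two_locus.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = two_locus.group(SeroGroup.RO_NEG_LA_NEG)
        res = conditional_scan(case, ctrl, A0501, Allele("DRB1", "16:02"),
                               polarity="without")
        row = {r.label: r for r in scan_locus(case, ctrl, "DPB1")}["DPB1*05:01"]
        assert res.case_count == row.case_count
        assert res.test.p == row.test.p

    def test_perfect_ld_association_absorbed_by_conditioning(self):
        """Two alleles on the same haplotype: conditioning on one removes the
        other's marginal association."""
        spec = SimSpec(
            haplotypes=[("08:03", "06:01", None, 0.10),
                        ("09:01", "03:01", None, 0.90)],
            effects={A0803: math.log(3.0)},
            baseline_logit=-0.5, n_case=500, n_control=500, seed=42,
        )
        cohort = simulate_cohort(spec)
        case = cohort.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = cohort.group(SeroGroup.RO_NEG_LA_NEG)
        marginal = {r.label: r for r in scan_locus(case, ctrl, "DQB1")}["DQB1*06:01"]
        assert marginal.test.or_point > 1.8  # strong marginal signal via LD
        res = conditional_scan(case, ctrl, A0601, A0803, polarity="without")
        # within non-carriers the target allele vanishes entirely
        assert res.case_count == 0 and res.control_count == 0

    def test_independent_loci_conditional_matches_marginal(self):
        """Without LD between conditioning and target, stratification leaves
        the target OR unchanged up to Monte-Carlo noise."""
        haps = [(d, q, None, fd * fq)
                for d, fd in (("08:03", 0.2), ("09:01", 0.8))
                for q, fq in (("06:01", 0.3), ("03:01", 0.7))]
        spec = SimSpec(haplotypes=haps, effects={A0601: math.log(2.5)},
                       baseline_logit=-0.5, n_case=1500, n_control=1500, seed=5)
        cohort = simulate_cohort(spec)
        case = cohort.group(SeroGroup.RO_POS_LA_NEG)
        ctrl = cohort.group(SeroGroup.RO_NEG_LA_NEG)
        marginal = {r.label: r for r in scan_locus(case, ctrl, "DQB1")}["DQB1*06:01"]
        cond = conditional_scan(case, ctrl, A0601, A0803, polarity="without")
        assert cond.test.or_point == pytest.approx(marginal.test.or_point, rel=0.25)


class TestExclusions:
    def test_se_exclusion_reproduces_published_subset(self, se_cohort):
        case = exclude_subjects(se_cohort.group(SeroGroup.RO_POS_LA_NEG), "SE_carrier")
        ctrl = exclude_subjects(se_cohort.group(SeroGroup.RO_NEG_LA_NEG), "SE_carrier")
        assert (len(case), len(ctrl)) == (69, 196)
        rows = {r.label: r for r in scan_locus(case, ctrl, "DRB1")}
        row = rows["DRB1*08:03"]
        assert (row.case_count, row.case_total) == (29, 138)
        assert (row.control_count, row.control_total) == (29, 392)
        assert row.test.or_point == pytest.approx(363 / 109, rel=1e-12)
        assert round(row.test.or_point, 2) == 3.33

    def test_other_se_excluded_rows(self, se_cohort):
        case = exclude_subjects(se_cohort.group(SeroGroup.RO_POS_LA_NEG), "SE_carrier")
        ctrl = exclude_subjects(se_cohort.group(SeroGroup.RO_NEG_LA_NEG), "SE_carrier")
        dq = {r.label: r for r in scan_locus(case, ctrl, "DQB1")}["DQB1*06:01"]
        dp = {r.label: r for r in scan_locus(case, ctrl, "DPB1")}["DPB1*05:01"]
        assert round(dq.test.or_point, 2) == 2.05
        assert round(dp.test.or_point, 2) == 1.53

    def test_cohort_without_se_carriers_is_identity(self, se_cohort):
        case = se_cohort.group(SeroGroup.RO_POS_LA_NEG)
        once = exclude_subjects(case, "SE_carrier")
        twice = exclude_subjects(once, "SE_carrier")
        assert twice.subjects == once.subjects

    def test_excluded_plus_retained_conserves_subjects(self, se_cohort):
        case = se_cohort.group(SeroGroup.RO_POS_LA_NEG)
        kept = exclude_subjects(case, "SE_carrier")
        n_se = sum(1 for s in case if is_se_carrier(s))
        assert len(kept) + n_se == len(case)

    def test_secondary_ss_exclusion_treats_missing_as_negative(self):
        subjects = [
            Subject(id="a", secondary_ss=True),
            Subject(id="b", secondary_ss=False),
            Subject(id="c", secondary_ss=None),
        ]
        kept = exclude_subjects(Cohort(subjects), "secondary_SS")
        assert sorted(s.id for s in kept) == ["b", "c"]

    def test_half_untyped_drb1_se_status(self):
        se_typed = Subject(id="x", genotypes={
            "DRB1": (Allele("DRB1", "04:05"), Allele("DRB1", "XX:XX"))})
        indeterminate = Subject(id="y", genotypes={
            "DRB1": (Allele("DRB1", "09:01"), Allele("DRB1", "XX:XX"))})
        assert is_se_carrier(se_typed) is True
        assert is_se_carrier(indeterminate) is None


def test_dpb1_0501_stratification_of_drb1_0803(two_locus):
    """Reverse conditioning: DRB1*08:03 within DPB1*05:01 strata; the
    reconstructed non-carrier stratum gives OR 5.55 (14/80 vs 22/598)."""
    cohort = two_locus_cohort_dpb1_0501()
    case = cohort.group(SeroGroup.RO_POS_LA_NEG)
    ctrl = cohort.group(SeroGroup.RO_NEG_LA_NEG)
    res = conditional_scan(case, ctrl, A0803, A0501, polarity="without")
    assert (res.case_count, res.case_total) == (14, 80)
    assert (res.control_count, res.control_total) == (22, 598)
    assert round(res.test.or_point, 2) == 5.55
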