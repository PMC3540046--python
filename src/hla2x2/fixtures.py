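"""Reconstructed benchmark cohorts from published contingency counts.

The chromosome counts below reconstruct a Japanese case-control comparison of
HLA class II allele frequencies by anti-Ro/SS-A / anti-La/SS-B serostatus in
RA (181 Ro+La-, 40 Ro+La+, 704 Ro-La- subjects) and SLE (129 / 45 / 137).
Counts are chromosome counts out of 2N per group; where a locus's printed
counts fall short of 2N (one DRB1 and one DQB1 chromosome carried novel
alleles that standard typing could not resolve, and a few DPB1 chromosomes
are unlisted) the remainder is recorded as the untyped sentinel so that
denominators are exact.

Carrier counts needed by the stratified (two-locus) and shared-epitope
reanalyses are not printed directly; they are back-calculated from stratum
denominators (e.g. 294 = 2*(181-34) fixes 34 DRB1*08:03 carriers among the
181 Ro+La- cases) and pinned explicitly in the fixtures.

``PRINTED_OR`` holds the published odds-ratio cells (2 dp) for batch
cross-checks of rendered scans.
"""

from __future__ import annotations

from .cohort import UNTYPED, Cohort, Disease, SeroGroup
from .simulate import FixtureSpec, build_fixture, concat_cohorts

# ---------------------------------------------------------------------------
# RA, marginal counts (Ro+La- and Ro+La+ vs the shared Ro-La- control group)

RA_RO_POS_LA_NEG = {  # n = 181
    "DRB1": {
        "01:01": 21, "04:01": 6, "04:03": 5, "04:05": 92, "04:06": 7,
        "04:10": 4, "08:02": 11, "08:03": 38, "08:23": 1, "09:01": 42,
        "10:01": 3, "11:01": 3, "12:01": 14, "12:02": 7, "13:01": 1,
        "13:02": 7, "14:03": 8, "14:05": 3, "14:06": 9, "14:54": 13,
        "15:01": 28, "15:02": 36, "16:02": 2, UNTYPED: 1,
    },
    "DQB1": {
        "03:01": 39, "03:02": 22, "03:03": 46, "04:01": 96, "04:02": 7,
        "05:01": 25, "05:02": 14, "05:03": 6, "06:01": 72, "06:02": 27,
        "06:03": 1, "06:04": 6, "06:09": 1,
    },
    "DPB1": {
        "01:01": 1, "02:01": 87, "02:02": 15, "03:01": 16, "04:01": 10,
        "04:02": 30, "05:01": 165, "09:01": 24, "13:01": 4, "14:01": 5,
        "19:01": 2, "41:01": 1, UNTYPED: 2,
    },
}

RA_RO_POS_LA_POS = {  # n = 40
    "DRB1": {
        "01:01": 3, "03:01": 1, "04:05": 15, "04:06": 1, "04:10": 5,
        "07:01": 1, "08:02": 4, "08:03": 5, "09:01": 6, "11:01": 1,
        "12:01": 4, "12:02": 3, "13:02": 4, "14:03": 1, "14:05": 2,
        "14:06": 3, "14:54": 2, "15:01": 12, "15:02": 7,
    },
    "DQB1": {
        "02:01": 2, "03:01": 12, "03:02": 4, "03:03": 6, "04:01": 15,
        "04:02": 6, "05:01": 3, "05:02": 1, "05:03": 3, "06:01": 12,
        "06:02": 12, "06:04": 4,
    },
    "DPB1": {
        "02:01": 11, "02:02": 1, "03:01": 5, "04:01": 2, "04:02": 4,
        "05:01": 44, "09:01": 6, "13:01": 2, "14:01": 4, "47:01": 1,
    },
}

RA_RO_NEG_LA_NEG = {  # n = 704
    "DRB1": {
        "01:01": 110, "04:01": 52, "04:03": 20, "04:04": 3, "04:05": 406,
        "04:06": 25, "04:07": 3, "04:10": 33, "07:01": 6, "08:02": 21,
        "08:03": 52, "09:01": 243, "10:01": 12, "11:01": 17, "12:01": 39,
        "12:02": 20, "13:01": 3, "13:02": 60, "14:02": 2, "14:03": 10,
        "14:05": 14, "14:06": 15, "14:07": 1, "14:54": 34, "15:01": 75,
        "15:02": 124, "16:02": 8,
    },
    "DQB1": {
        "02:01": 6, "03:01": 133, "03:02": 73, "03:03": 229, "03:06": 3,
        "04:01": 432, "04:02": 35, "05:01": 125, "05:02": 27, "05:03": 29,
        "06:01": 179, "06:02": 75, "06:03": 3, "06:04": 57, "06:09": 1,
        UNTYPED: 1,
    },
    "DPB1": {
        "02:01": 387, "02:02": 59, "03:01": 56, "04:01": 55, "04:02": 171,
        "05:01": 493, "06:01": 9, "09:01": 112, "13:01": 16, "14:01": 25,
        "17:01": 5, "19:01": 5, "38:01": 3, "41:01": 7, "47:01": 3,
        UNTYPED: 2,
    },
}

# ---------------------------------------------------------------------------
# SLE, DPB1 marginal counts

SLE_RO_POS_LA_NEG = {  # n = 129
    "DPB1": {
        "02:01": 49, "02:02": 11, "03:01": 13, "04:01": 6, "04:02": 27,
        "05:01": 118, "06:01": 1, "09:01": 18, "13:01": 6, "14:01": 8,
        "19:01": 1,
    },
}
SLE_RO_POS_LA_POS = {  # n = 45
    "DPB1": {
        "01:01": 1, "02:01": 10, "02:02": 3, "03:01": 3, "04:02": 7,
        "05:01": 56, "09:01": 4, "13:01": 3, "14:01": 2, UNTYPED: 1,
    },
}
SLE_RO_NEG_LA_NEG = {  # n = 137
    "DPB1": {
        "02:01": 73, "02:02": 19, "03:01": 10, "04:01": 9, "04:02": 25,
        "05:01": 91, "06:01": 2, "09:01": 23, "13:01": 10, "14:01": 8,
        "19:01": 2, "38:01": 2,
    },
}

_GROUP_SIZES = {
    (Disease.RA, SeroGroup.RO_POS_LA_NEG): 181,
    (Disease.RA, SeroGroup.RO_POS_LA_POS): 40,
    (Disease.RA, SeroGroup.RO_NEG_LA_NEG): 704,
    (Disease.SLE, SeroGroup.RO_POS_LA_NEG): 129,
    (Disease.SLE, SeroGroup.RO_POS_LA_POS): 45,
    (Disease.SLE, SeroGroup.RO_NEG_LA_NEG): 137,
}

_SERO_FLAGS = {
    SeroGroup.RO_POS_LA_NEG: (True, False),
    SeroGroup.RO_POS_LA_POS: (True, True),
    SeroGroup.RO_NEG_LA_NEG: (False, False),
}


def _group_fixture(counts, disease, group, prefix) -> Cohort:
    ro, la = _SERO_FLAGS[group]
    spec = FixtureSpec(
        n_subjects=_GROUP_SIZES[(disease, group)],
        counts=counts, disease=disease, anti_ro=ro, anti_la=la,
        id_prefix=prefix,
    )
    return build_fixture(spec)


def ra_cohort() -> Cohort:
    """RA cohort with all three serostatus groups at the printed marginals."""
    return concat_cohorts(
        [
            _group_fixture(RA_RO_POS_LA_NEG, Disease.RA, SeroGroup.RO_POS_LA_NEG, "RA_RP_"),
            _group_fixture(RA_RO_POS_LA_POS, Disease.RA, SeroGroup.RO_POS_LA_POS, "RA_PP_"),
            _group_fixture(RA_RO_NEG_LA_NEG, Disease.RA, SeroGroup.RO_NEG_LA_NEG, "RA_NN_"),
        ],
        provenance="ra-benchmark",
    )


def sle_cohort() -> Cohort:
    """SLE cohort (DPB1 only) with all three serostatus groups."""
    return concat_cohorts(
        [
            _group_fixture(SLE_RO_POS_LA_NEG, Disease.SLE, SeroGroup.RO_POS_LA_NEG, "SL_RP_"),
            _group_fixture(SLE_RO_POS_LA_POS, Disease.SLE, SeroGroup.RO_POS_LA_POS, "SL_PP_"),
            _group_fixture(SLE_RO_NEG_LA_NEG, Disease.SLE, SeroGroup.RO_NEG_LA_NEG, "SL_NN_"),
        ],
        provenance="sle-benchmark",
    )


# ---------------------------------------------------------------------------
# two-locus fixtures: carrier-stratified blocks with pinned carrier counts

def two_locus_cohort_drb1_0803() -> Cohort:
    """RA Ro+La- vs Ro-La- with the joint DRB1*08:03 x DQB1*06:01 x DPB1*05:01
    structure of the carrier-stratified analysis.

    34 of 181 cases and 51 of 704 controls carry DRB1*08:03 (back-calculated
    from stratum denominators 294 = 2*(181-34) and 1306 = 2*(704-51)); the
    within-stratum counts reproduce the published stratified rows exactly.
    """
    case_carriers = FixtureSpec(
        n_subjects=34,
        counts={
            "DRB1": {"08:03": 38, "01:01": 30},
            "DQB1": {"06:01": 40, "03:01": 28},
            "DPB1": {"05:01": 22, "02:01": 46},
        },
        carriers={"DRB1": {"08:03": 34}},
        disease=Disease.RA, anti_ro=True, anti_la=False, id_prefix="TLC_",
    )
    case_noncarriers = FixtureSpec(
        n_subjects=147,
        counts={
            "DRB1": {"01:01": 294},
            "DQB1": {"06:01": 32, "03:01": 262},
            "DPB1": {"05:01": 143, "02:01": 151},
        },
        disease=Disease.RA, anti_ro=True, anti_la=False, id_prefix="TLN_",
    )
    ctrl_carriers = FixtureSpec(
        n_subjects=51,
        counts={
            "DRB1": {"08:03": 52, "01:01": 50},
            "DQB1": {"06:01": 55, "03:01": 47},
            "DPB1": {"05:01": 37, "02:01": 65},
        },
        carriers={"DRB1": {"08:03": 51}},
        disease=Disease.RA, anti_ro=False, anti_la=False, id_prefix="TKC_",
    )
    ctrl_noncarriers = FixtureSpec(
        n_subjects=653,
        counts={
            "DRB1": {"01:01": 1306},
            "DQB1": {"06:01": 124, "03:01": 1182},
            "DPB1": {"05:01": 456, "02:01": 850},
        },
        disease=Disease.RA, anti_ro=False, anti_la=False, id_prefix="TKN_",
    )
    return concat_cohorts(
        [build_fixture(s) for s in
         (case_carriers, case_noncarriers, ctrl_carriers, ctrl_noncarriers)],
        provenance="ra-two-locus-drb1-0803",
    )


def two_locus_cohort_dpb1_0501() -> Cohort:
    """RA Ro+La- vs Ro-La- stratified by DPB1*05:01 carriage.

    141 of 181 cases and 405 of 704 controls carry DPB1*05:01; the
    DRB1*08:03 counts within strata follow the published stratified rows
    (14/80 and 22/598 in non-carriers; 24/282 and 30/810 in carriers).
    """
    case_carriers = FixtureSpec(
        n_subjects=141,
        counts={
            "DPB1": {"05:01": 165, "02:01": 117},
            "DRB1": {"08:03": 24, "01:01": 258},
        },
        carriers={"DPB1": {"05:01": 141}},
        disease=Disease.RA, anti_ro=True, anti_la=False, id_prefix="PLC_",
    )
    case_noncarriers = FixtureSpec(
        n_subjects=40,
        counts={
            "DPB1": {"02:01": 80},
            "DRB1": {"08:03": 14, "01:01": 66},
        },
        disease=Disease.RA, anti_ro=True, anti_la=False, id_prefix="PLN_",
    )
    ctrl_carriers = FixtureSpec(
        n_subjects=405,
        counts={
            "DPB1": {"05:01": 493, "02:01": 317},
            "DRB1": {"08:03": 30, "01:01": 780},
        },
        carriers={"DPB1": {"05:01": 405}},
        disease=Disease.RA, anti_ro=False, anti_la=False, id_prefix="PKC_",
    )
    ctrl_noncarriers = FixtureSpec(
        n_subjects=299,
        counts={
            "DPB1": {"02:01": 598},
            "DRB1": {"08:03": 22, "01:01": 576},
        },
        disease=Disease.RA, anti_ro=False, anti_la=False, id_prefix="PKN_",
    )
    return concat_cohorts(
        [build_fixture(s) for s in
         (case_carriers, case_noncarriers, ctrl_carriers, ctrl_noncarriers)],
        provenance="ra-two-locus-dpb1-0501",
    )


# ---------------------------------------------------------------------------
# shared-epitope stratified fixture

def se_stratified_cohort() -> Cohort:
    """RA Ro+La- vs Ro-La- split into SE carriers and SE-free subjects.

    69 of 181 cases and 196 of 704 controls are SE-free (denominators 138 and
    392); DRB1*08:03 / DQB1*06:01 / DPB1*05:01 counts within the SE-free
    block reproduce the published SE-excluded rows. Every subject in the SE
    block carries exactly one DRB1*04:05 (shared-epitope) allele, pinned via
    a carrier target equal to the block size.
    """
    case_se_free = FixtureSpec(
        n_subjects=69,
        counts={
            "DRB1": {"08:03": 29, "09:01": 60, "15:02": 49},
            "DQB1": {"06:01": 47, "04:01": 91},
            "DPB1": {"05:01": 60, "02:01": 78},
        },
        disease=Disease.RA, anti_ro=True, anti_la=False, id_prefix="SEFC_",
    )
    case_se = FixtureSpec(
        n_subjects=112,
        counts={
            "DRB1": {"04:05": 112, "08:03": 9, "09:01": 103},
            "DQB1": {"06:01": 25, "04:01": 199},
            "DPB1": {"05:01": 105, "02:01": 119},
        },
        carriers={"DRB1": {"04:05": 112}},
        disease=Disease.RA, anti_ro=True, anti_la=False, id_prefix="SEPC_",
    )
    ctrl_se_free = FixtureSpec(
        n_subjects=196,
        counts={
            "DRB1": {"08:03": 29, "09:01": 200, "15:02": 163},
            "DQB1": {"06:01": 79, "04:01": 313},
            "DPB1": {"05:01": 131, "02:01": 261},
        },
        disease=Disease.RA, anti_ro=False, anti_la=False, id_prefix="SEFK_",
    )
    ctrl_se = FixtureSpec(
        n_subjects=508,
        counts={
            "DRB1": {"04:05": 508, "08:03": 23, "09:01": 485},
            "DQB1": {"06:01": 100, "04:01": 916},
            "DPB1": {"05:01": 362, "02:01": 654},
        },
        carriers={"DRB1": {"04:05": 508}},
        disease=Disease.RA, anti_ro=False, anti_la=False, id_prefix="SEPK_",
    )
    return concat_cohorts(
        [build_fixture(s) for s in
         (case_se_free, case_se, ctrl_se_free, ctrl_se)],
        provenance="ra-se-stratified",
    )


# ---------------------------------------------------------------------------
# published odds-ratio cells (2 dp) for batch cross-checks

PRINTED_OR_RA_RO = {  # Ro+La- vs Ro-La-, RA
    "DRB1": {
        "01:01": 0.73, "04:01": 0.44, "04:03": 0.97, "04:04": 0.55,
        "04:05": 0.84, "04:06": 1.09, "04:07": 0.55, "04:10": 0.47,
        "07:01": 0.30, "08:02": 2.07, "08:03": 3.06, "08:23": 11.69,
        "09:01": 0.63, "10:01": 0.97, "11:01": 0.68, "12:01": 1.41,
        "12:02": 1.37, "13:01": 1.30, "13:02": 0.44, "14:02": 0.78,
        "14:03": 3.16, "14:05": 0.83, "14:06": 2.37, "14:07": 1.29,
        "14:54": 1.51, "15:01": 1.49, "15:02": 1.14, "16:02": 0.97,
    },
    "DQB1": {
        "02:01": 0.30, "03:01": 1.16, "03:02": 1.18, "03:03": 0.75,
        "03:06": 0.55, "04:01": 0.82, "04:02": 0.77, "05:01": 0.76,
        "05:02": 2.06, "05:03": 0.80, "06:01": 1.70, "06:02": 1.43,
        "06:03": 1.30, "06:04": 0.40, "06:09": 3.90,
    },
    "DPB1": {
        "01:01": 11.69, "02:01": 0.83, "02:02": 0.99, "03:01": 1.12,
        "04:01": 0.70, "04:02": 0.65, "05:01": 1.55, "06:01": 0.20,
        "09:01": 0.82, "13:01": 0.97, "14:01": 0.77, "17:01": 0.35,
        "19:01": 1.56, "38:01": 0.55, "41:01": 0.55, "47:01": 0.55,
    },
}

PRINTED_OR_RA_LA = {  # Ro+La+ vs Ro-La-, RA
    "DRB1": {
        "01:01": 0.46, "03:01": 53.15, "04:01": 0.16, "04:03": 0.42,
        "04:04": 2.49, "04:05": 0.57, "04:06": 0.70, "04:07": 2.49,
        "04:10": 2.78, "07:01": 2.96, "08:02": 3.48, "08:03": 1.74,
        "09:01": 0.39, "10:01": 0.69, "11:01": 1.04, "12:01": 1.85,
        "12:02": 2.70, "13:01": 2.49, "13:02": 1.18, "14:02": 3.49,
        "14:03": 1.77, "14:05": 2.55, "14:06": 3.62, "14:07": 5.83,
        "14:54": 1.04, "15:01": 3.14, "15:02": 0.99, "16:02": 1.02,
    },
    "DQB1": {
        "02:01": 5.99, "03:01": 1.69, "03:02": 0.96, "03:03": 0.42,
        "03:06": 2.49, "04:01": 0.52, "04:02": 3.18, "05:01": 0.40,
        "05:02": 0.65, "05:03": 1.85, "06:01": 1.21, "06:02": 3.14,
        "06:03": 2.49, "06:04": 1.25, "06:09": 5.83,
    },
    "DPB1": {
        "02:01": 0.42, "02:02": 0.29, "03:01": 1.61, "04:01": 0.63,
        "04:02": 0.38, "05:01": 2.27, "06:01": 0.92, "09:01": 0.94,
        "13:01": 2.23, "14:01": 2.91, "17:01": 1.58, "19:01": 1.58,
        "38:01": 2.49, "41:01": 1.16, "47:01": 5.93,
    },
}

PRINTED_OR_SLE = {  # DPB1 only
    "ro_pos_la_neg": {
        "02:01": 0.65, "02:02": 0.60, "03:01": 1.40, "04:01": 0.70,
        "04:02": 1.16, "05:01": 1.69, "06:01": 0.53, "09:01": 0.82,
        "13:01": 0.63, "14:01": 1.06, "19:01": 0.53, "38:01": 0.21,
    },
    "ro_pos_la_pos": {
        "01:01": 9.20, "02:01": 0.34, "02:02": 0.46, "03:01": 0.91,
        "04:01": 0.15, "04:02": 0.84, "05:01": 3.31, "06:01": 0.60,
        "09:01": 0.51, "13:01": 0.91, "14:01": 0.76, "19:01": 0.60,
        "38:01": 0.60,
    },
}
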