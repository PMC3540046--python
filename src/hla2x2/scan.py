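"""Per-locus one-vs-rest allele association scans between serostatus groups.

Each allele observed on at least one chromosome in the case or the control
group is dichotomized against all other alleles at its locus, tested by
two-sided Fisher exact on chromosome counts, and Bonferroni-corrected with
family size m = number of alleles in the scan. Sentinel untyped chromosomes
stay in the denominators but generate no row (an unresolvable allele cannot
be tested), so m matches the number of reportable alleles.

Named allele sets (serologic groups) are tested as single pre-specified
pooled dichotomies without correction:

* DR2 = all DRB1*15:xx and *16:xx alleles (first-field prefix match),
* DR4 = all DRB1*04:xx alleles,
* SE  = the shared-epitope DRB1 alleles (70-74 motif QKRAA/RRRAA/QRRAA):
  *01:01, *04:01, *04:04, *04:05, *04:10, *10:01, *14:02, *14:06.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .cohort import Allele, Cohort, Disease, SeroGroup, allele_counts
from .stats import CountTable2x2, TestResult, test_table


class ScanError(ValueError):
    pass


#: Shared-epitope DRB1 alleles (two-field names).
SE_ALLELE_NAMES = ("01:01", "04:01", "04:04", "04:05", "04:10",
                   "10:01", "14:02", "14:06")
SE_ALLELES = frozenset(Allele("DRB1", n) for n in SE_ALLELE_NAMES)

#: First-field prefixes defining the DR2 and DR4 serologic groups.
GROUP_PREFIXES = {"DR2": ("15", "16"), "DR4": ("04",)}


@dataclass(frozen=True)
class AssociationResult:
    """One row of a scan: counts, frequencies and the embedded test."""

    label: str
    case_count: int
    case_total: int
    control_count: int
    control_total: int
    test: TestResult

    @property
    def table(self) -> CountTable2x2:
        return CountTable2x2(
            self.case_count, self.case_total - self.case_count,
            self.control_count, self.control_total - self.control_count,
        )

    @property
    def case_freq(self) -> float:
        """Case allele frequency in percent."""
        return 100.0 * self.case_count / self.case_total if self.case_total else 0.0

    @property
    def control_freq(self) -> float:
        return 100.0 * self.control_count / self.control_total if self.control_total else 0.0


@dataclass
class ScanReport:
    """Full multi-locus scan output (ordered rows plus per-locus family sizes)."""

    disease: Optional[Disease]
    comparison: tuple
    results: dict = field(default_factory=dict)  # locus -> list[AssociationResult]
    m_per_locus: dict = field(default_factory=dict)  # locus -> int


def _scan_alleles(case: Cohort, control: Cohort, locus: str):
    case_counts, case_total = allele_counts(case, locus)
    ctrl_counts, ctrl_total = allele_counts(control, locus)
    if case_total == 0:
        raise ScanError(f"case group has no subjects typed at {locus}")
    if ctrl_total == 0:
        raise ScanError(f"control group has no subjects typed at {locus}")
    alleles = sorted(
        {a for a in (set(case_counts) | set(ctrl_counts)) if not a.is_untyped},
        key=Allele.sort_key,
    )
    return case_counts, case_total, ctrl_counts, ctrl_total, alleles


def scan_locus(case: Cohort, control: Cohort, locus: str) -> list:
    """One-vs-rest scan of every observed allele at ``locus``.

    Rows are sorted in canonical allele order; Pc uses m = number of rows.
    """
    case_counts, case_total, ctrl_counts, ctrl_total, alleles = _scan_alleles(
        case, control, locus
    )
    m = len(alleles)
    rows = []
    for allele in alleles:
        ca, co = case_counts.get(allele, 0), ctrl_counts.get(allele, 0)
        t = CountTable2x2(ca, case_total - ca, co, ctrl_total - co)
        rows.append(AssociationResult(
            label=str(allele), case_count=ca, case_total=case_total,
            control_count=co, control_total=ctrl_total,
            test=test_table(t, m=m),
        ))
    return rows


def group_alleles(group: str, observed: Iterable[Allele]) -> set:
    """Resolve a named allele set against the observed alleles at DRB1."""
    if group in GROUP_PREFIXES:
        prefixes = GROUP_PREFIXES[group]
        return {a for a in observed
                if a.locus == "DRB1" and not a.is_untyped
                and a.name.split(":")[0] in prefixes}
    if group == "SE":
        return set(SE_ALLELES)
    raise ScanError(f"unknown allele group {group!r} (known: DR2, DR4, SE)")


def scan_group(case: Cohort, control: Cohort, group) -> AssociationResult:
    """Pooled one-vs-rest test of a named allele set ('DR2', 'DR4', 'SE') or
    an explicit iterable of Allele (all at one locus).

    A single pre-specified test: no Bonferroni correction is applied
    (``test.pc`` is None).
    """
    if isinstance(group, str):
        label = group
        locus = "DRB1"
        case_counts, case_total, ctrl_counts, ctrl_total, observed = _scan_alleles(
            case, control, locus
        )
        members = group_alleles(group, observed)
    else:
        members = set(group)
        loci = {a.locus for a in members}
        if len(loci) != 1:
            raise ScanError("explicit allele group must be at a single locus")
        locus = loci.pop()
        label = "+".join(str(a) for a in sorted(members, key=Allele.sort_key))
        case_counts, case_total, ctrl_counts, ctrl_total, _ = _scan_alleles(
            case, control, locus
        )
    ca = sum(case_counts.get(a, 0) for a in members)
    co = sum(ctrl_counts.get(a, 0) for a in members)
    t = CountTable2x2(ca, case_total - ca, co, ctrl_total - co)
    return AssociationResult(
        label=label, case_count=ca, case_total=case_total,
        control_count=co, control_total=ctrl_total,
        test=test_table(t, correct=False),
    )


def scan(
    case: Cohort,
    control: Cohort,
    loci: Iterable[str] = ("DRB1", "DQB1", "DPB1"),
    disease: Optional[Disease] = None,
    comparison: tuple = (SeroGroup.RO_POS_LA_NEG, SeroGroup.RO_NEG_LA_NEG),
) -> ScanReport:
    """Scan several loci and assemble a ScanReport."""
    report = ScanReport(disease=disease, comparison=comparison)
    for locus in loci:
        rows = scan_locus(case, control, locus)
        report.results[locus] = rows
        report.m_per_locus[locus] = len(rows)
    return report
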