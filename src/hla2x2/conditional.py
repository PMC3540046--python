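"""Two-locus conditional (carrier-stratified) analysis and subgroup exclusions.

Conditioning is on *carrier status* at the subject level: the cohort is split
into subjects carrying at least one copy of the conditioning allele and those
carrying none, and the one-vs-rest test for a target allele at a *different*
locus is then run on chromosome counts within the chosen stratum (frequencies
remain counts out of 2N within the stratum). This disentangles loci in strong
linkage disequilibrium: if the target's marginal association is driven purely
by haplotypes carrying the conditioning allele, it vanishes in the
without-stratum.

Subgroup-exclusion reanalyses remove shared-epitope carriers (computed from
the DRB1 genotype) or subjects with secondary Sjogren's syndrome before
re-running a scan.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional

from .cohort import Allele, Cohort, Subject, allele_counts
from .scan import SE_ALLELES, AssociationResult, ScanError
from .stats import CountTable2x2, test_table

logger = logging.getLogger(__name__)


class ExclusionCriterion(str, enum.Enum):
    SE_CARRIER = "SE_carrier"
    SECONDARY_SS = "secondary_SS"


@dataclass
class CarrierStratum:
    """One side of a carrier partition for a conditioning allele."""

    conditioning_allele: Allele
    polarity: str  # "with" | "without"
    subjects: Cohort

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def chromosomes(self) -> int:
        return 2 * self.n


def carriers(c: Cohort, allele: Allele) -> tuple[CarrierStratum, CarrierStratum]:
    """Partition subjects typed at the allele's locus by carrier status."""
    typed = c.subset(lambda s: s.typed_at(allele.locus))
    with_ = typed.subset(lambda s: s.carries(allele), label=f"{allele}+")
    without = typed.subset(lambda s: not s.carries(allele), label=f"{allele}-")
    return (
        CarrierStratum(allele, "with", with_),
        CarrierStratum(allele, "without", without),
    )


def conditional_scan(
    case: Cohort,
    control: Cohort,
    target: Allele,
    conditioning: Allele,
    polarity: str = "without",
    m: int = 1,
) -> Optional[AssociationResult]:
    """Test ``target`` one-vs-rest within the ``polarity`` stratum of
    ``conditioning`` carriers.

    Same-locus conditioning is rejected. An empty stratum yields None
    (untestable), not an exception. ``m`` is the number of
    (target, conditioning, polarity) combinations in the analysis batch.
    """
    if target.locus == conditioning.locus:
        raise ScanError(
            f"conditioning allele {conditioning} is at the target locus {target.locus}"
        )
    idx = 0 if polarity == "with" else 1
    if polarity not in ("with", "without"):
        raise ScanError(f"polarity must be 'with' or 'without', got {polarity!r}")
    case_stratum = carriers(case, conditioning)[idx].subjects
    ctrl_stratum = carriers(control, conditioning)[idx].subjects
    case_counts, case_total = allele_counts(case_stratum, target.locus)
    ctrl_counts, ctrl_total = allele_counts(ctrl_stratum, target.locus)
    if case_total == 0 or ctrl_total == 0:
        logger.warning(
            "untestable stratum: %s given %s(%s) — empty %s group",
            target, conditioning, polarity,
            "case" if case_total == 0 else "control",
        )
        return None
    ca, co = case_counts.get(target, 0), ctrl_counts.get(target, 0)
    t = CountTable2x2(ca, case_total - ca, co, ctrl_total - co)
    return AssociationResult(
        label=f"{target} | {conditioning}({'+' if polarity == 'with' else '-'})",
        case_count=ca, case_total=case_total,
        control_count=co, control_total=ctrl_total,
        test=test_table(t, m=m),
    )


def is_se_carrier(s: Subject) -> Optional[bool]:
    """Shared-epitope carrier status from the DRB1 genotype.

    Returns None (indeterminate) when the subject is untyped at DRB1, or has
    one untyped call and no SE allele on the typed one — such subjects are
    dropped from SE-stratified analyses with a logged warning.
    """
    pair = s.genotypes.get("DRB1")
    if pair is None:
        return None
    if any(a in SE_ALLELES for a in pair):
        return True
    if any(a.is_untyped for a in pair):
        return None
    return False


def exclude_subjects(c: Cohort, criterion) -> Cohort:
    """Complement subset after removing subjects matching ``criterion``.

    ``SE_carrier``: removes shared-epitope carriers (indeterminate SE status
    is also removed, with a warning). ``secondary_SS``: removes subjects with
    secondary Sjogren's syndrome; missing status is treated as negative
    (retained), with a log note.
    """
    criterion = ExclusionCriterion(criterion)
    if criterion is ExclusionCriterion.SE_CARRIER:
        kept, dropped_indeterminate = [], 0
        for s in c:
            status = is_se_carrier(s)
            if status is False:
                kept.append(s)
            elif status is None:
                dropped_indeterminate += 1
        if dropped_indeterminate:
            logger.warning(
                "%d subjects with indeterminate SE status dropped from the "
                "SE-excluded analysis", dropped_indeterminate,
            )
        return Cohort(kept, provenance=f"{c.provenance}/SE-")
    # secondary SS
    n_missing = sum(1 for s in c if s.secondary_ss is None)
    if n_missing:
        logger.info(
            "%d subjects with missing secondary-SS status treated as negative",
            n_missing,
        )
    return c.subset(lambda s: s.secondary_ss is not True,
                    label=f"{c.provenance}/noSS")
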