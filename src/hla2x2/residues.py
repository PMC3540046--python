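"""Amino-acid-residue fine-mapping of HLA class II associations.

An allele-to-residue alignment maps each two-field allele to the one-letter
residue it encodes at a set of mature-beta-chain positions (the numbering in
which the shared epitope spans DRbeta 70-74). A residue scan collapses
chromosome counts by residue at each position and tests every observed
residue one-vs-rest by Fisher exact, correcting over all (position, residue)
tests in the scan. Because collapsing is linear in chromosome counts, a
residue carried by exactly one observed allele reproduces that allele's test.

The shipped default map (``data/residue_map_synthetic.tsv``) is a synthetic
alignment fixture: it encodes the shared-epitope motifs and the documented
residue-sharing relationships among the alleles covered by the bundled
cohort fixtures, not any specific public alignment release.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort import Allele, Cohort, allele_counts
from .scan import AssociationResult, ScanError
from .stats import CountTable2x2, bonferroni, test_table

#: Shared-epitope motifs at DRbeta 70-74.
SE_MOTIFS = frozenset({"QKRAA", "RRRAA", "QRRAA"})
SE_POSITIONS = (70, 71, 72, 73, 74)

GAP = "-"


class ResidueLookupError(KeyError):
    pass


@dataclass
class ResidueMap:
    """Lookup (Allele, position) -> one-letter residue (or '-' for a gap).

    Within one map, every allele of a locus covers the same set of positions.
    """

    entries: dict = field(default_factory=dict)  # Allele -> {position: residue}

    def __post_init__(self) -> None:
        by_locus: dict[str, frozenset] = {}
        for allele, posmap in self.entries.items():
            positions = frozenset(posmap)
            ref = by_locus.setdefault(allele.locus, positions)
            if positions != ref:
                raise ValueError(
                    f"{allele} covers positions {sorted(positions)} but other "
                    f"{allele.locus} alleles cover {sorted(ref)}"
                )

    def positions(self, locus: str) -> list[int]:
        for allele, posmap in self.entries.items():
            if allele.locus == locus:
                return sorted(posmap)
        return []

    def alleles(self, locus: str) -> list[Allele]:
        return sorted((a for a in self.entries if a.locus == locus),
                      key=Allele.sort_key)

    def residue(self, allele: Allele, position: int) -> str:
        try:
            return self.entries[allele][position]
        except KeyError:
            raise ResidueLookupError(
                f"no residue mapped for {allele} at position {position}"
            ) from None

    @classmethod
    def from_tsv(cls, path, sep: str = "\t") -> "ResidueMap":
        """Read a ``locus allele position residue`` table."""
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"locus", "allele", "position", "residue"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: residue map needs columns {sorted(required)}")
        entries: dict = {}
        for _, row in df.iterrows():
            allele = Allele.parse(row["allele"], locus=row["locus"])
            entries.setdefault(allele, {})[int(row["position"])] = str(row["residue"])
        return cls(entries)

    def to_tsv(self, path, sep: str = "\t") -> None:
        rows = [
            {"locus": a.locus, "allele": a.name, "position": p, "residue": r}
            for a in sorted(self.entries, key=Allele.sort_key)
            for p, r in sorted(self.entries[a].items())
        ]
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def default_residue_map() -> ResidueMap:
    """The bundled synthetic residue alignment fixture."""
    ref = importlib.resources.files("hla2x2").joinpath(
        "data/residue_map_synthetic.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return ResidueMap.from_tsv(path)


def residues_at(rmap: ResidueMap, allele: Allele, positions: Sequence[int]) -> str:
    """Concatenated residues of ``allele`` at ``positions``, in given order."""
    return "".join(rmap.residue(allele, p) for p in positions)


def se_motif(rmap: ResidueMap, allele: Allele) -> bool:
    """True iff the allele's DRbeta 70-74 residues form a shared-epitope motif."""
    if allele.locus != "DRB1":
        raise ValueError(f"shared epitope is defined on DRB1, got {allele}")
    motif = residues_at(rmap, allele, SE_POSITIONS)
    if GAP in motif:
        raise ResidueLookupError(f"gap within positions 70-74 for {allele}")
    return motif in SE_MOTIFS


@dataclass(frozen=True)
class ResidueResult:
    """One residue-level test at one position."""

    locus: str
    position: int
    residue: str
    association: AssociationResult


def residue_scan(
    case: Cohort,
    control: Cohort,
    locus: str,
    rmap: ResidueMap,
    correction: str = "scan",
    gaps: str = "residue",
) -> list[ResidueResult]:
    """Per-position residue association scan.

    Chromosome counts are collapsed by residue at each mapped position; every
    residue observed at a polymorphic position is tested one-vs-rest.
    Monomorphic positions generate no test. Pc multiplies by the total number
    of (position, residue) tests in the scan (``correction="scan"``) or by
    the number of residues at the same position (``correction="position"``).
    Gap characters are a testable residue category by default
    (``gaps="residue"``); ``gaps="drop"`` removes gap chromosomes from that
    position's denominator.

    Sentinel untyped chromosomes are dropped from residue denominators; any
    other allele absent from the map raises an error naming it.
    """
    if correction not in ("scan", "position"):
        raise ValueError(f"unknown correction mode {correction!r}")
    if gaps not in ("residue", "drop"):
        raise ValueError(f"unknown gap mode {gaps!r}")

    case_counts, _, ctrl_counts, _ = _mapped_counts(case, control, locus, rmap)
    positions = rmap.positions(locus)

    # collapse allele counts to residue counts per position
    per_pos: list[tuple[int, dict, dict, int, int]] = []
    for pos in positions:
        c_res: dict[str, int] = {}
        k_res: dict[str, int] = {}
        for allele, n in case_counts.items():
            r = rmap.residue(allele, pos)
            c_res[r] = c_res.get(r, 0) + n
        for allele, n in ctrl_counts.items():
            r = rmap.residue(allele, pos)
            k_res[r] = k_res.get(r, 0) + n
        if gaps == "drop":
            c_res.pop(GAP, None)
            k_res.pop(GAP, None)
        residues = sorted(set(c_res) | set(k_res))
        if len(residues) < 2:
            continue  # monomorphic: no test
        ct = sum(c_res.values())
        kt = sum(k_res.values())
        per_pos.append((pos, c_res, k_res, ct, kt))

    m_scan = sum(len(set(c) | set(k)) for _, c, k, _, _ in per_pos)
    results = []
    for pos, c_res, k_res, ct, kt in per_pos:
        residues = sorted(set(c_res) | set(k_res))
        m = m_scan if correction == "scan" else len(residues)
        for r in residues:
            ca = c_res.get(r, 0)
            co = k_res.get(r, 0)
            t = CountTable2x2(ca, ct - ca, co, kt - co)
            results.append(ResidueResult(
                locus=locus, position=pos, residue=r,
                association=AssociationResult(
                    label=f"{locus} pos{pos} {r}",
                    case_count=ca, case_total=ct,
                    control_count=co, control_total=kt,
                    test=test_table(t, m=m),
                ),
            ))
    return results


def _mapped_counts(case: Cohort, control: Cohort, locus: str, rmap: ResidueMap):
    case_counts, case_total = allele_counts(case, locus)
    ctrl_counts, ctrl_total = allele_counts(control, locus)
    missing = sorted(
        str(a)
        for a in (set(case_counts) | set(ctrl_counts))
        if not a.is_untyped and a not in rmap.entries
    )
    if missing:
        raise ScanError(f"alleles missing from the residue map: {missing}")
    case_counts = {a: n for a, n in case_counts.items() if not a.is_untyped}
    ctrl_counts = {a: n for a, n in ctrl_counts.items() if not a.is_untyped}
    return case_counts, case_total, ctrl_counts, ctrl_total
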