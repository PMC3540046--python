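"""Subject-level data model and delimited-text I/O.

The unit of analysis is a diploid subject genotyped at up to three HLA class
II loci (DRB1, DQB1, DPB1) with autoantibody serostatus (anti-Ro/SS-A,
anti-La/SS-B) and clinical covariates. All downstream statistics count
chromosomes: each subject typed at a locus contributes exactly two allele
observations there, so allele frequencies are counts out of 2N.

Allele names use two-field nomenclature ("08:03"). Higher-resolution input
("08:36:02") is truncated to two fields with a logged note. A chromosome whose
allele could not be resolved by typing is recorded with the sentinel name
``UNTYPED`` ("XX:XX"); it contributes to chromosome denominators but is never
reported as an allele of its own.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

LOCI = ("DRB1", "DQB1", "DPB1")

#: Sentinel second-field name for a chromosome that could not be typed.
UNTYPED = "XX:XX"

_ALLELE_RE = re.compile(r"^\d{2,3}:\d{2,3}$")


class CohortError(ValueError):
    """Raised on malformed or inconsistent cohort input."""


@dataclass(frozen=True, order=True)
class Allele:
    """One HLA class II allele call, canonicalized to two-field nomenclature.

    ``Allele.parse("DRB1*08:03")``, ``Allele.parse("*DRB1*08:03")`` and
    ``Allele("DRB1", "08:03")`` all compare equal.
    """

    locus: str
    name: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise CohortError(f"unknown locus {self.locus!r} (expected one of {LOCI})")
        if self.name != UNTYPED and not _ALLELE_RE.match(self.name):
            raise CohortError(
                f"malformed allele name {self.name!r} for locus {self.locus} "
                "(expected two numeric fields like '08:03')"
            )

    @classmethod
    def parse(cls, text: str, locus: Optional[str] = None) -> "Allele":
        """Parse an allele from free text, optionally with a known locus.

        Accepts "DRB1*08:03", "*DRB1*08:03", "08:03" (with ``locus`` given),
        and truncates >2-field names ("08:36:02") to two fields.
        """
        raw = text.strip().strip("*")
        if "*" in raw:
            loc, _, name = raw.partition("*")
            loc = loc.strip().upper()
        else:
            loc, name = locus or "", raw
        if locus is not None and loc and loc != locus:
            raise CohortError(f"allele {text!r} names locus {loc}, expected {locus}")
        loc = loc or (locus or "")
        name = name.strip()
        if name.upper() in ("", "XX:XX", "UNTYPED", "NA", "-"):
            return cls(loc, UNTYPED)
        fields = name.split(":")
        if len(fields) > 2:
            logger.info("truncating allele %s*%s to two fields", loc, name)
            name = ":".join(fields[:2])
        if not _ALLELE_RE.match(name):
            raise CohortError(f"malformed allele string {text!r}")
        return cls(loc, name)

    @property
    def is_untyped(self) -> bool:
        return self.name == UNTYPED

    def sort_key(self) -> tuple:
        """Canonical ordering: locus order, then numeric fields; untyped last."""
        li = LOCI.index(self.locus)
        if self.is_untyped:
            return (li, 1 << 30, 1 << 30)
        f1, f2 = self.name.split(":")
        return (li, int(f1), int(f2))

    def __str__(self) -> str:
        return f"{self.locus}*{self.name}"


class Disease(str, enum.Enum):
    RA = "RA"
    SLE = "SLE"


class SeroGroup(enum.Enum):
    """Serostatus group defined jointly by anti-Ro/SS-A and anti-La/SS-B."""

    RO_POS_LA_NEG = "ro_pos_la_neg"
    RO_POS_LA_POS = "ro_pos_la_pos"
    RO_NEG_LA_NEG = "ro_neg_la_neg"
    RO_NEG_LA_POS = "ro_neg_la_pos"
    UNCLASSIFIABLE = "unclassifiable"


# tri-states are Optional[bool]: True = positive, False = negative, None = missing
TriState = Optional[bool]

_TRI_IN = {
    "pos": True, "positive": True, "1": True, "true": True,
    "neg": False, "negative": False, "0": False, "false": False,
    "": None, "na": None, "nan": None, "missing": None,
}


def parse_tristate(text: object) -> TriState:
    s = str(text).strip().lower() if text is not None else ""
    if s not in _TRI_IN:
        raise CohortError(f"cannot parse tri-state value {text!r}")
    return _TRI_IN[s]


def tristate_str(v: TriState) -> str:
    return "" if v is None else ("pos" if v else "neg")


@dataclass
class Subject:
    """One study subject: identity, phenotype and per-locus diploid genotype."""

    id: str
    disease: Optional[Disease] = None
    anti_ro: TriState = None
    anti_la: TriState = None
    secondary_ss: TriState = None
    sex: Optional[str] = None  # "male" / "female" / None
    age_years: Optional[float] = None
    duration_years: Optional[float] = None
    rf: TriState = None
    acpa: TriState = None
    anti_dsdna: TriState = None
    genotypes: dict = field(default_factory=dict)  # locus -> (Allele, Allele)

    def typed_at(self, locus: str) -> bool:
        return locus in self.genotypes

    def carries(self, allele: Allele) -> bool:
        """Carrier status: at least one copy of ``allele`` (homozygotes count once)."""
        pair = self.genotypes.get(allele.locus)
        return pair is not None and allele in pair

    def sero_group(self) -> SeroGroup:
        return sero_group(self)


def sero_group(s: Subject) -> SeroGroup:
    """Classify a subject by joint anti-Ro / anti-La serostatus.

    Any missing component makes the subject unclassifiable; classification is
    a pure function of the two tri-states.
    """
    ro, la = s.anti_ro, s.anti_la
    if ro is None or la is None:
        return SeroGroup.UNCLASSIFIABLE
    if ro and not la:
        return SeroGroup.RO_POS_LA_NEG
    if ro and la:
        return SeroGroup.RO_POS_LA_POS
    if not ro and not la:
        return SeroGroup.RO_NEG_LA_NEG
    return SeroGroup.RO_NEG_LA_POS


@dataclass
class Cohort:
    """A list of subjects with unique ids plus a free-text provenance label."""

    subjects: list
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subset(self, predicate: Callable[[Subject], bool], label: str = "") -> "Cohort":
        return Cohort([s for s in self.subjects if predicate(s)],
                      provenance=label or self.provenance)

    def group(self, group: SeroGroup, disease: Optional[Disease] = None) -> "Cohort":
        """Subjects in one serostatus group (optionally restricted by disease)."""
        def pred(s: Subject) -> bool:
            if disease is not None and s.disease != disease:
                return False
            return sero_group(s) is group
        tag = f"{self.provenance}/{group.value}" if self.provenance else group.value
        return self.subset(pred, label=tag)


def allele_counts(
    c: Cohort, locus: str, group: Optional[SeroGroup] = None
) -> tuple[Counter, int]:
    """Chromosome counts per allele at ``locus`` (optionally within one group).

    Each typed subject contributes exactly two chromosomes; homozygotes
    contribute 2 to one allele. Returns ``(counts, total_chromosomes)`` with
    ``total_chromosomes = 2 * number of typed subjects``; untyped-at-locus
    subjects are excluded from this locus only. Sentinel untyped chromosomes
    appear in the Counter under their untyped Allele.
    """
    counts: Counter = Counter()
    n_typed = 0
    for s in c:
        if group is not None and sero_group(s) is not group:
            continue
        pair = s.genotypes.get(locus)
        if pair is None:
            continue
        n_typed += 1
        counts[pair[0]] += 1
        counts[pair[1]] += 1
    return counts, 2 * n_typed


# ---------------------------------------------------------------------------
# delimited-text I/O

GENOTYPE_COLUMNS = ["subject_id", "locus", "allele1", "allele2"]
PHENOTYPE_COLUMNS = [
    "subject_id", "disease", "anti_ro", "anti_la", "secondary_ss",
    "sex", "age", "duration", "rf", "acpa", "anti_dsdna",
]


def _read_table(path: Path, columns: list[str], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required columns {missing}")
    return df


def read_cohort(
    genotype_path, phenotype_path, sep: str = "\t", provenance: str = ""
) -> Cohort:
    """Join genotype and phenotype tables on subject id into a Cohort.

    Subjects present in only one file are retained with missing fields (a
    warning is logged). Malformed allele strings raise a parse error naming
    the offending line; duplicate (subject, locus) rows raise a validation
    error.
    """
    gdf = _read_table(Path(genotype_path), GENOTYPE_COLUMNS, sep)
    pdf = _read_table(Path(phenotype_path), PHENOTYPE_COLUMNS, sep)

    subjects: dict[str, Subject] = {}
    for _, row in pdf.iterrows():
        sid = str(row["subject_id"])
        if sid in subjects:
            raise CohortError(f"duplicate phenotype rows for subject {sid!r}")
        disease = None
        if str(row["disease"]).strip():
            try:
                disease = Disease(str(row["disease"]).strip().upper())
            except ValueError as exc:
                raise CohortError(f"unknown disease {row['disease']!r} for {sid}") from exc
        sex = str(row["sex"]).strip().lower() or None
        subjects[sid] = Subject(
            id=sid,
            disease=disease,
            anti_ro=parse_tristate(row["anti_ro"]),
            anti_la=parse_tristate(row["anti_la"]),
            secondary_ss=parse_tristate(row["secondary_ss"]),
            sex=sex if sex in ("male", "female") else None,
            age_years=float(row["age"]) if str(row["age"]).strip() else None,
            duration_years=float(row["duration"]) if str(row["duration"]).strip() else None,
            rf=parse_tristate(row["rf"]),
            acpa=parse_tristate(row["acpa"]),
            anti_dsdna=parse_tristate(row["anti_dsdna"]),
        )

    seen: set[tuple[str, str]] = set()
    n_geno_only = 0
    for i, row in gdf.iterrows():
        sid = str(row["subject_id"])
        locus = str(row["locus"]).strip().upper()
        if locus not in LOCI:
            raise CohortError(f"{genotype_path} line {i + 2}: unknown locus {locus!r}")
        if (sid, locus) in seen:
            raise CohortError(
                f"{genotype_path} line {i + 2}: duplicate row for subject {sid!r} locus {locus}"
            )
        seen.add((sid, locus))
        try:
            a1 = Allele.parse(str(row["allele1"]), locus=locus)
            a2 = Allele.parse(str(row["allele2"]), locus=locus)
        except CohortError as exc:
            raise CohortError(f"{genotype_path} line {i + 2}: {exc}") from exc
        if sid not in subjects:
            n_geno_only += 1
            subjects[sid] = Subject(id=sid)
        subjects[sid].genotypes[locus] = (a1, a2)

    n_pheno_only = sum(1 for s in subjects.values() if not s.genotypes)
    if n_geno_only:
        logger.warning("%d subjects present only in the genotype table", n_geno_only)
    if n_pheno_only:
        logger.warning("%d subjects present only in the phenotype table", n_pheno_only)
    return Cohort(list(subjects.values()), provenance=provenance or str(genotype_path))


def write_cohort(c: Cohort, genotype_path, phenotype_path, sep: str = "\t") -> None:
    """Write a cohort back to the two-table text schema (inverse of read_cohort)."""
    grows = []
    prows = []
    for s in c:
        prows.append({
            "subject_id": s.id,
            "disease": s.disease.value if s.disease else "",
            "anti_ro": tristate_str(s.anti_ro),
            "anti_la": tristate_str(s.anti_la),
            "secondary_ss": tristate_str(s.secondary_ss),
            "sex": s.sex or "",
            "age": "" if s.age_years is None else repr(s.age_years),
            "duration": "" if s.duration_years is None else repr(s.duration_years),
            "rf": tristate_str(s.rf),
            "acpa": tristate_str(s.acpa),
            "anti_dsdna": tristate_str(s.anti_dsdna),
        })
        for locus in LOCI:
            pair = s.genotypes.get(locus)
            if pair is None:
                continue
            grows.append({
                "subject_id": s.id, "locus": locus,
                "allele1": pair[0].name, "allele2": pair[1].name,
            })
    pd.DataFrame(prows, columns=PHENOTYPE_COLUMNS).to_csv(phenotype_path, sep=sep, index=False)
    pd.DataFrame(grows, columns=GENOTYPE_COLUMNS).to_csv(genotype_path, sep=sep, index=False)
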