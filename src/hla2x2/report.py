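"""Run configuration, table rendering and the end-to-end pipeline.

This module formats upstream results and orchestrates stages; it performs no
statistics of its own. Two rendering styles are provided: ``machine``
(full-precision TSV that round-trips losslessly) and ``paper`` (counts with
percent at 1 dp, OR at 2 dp, Pc printed only when the uncorrected p < 0.05
and 'NS' otherwise, CI printed when Pc is numeric).
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cohort import Cohort, Disease, SeroGroup, read_cohort
from .conditional import exclude_subjects
from .residues import ResidueMap, default_residue_map, residue_scan
from .scan import AssociationResult, ScanReport, scan
from .stats import compare_means_raw, fisher_two_sided, CountTable2x2, fmt_freq, fmt_or, fmt_p, fmt_pc

logger = logging.getLogger(__name__)

MACHINE_COLUMNS = [
    "locus", "allele", "case_count", "case_total", "control_count",
    "control_total", "case_pct", "control_pct", "P", "OR", "Pc",
    "CI_low", "CI_high", "m", "corrected_cells",
]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated description of one pipeline run (serialized for provenance)."""

    genotype_path: str
    phenotype_path: str
    disease: str = "RA"
    case_group: str = "ro_pos_la_neg"
    control_group: str = "ro_neg_la_neg"
    loci: tuple = ("DRB1", "DQB1", "DPB1")
    exclude: Optional[str] = None  # None | "se" | "secondary-ss"
    residue_map_path: Optional[str] = None
    run_residues: bool = False
    out_prefix: str = "hla2x2_out"
    style: str = "machine"
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            Disease(self.disease)
        except ValueError:
            raise ConfigError(f"unknown disease {self.disease!r}")
        for name in (self.case_group, self.control_group):
            try:
                SeroGroup(name)
            except ValueError:
                raise ConfigError(f"unknown serostatus group {name!r}")
        bad = [l for l in self.loci if l not in ("DRB1", "DQB1", "DPB1")]
        if bad:
            raise ConfigError(f"unknown loci {bad}")
        if self.exclude not in (None, "se", "secondary-ss"):
            raise ConfigError(f"unknown exclusion {self.exclude!r}")
        if self.style not in ("machine", "paper"):
            raise ConfigError(f"unknown style {self.style!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "loci" in data:
            data["loci"] = tuple(data["loci"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["loci"] = list(data["loci"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _row_record(locus: str, r: AssociationResult) -> dict:
    t = r.test
    return {
        "locus": locus,
        "allele": r.label,
        "case_count": r.case_count,
        "case_total": r.case_total,
        "control_count": r.control_count,
        "control_total": r.control_total,
        "case_pct": repr(r.case_freq),
        "control_pct": repr(r.control_freq),
        "P": repr(t.p),
        "OR": repr(t.or_point),
        "Pc": "" if t.pc is None else repr(t.pc),
        "CI_low": repr(t.ci_low),
        "CI_high": repr(t.ci_high),
        "m": t.m,
        "corrected_cells": int(t.corrected_cells),
    }


def render_table(report: ScanReport, style: str = "machine") -> str:
    """Render a ScanReport as text (machine TSV or paper-style table)."""
    if not report.results:
        raise ValueError("empty report")
    if style == "machine":
        rows = [
            _row_record(locus, r)
            for locus, results in report.results.items()
            for r in results
        ]
        buf = io.StringIO()
        pd.DataFrame(rows, columns=MACHINE_COLUMNS).to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    if style != "paper":
        raise ValueError(f"unknown style {style!r}")
    lines = ["allele\tcase n (%)\tcontrol n (%)\tP\tOR\tPc\t95%CI"]
    for locus, results in report.results.items():
        for r in results:
            t = r.test
            pc_cell = fmt_pc(t)
            ci_cell = (
                f"({fmt_or(t.ci_low)}-{fmt_or(t.ci_high)})"
                if (t.pc is not None and t.p < 0.05) else ""
            )
            lines.append("\t".join([
                r.label,
                fmt_freq(r.case_count, r.case_total),
                fmt_freq(r.control_count, r.control_total),
                fmt_p(t.p),
                fmt_or(t.or_point),
                pc_cell,
                ci_cell,
            ]))
    return "\n".join(lines) + "\n"


def read_machine_table(path_or_buf) -> pd.DataFrame:
    """Read back a machine-style TSV (lossless inverse of render_table)."""
    return pd.read_csv(path_or_buf, sep="\t", float_precision="round_trip")


def characteristics_table(group_a: Cohort, group_b: Cohort) -> pd.DataFrame:
    """Cohort-characteristics comparison between two groups.

    Continuous covariates (age, disease duration) are compared by the Welch
    two-sample t test on the raw values; binary covariates (sex, secondary
    SS, RF, ACPA, anti-dsDNA) by two-sided Fisher exact on subject counts.
    """
    rows = []

    def cont(label, attr):
        xa = [getattr(s, attr) for s in group_a if getattr(s, attr) is not None]
        xb = [getattr(s, attr) for s in group_b if getattr(s, attr) is not None]
        if len(xa) >= 2 and len(xb) >= 2:
            p = compare_means_raw(xa, xb, method="welch")
            rows.append({"characteristic": label, "case": len(xa),
                         "control": len(xb), "P": p, "test": "welch-t"})

    def binary(label, fn):
        va = [fn(s) for s in group_a]
        vb = [fn(s) for s in group_b]
        a = sum(1 for v in va if v is True)
        b = sum(1 for v in va if v is False)
        c = sum(1 for v in vb if v is True)
        d = sum(1 for v in vb if v is False)
        if a + b and c + d:
            p = fisher_two_sided(CountTable2x2(a, b, c, d))
            rows.append({"characteristic": label, "case": a, "control": c,
                         "P": p, "test": "fisher"})

    cont("age_years", "age_years")
    cont("duration_years", "duration_years")
    binary("male", lambda s: None if s.sex is None else s.sex == "male")
    binary("secondary_ss", lambda s: s.secondary_ss)
    binary("rf_positive", lambda s: s.rf)
    binary("acpa_positive", lambda s: s.acpa)
    binary("anti_dsdna_positive", lambda s: s.anti_dsdna)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> list:
    """Execute the configured scan stages; returns the list of written paths."""
    cohort = read_cohort(cfg.genotype_path, cfg.phenotype_path)
    disease = Disease(cfg.disease)
    case = cohort.group(SeroGroup(cfg.case_group), disease)
    control = cohort.group(SeroGroup(cfg.control_group), disease)
    if cfg.exclude == "se":
        case = exclude_subjects(case, "SE_carrier")
        control = exclude_subjects(control, "SE_carrier")
    elif cfg.exclude == "secondary-ss":
        case = exclude_subjects(case, "secondary_SS")
        control = exclude_subjects(control, "secondary_SS")
    logger.info("case group: %d subjects; control group: %d subjects",
                len(case), len(control))

    written = []
    prefix = Path(cfg.out_prefix)
    report = scan(case, control, loci=cfg.loci, disease=disease,
                  comparison=(SeroGroup(cfg.case_group), SeroGroup(cfg.control_group)))
    for locus in cfg.loci:
        sub = ScanReport(report.disease, report.comparison,
                         {locus: report.results[locus]},
                         {locus: report.m_per_locus[locus]})
        path = Path(f"{prefix}.{locus}.tsv")
        path.write_text(render_table(sub, style=cfg.style))
        written.append(path)
        logger.info("%s: %d alleles tested (m=%d)", locus,
                    report.m_per_locus[locus], report.m_per_locus[locus])

    if cfg.run_residues:
        rmap = (ResidueMap.from_tsv(cfg.residue_map_path)
                if cfg.residue_map_path else default_residue_map())
        for locus in cfg.loci:
            results = residue_scan(case, control, locus, rmap)
            rows = [{
                "locus": rr.locus, "position": rr.position, "residue": rr.residue,
                "case_count": rr.association.case_count,
                "case_total": rr.association.case_total,
                "control_count": rr.association.control_count,
                "control_total": rr.association.control_total,
                "P": repr(rr.association.test.p),
                "Pc": repr(rr.association.test.pc),
                "OR": repr(rr.association.test.or_point),
            } for rr in results]
            path = Path(f"{prefix}.{locus}.residues.tsv")
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            written.append(path)

    cfg.to_yaml(f"{prefix}.config.yaml")
    written.append(Path(f"{prefix}.config.yaml"))
    return written
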