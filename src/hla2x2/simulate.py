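"""Synthetic cohorts: haplotype-based simulation and exact count fixtures.

Two generators are provided.

``simulate_cohort`` draws diploid genotypes as two i.i.d. three-locus
haplotypes per subject from a specified haplotype frequency spectrum (which
is how inter-locus linkage disequilibrium is encoded: put two alleles on the
same haplotype and they co-occur), then assigns case/control serostatus from
a logistic model whose logit is a baseline plus per-allele log-odds effects
additive in copy number. Sampling rejects subjects until the requested case
and control quotas are filled, mimicking case-control ascertainment. Fully
reproducible given the seed.

``build_fixture`` deterministically constructs a cohort whose per-group
chromosome counts match a specification *exactly*, for reconstructing
published contingency tables. Genotype pairing is greedy over the remaining
allele pool in canonical order unless a carrier count is pinned for an
allele, in which case ``count - carriers`` homozygotes are created and every
remaining copy is paired with a non-target allele so the carrier total is hit
exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .cohort import LOCI, Allele, Cohort, Disease, Subject

_ATTEMPT_CAP = 200  # batches of max(n_case, n_control) subjects each


class SimulationError(RuntimeError):
    pass


@dataclass
class SimSpec:
    """Full description of a simulated case-control cohort.

    ``haplotypes`` is a list of ``(drb1, dqb1, dpb1, frequency)`` with allele
    names as two-field strings (None to leave a locus untyped); frequencies
    must sum to 1. ``effects`` maps Allele -> log-OR per allele copy.
    """

    haplotypes: list
    effects: Mapping[Allele, float] = field(default_factory=dict)
    baseline_logit: float = 0.0
    n_case: int = 100
    n_control: int = 100
    seed: int = 0
    disease: Disease = Disease.RA

    def __post_init__(self) -> None:
        total = sum(h[3] for h in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(h[3] < 0 for h in self.haplotypes):
            raise ValueError("haplotype frequencies must be non-negative")


def _haplotype_alleles(hap: Sequence) -> dict:
    out = {}
    for locus, name in zip(LOCI, hap[:3]):
        if name is not None:
            out[locus] = Allele(locus, name)
    return out


def simulate_cohort(spec: SimSpec) -> Cohort:
    """Simulate a case-control cohort under the logistic serostatus model.

    Cases are labelled anti-Ro positive / anti-La negative and controls
    doubly negative, so a simulated comparison is Ro(+)La(-) vs Ro(-)La(-).
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([h[3] for h in spec.haplotypes], dtype=float)
    freqs = freqs / freqs.sum()
    hap_alleles = [_haplotype_alleles(h) for h in spec.haplotypes]
    # per-haplotype effect contribution (sum of allele effects on it)
    hap_eff = np.array(
        [sum(spec.effects.get(a, 0.0) for a in alleles.values())
         for alleles in hap_alleles]
    )

    cases: list[Subject] = []
    controls: list[Subject] = []
    batch = max(spec.n_case, spec.n_control, 256)
    sid = itertools.count()
    for _ in range(_ATTEMPT_CAP):
        if len(cases) >= spec.n_case and len(controls) >= spec.n_control:
            break
        h1 = rng.choice(len(freqs), size=batch, p=freqs)
        h2 = rng.choice(len(freqs), size=batch, p=freqs)
        logit = spec.baseline_logit + hap_eff[h1] + hap_eff[h2]
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        for i in range(batch):
            bucket, quota = (
                (cases, spec.n_case) if is_case[i] else (controls, spec.n_control)
            )
            if len(bucket) >= quota:
                continue
            genotypes = {}
            for locus in LOCI:
                a1 = hap_alleles[h1[i]].get(locus)
                a2 = hap_alleles[h2[i]].get(locus)
                if a1 is not None and a2 is not None:
                    genotypes[locus] = (a1, a2)
            bucket.append(Subject(
                id=f"S{next(sid):06d}",
                disease=spec.disease,
                anti_ro=bool(is_case[i]),
                anti_la=False,
                genotypes=genotypes,
            ))
    else:
        raise SimulationError(
            f"could not fill quotas ({len(cases)}/{spec.n_case} cases, "
            f"{len(controls)}/{spec.n_control} controls) within "
            f"{_ATTEMPT_CAP} batches; effects may make one class too rare"
        )
    return Cohort(cases + controls, provenance=f"sim(seed={spec.seed})")


# ---------------------------------------------------------------------------
# exact fixtures

@dataclass
class FixtureSpec:
    """Exact per-group chromosome counts for one homogeneous block of subjects.

    ``counts`` maps locus -> {allele name -> chromosome count}; per locus the
    counts must sum to ``2 * n_subjects`` (use the untyped sentinel "XX:XX"
    to absorb untypable chromosomes). ``carriers`` optionally pins the number
    of subjects carrying an allele; a pinned allele with count k and carrier
    target c yields exactly ``k - c`` homozygotes.
    """

    n_subjects: int
    counts: Mapping[str, Mapping[str, int]]
    carriers: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    disease: Disease = Disease.RA
    anti_ro: Optional[bool] = None
    anti_la: Optional[bool] = None
    secondary_ss: Optional[bool] = None
    id_prefix: str = "F"

    def __post_init__(self) -> None:
        for locus, cmap in self.counts.items():
            total = sum(cmap.values())
            if total != 2 * self.n_subjects:
                raise ValueError(
                    f"{locus}: counts sum to {total}, expected {2 * self.n_subjects}"
                )
            if any(v < 0 for v in cmap.values()):
                raise ValueError(f"{locus}: negative count")
        for locus, pins in self.carriers.items():
            for name, c in pins.items():
                k = self.counts[locus].get(name, 0)
                lo, hi = math.ceil(k / 2), min(k, self.n_subjects)
                if not lo <= c <= hi:
                    raise ValueError(
                        f"carrier target {c} for {locus}*{name} infeasible: "
                        f"count {k} in {self.n_subjects} subjects allows "
                        f"[{lo}, {hi}]"
                    )


def _pair_locus(spec: FixtureSpec, locus: str) -> list[tuple[Allele, Allele]]:
    """Deterministic genotype pairing for one locus matching counts exactly."""
    cmap = dict(spec.counts[locus])
    pins = dict(spec.carriers.get(locus, {}))
    pairs: list[tuple[Allele, Allele]] = []

    # pinned alleles first: homozygotes, then singles paired with non-target
    for name in sorted(pins):
        k = cmap.get(name, 0)
        target = Allele(locus, name)
        n_hom = k - pins[name]
        cmap[name] = 0
        remaining_singles = k - 2 * n_hom
        pairs.extend((target, target) for _ in range(n_hom))
        for _ in range(remaining_singles):
            partner = next(
                (nm for nm in sorted(cmap, key=lambda x: Allele(locus, x).sort_key())
                 if cmap[nm] > 0 and nm not in pins),
                None,
            )
            if partner is None:
                raise ValueError(
                    f"cannot pair {remaining_singles} copies of {target} "
                    "with non-target alleles: pool exhausted"
                )
            cmap[partner] -= 1
            pairs.append((target, Allele(locus, partner)))

    # greedy pairing of the remaining pool in canonical order
    pool: list[Allele] = []
    for name in sorted(cmap, key=lambda x: Allele(locus, x).sort_key()):
        pool.extend([Allele(locus, name)] * cmap[name])
    if len(pool) % 2:
        raise ValueError(f"{locus}: odd residual pool")  # unreachable if counts valid
    pairs.extend((pool[i], pool[i + 1]) for i in range(0, len(pool), 2))

    if len(pairs) != spec.n_subjects:
        raise ValueError(f"{locus}: produced {len(pairs)} genotypes "
                         f"for {spec.n_subjects} subjects")
    return pairs


def build_fixture(spec: FixtureSpec) -> Cohort:
    """Construct a concrete cohort reproducing the specified counts exactly."""
    per_locus = {locus: _pair_locus(spec, locus) for locus in spec.counts}
    subjects = []
    for i in range(spec.n_subjects):
        genotypes = {locus: pairs[i] for locus, pairs in per_locus.items()}
        subjects.append(Subject(
            id=f"{spec.id_prefix}{i:05d}",
            disease=spec.disease,
            anti_ro=spec.anti_ro,
            anti_la=spec.anti_la,
            secondary_ss=spec.secondary_ss,
            genotypes=genotypes,
        ))
    return Cohort(subjects, provenance=f"fixture({spec.id_prefix})")


def concat_cohorts(cohorts: Iterable[Cohort], provenance: str = "") -> Cohort:
    """Union of disjoint cohorts (subject ids must stay unique)."""
    subjects = [s for c in cohorts for s in c]
    return Cohort(subjects, provenance=provenance)
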