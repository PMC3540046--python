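# Methods

## Counting model

The unit of counting is the chromosome. A diploid subject typed at a locus
contributes exactly two allele observations there; homozygotes contribute two
to one allele. Allele frequency within a group is `count / 2N` where N is the
number of subjects *typed at that locus* — subjects untyped at a locus drop
out of that locus's denominator only and remain in every other analysis.
A chromosome whose allele could not be resolved by typing (e.g. a novel
allele outside the typing panel) is kept in the denominator under an explicit
`untyped` sentinel but is never reported or tested as an allele of its own;
this keeps denominators equal to 2N while the Bonferroni family contains only
reportable alleles. Alleles are canonicalized to two-field nomenclature;
higher-resolution calls are truncated with a log note.

Serostatus groups are a pure function of the two antibody tri-states:
Ro(+)La(−), Ro(+)La(+), Ro(−)La(−), Ro(−)La(+), with any missing component
making the subject unclassifiable. Ro(−)La(+) subjects are excluded from
every comparison: anti-La positivity essentially never occurs without
anti-Ro, and the three named groups are the analysis design. RA and SLE
cohorts are never pooled.

## Statistics

**Fisher exact P** is two-sided by the point-probability rule: the sum of
hypergeometric point probabilities of all tables with the observed margins
whose probability does not exceed the observed table's (a `1 + 1e-7`
relative tolerance guards floating-point ties). Degenerate margins return 1.
The implementation delegates to `scipy.stats.fisher_exact`; the test suite
checks it against an independent exact-integer enumeration of the support.

**Odds ratio**: cross-product `ad/bc`. If any cell is zero, 0.5 is added to
*all four* cells first (Haldane–Anscombe) and the result is flagged. The
correction is never applied to tables without zeros. **CI**: Woolf logit
interval with z = 1.959964. Both choices reproduce the full set of published
benchmark cells, including every zero-cell row (e.g. 1 vs 0 chromosomes →
OR (1.5·1408.5)/(361.5·0.5) = 11.69).

**Bonferroni**: `Pc = min(1, m·P)`. For an allele scan, m is the number of
distinct alleles observed in case ∪ control at that locus (alleles absent
from both groups generate no row and do not count). This rule reproduces the
published correction factors in every benchmark comparison (28 DRB1 / 15
DQB1 / 16 DPB1 in the anti-Ro RA comparison; 12 and 13 in the two SLE
comparisons). Named allele-set tests (DR2, DR4, shared epitope) are single
pre-specified dichotomies and are reported uncorrected.

**Mean comparisons** for cohort characteristics use the two-sample t test
from summary statistics or raw values. Both the unequal-variance (Welch) and
pooled (Student) statistics are exposed; the default is Welch, which matches
the published benchmark age comparison (P = 0.0002 for 59.8 ± 13.1 vs
63.9 ± 11.8 at n = 181/704; the pooled statistic gives ~5×10⁻⁵). Binary
covariates use Fisher exact on subject counts.

## Conditional (two-locus) analysis

Conditioning is at the *subject* level — carrier vs non-carrier of the
conditioning allele (≥1 copy) — while the test inside a stratum remains at
the chromosome level out of 2N stratum subjects. Same-locus conditioning is
rejected; an empty stratum yields an explicit "untestable" result rather
than an exception. Under perfect linkage disequilibrium the passenger
allele's within-stratum association collapses (verified by simulation); under
independence the conditional OR matches the marginal one.

Shared-epitope carrier status derives from the DRB1 genotype via the
configured allele list (motif-equivalently, the 70–74 residue test). A
subject with one untyped DRB1 call is an SE carrier if the typed call is SE,
otherwise indeterminate and dropped from SE-stratified analyses with a
warning. Missing secondary-SS status is treated as negative (retained) with
a log note.

## Residue fine-mapping

The allele→residue alignment uses mature-β-chain numbering (the numbering in
which the shared epitope spans DRβ 70–74). At each aligned position,
chromosome counts are collapsed by residue; every residue observed at a
polymorphic position is tested one-vs-rest, and Pc multiplies by the total
number of (position, residue) tests in the scan (per-position correction is
available as an option). Monomorphic positions generate no test. Gap
characters are a testable category by default (configurable to drop).
Collapsing is linear in counts, so a residue unique to one allele reproduces
that allele's test exactly — a property the suite asserts bit-for-bit.

The bundled map `data/residue_map_synthetic.tsv` is a **synthetic alignment
fixture**, not a transcription of any specific public release: it encodes
the three shared-epitope motifs for exactly the eight classic SE alleles
(*01:01, *04:01, *04:04, *04:05, *04:10, *10:01, *14:02, *14:06*), identical
residues for *DRB1\*08:02/\*08:03/\*08:23* at positions 13, 16 and 74, and
for *DPB1\*05:01/\*38:01* at 35, 55 and 56, with the remaining entries
chosen to be realistic (DR2 QARAA, DR3 QKRGR, DERAA on *13:01/*13:02, the
DPβ 84–87 DEAV/GGPM dimorphism). Conclusions that depend on exact residue
identities outside these pinned relationships should use a real alignment
via `ResidueMap.from_tsv`.

## Synthetic cohorts

`simulate_cohort` draws two i.i.d. three-locus haplotypes per subject from a
specified haplotype frequency spectrum — linkage disequilibrium is encoded
by placing alleles on the same haplotype — and assigns case (Ro+La−) vs
control (Ro−La−) status from a logistic model whose logit is a baseline plus
per-allele log-ORs, additive in copy number. Subjects are rejection-sampled
until the case and control quotas fill (capped, with an explicit error when
effects make one class unreachable); given a seed the cohort is
bit-reproducible. The simulator makes no attempt at population-genetic
realism (no Hardy–Weinberg testing, ancestry structure, or phasing
uncertainty) and models serostatus as a single binary label per run, so
passing calibration tests demonstrate the statistics, not the biology of
coupled antibody responses.

Calibration conditions: the parameter-recovery check uses a log(3.0)
per-copy effect on an allele riding a 5%-frequency haplotype, baseline logit
−1 (≈27% prevalence before ascertainment), 2000 cases / 2000 controls, 100
replicates. Under case-control ascertainment the chromosome-level OR is
expected slightly below e^β (≈2.96 analytically, because "other"
chromosomes in carrier subjects share the carrier's elevated risk); the
recovered median falls in [2.7, 3.3] and Woolf CI coverage of 3.0 is ≈95%.
The type-I check uses identical 8-allele spectra at n = 200/200 over 500
replicates; with per-locus Bonferroni, replicates with any Pc < 0.05 are
rare (<5%).

`build_fixture` reconstructs a cohort exactly matching per-group chromosome
counts. Genotype pairing is deterministic (greedy over the canonical-order
pool); chromosome-level scans are invariant to this arbitrary pairing, and
analyses that are *not* invariant (carrier stratification, SE exclusion) are
driven by explicitly pinned carrier counts: a pinned allele with count k and
carrier target c produces exactly k − c homozygotes and pairs every
remaining copy with a non-target allele. Carrier totals for the benchmark
fixtures are back-calculated from published stratum denominators (34/51
DRB1*08:03 and 141/405 DPB1*05:01 carriers in cases/controls; 69/196
SE-free subjects). One published stratified cell (OR 5.59 for DRB1*08:03 in
DPB1*05:01-negatives) is not exactly consistent with its own reconstructed
denominators, which give 5.55; the discrepancy is reported as-is and that
row is excluded from the exact-reproduction surface.

## Numerical and interface choices

- P display: 4 dp, switching to 3-significant-digit scientific below 1e-4;
  OR and CI at 2 dp; frequencies at 1 dp. The publication-style (``paper``)
  renderer prints Pc
  only when the uncorrected P < 0.05 (else `NS`), and the CI only alongside
  a numeric Pc; the machine style is full-precision TSV and round-trips
  losslessly (`float_precision="round_trip"` on read).
- Scan rows are ordered canonically (locus, then numeric allele fields);
  results are invariant to subject order and within-genotype allele order.
- Family size m is always attached to the result object, so alternative
  correction conventions can be applied downstream without re-testing.
- All randomness flows through a single integer seed per simulation spec.

## Problem sizes

The shipped benchmark cohorts are analyzed at full published size (925 RA,
311 SLE subjects). Simulation-based checks use 2000/2000 subjects × 100
replicates (recovery) and 200/200 × 500 (type-I), sizes at which the
Monte-Carlo error of the checked summaries is comfortably inside the
asserted bands; the entire suite runs in well under a minute on one core.
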