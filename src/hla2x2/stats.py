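"""Exact and asymptotic statistics on 2x2 contingency tables.

Conventions used throughout the pipeline:

* two-sided Fisher exact P by the point-probability rule (sum over all tables
  with the observed margins whose hypergeometric probability does not exceed
  the observed table's, with a small relative tolerance for float ties);
* odds ratio by the cross-product, with the Haldane-Anscombe correction
  (add 0.5 to every cell) applied if and only if some cell is zero;
* 95% CI by the Woolf logit interval, exp(ln OR +/- z * sqrt(sum 1/cell));
* Bonferroni correction Pc = min(1, m * P) with family size m = the number of
  alleles (or position/residue pairs) tested;
* two-sample mean comparison from summary statistics, Welch (default) or
  pooled-variance Student.

Report rounding rules are centralized here: OR at 2 dp, frequencies at 1 dp,
P at 4 dp, or scientific notation with 3 significant digits below 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats as sps

#: z quantile used for 95% Woolf intervals.
Z95 = 1.959964


@dataclass(frozen=True)
class CountTable2x2:
    """Chromosome counts: (target, other) x (case, control).

    ``a``/``b`` are target/other chromosomes among cases; ``c``/``d`` among
    controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"2x2 cells must be non-negative integers, got {self}")

    @property
    def case_total(self) -> int:
        return self.a + self.b

    @property
    def control_total(self) -> int:
        return self.c + self.d

    def swapped_rows(self) -> "CountTable2x2":
        return CountTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class TestResult:
    """One allele- or residue-level test: P, Pc, OR and Woolf 95% CI.

    ``pc`` is None when no multiplicity correction was applied (single
    pre-specified test); otherwise ``pc = min(1, m * p)``.
    ``corrected_cells`` records whether the Haldane-Anscombe zero-cell
    correction was used for the OR/CI.
    """

    p: float
    m: int
    pc: Optional[float]
    or_point: float
    ci_low: float
    ci_high: float
    corrected_cells: bool


def fisher_two_sided(t: CountTable2x2) -> float:
    """Two-sided Fisher exact P for a 2x2 table.

    Degenerate margins (an empty row or column) carry no information and
    return 1.0.
    """
    if min(t.a + t.b, t.c + t.d) == 0 or min(t.a + t.c, t.b + t.d) == 0:
        return 1.0
    _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def odds_ratio_ci(
    t: CountTable2x2, z: float = Z95
) -> tuple[float, float, float, bool]:
    """Cross-product OR with Woolf logit CI; Haldane-Anscombe on zero cells.

    Returns ``(or_point, ci_low, ci_high, corrected_cells)``. The 0.5
    continuity correction is added to *all four* cells if and only if at least
    one cell is zero; otherwise the plain cross-product is used.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return (
        or_point,
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
        corrected,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1 or int(m) != m:
        raise ValueError(f"family size m must be a positive integer, got {m}")
    return min(1.0, m * p)


def test_table(t: CountTable2x2, m: int = 1, correct: bool = True) -> TestResult:
    """Full test of one 2x2 table: Fisher P, OR + Woolf CI, optional Pc."""
    p = fisher_two_sided(t)
    or_point, lo, hi, corrected = odds_ratio_ci(t)
    pc = bonferroni(p, m) if correct else None
    return TestResult(p=p, m=m, pc=pc, or_point=or_point,
                      ci_low=lo, ci_high=hi, corrected_cells=corrected)


# ---------------------------------------------------------------------------
# two-sample mean comparison (cohort characteristics)

def compare_means(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    method: str = "welch",
) -> float:
    """Two-sided P for a two-sample t test from summary statistics.

    ``method="welch"`` (default) uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom; ``method="student"`` uses the
    pooled-variance statistic with n1 + n2 - 2 degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1 ** 2, sd2 ** 2
    if method == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (mean1 - mean2) / math.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif method == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(2.0 * sps.t.sf(abs(t), df))


def compare_means_raw(x, y, method: str = "welch") -> float:
    """Two-sided two-sample t test P from raw samples (scipy route)."""
    res = sps.ttest_ind(list(x), list(y), equal_var=(method == "student"))
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# report rounding, centralized

def fmt_p(p: float) -> str:
    """P display: 4 dp, or 3-significant-digit scientific below 1e-4."""
    if p < 1e-4:
        mant, exp = f"{p:.2e}".split("e")
        return f"{float(mant):.2f}e{int(exp):+03d}"
    return f"{p:.4f}"


def fmt_or(v: float) -> str:
    return f"{v:.2f}"


def fmt_freq(count: int, total: int) -> str:
    pct = 100.0 * count / total if total else 0.0
    return f"{count} ({pct:.1f})"


def fmt_pc(result: TestResult) -> str:
    """Paper-style Pc cell: numeric when uncorrected p < 0.05, else 'NS'."""
    if result.pc is None:
        return fmt_p(result.p)
    return fmt_p(result.pc) if result.p < 0.05 else "NS"
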