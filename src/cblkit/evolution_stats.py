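"""Tajima's relative rate test and Tajima's test of neutrality.

Both tests are implemented directly from Tajima's formulas and applied,
as in the family analysis this package supports, to amino-acid
alignments (the machinery is alphabet-agnostic; "nucleotide diversity"
is computed on residues).

Relative rate test (Tajima 1993): for three sequences A, B and C with C
as outgroup, the counts of sites where only A differs (nA) and only B
differs (nB) are equal in expectation under rate constancy; the test
statistic is chi2 = (nA - nB)^2 / (nA + nB) with one degree of freedom.
Site columns containing gaps are removed first (complete deletion).

Neutrality test (Tajima 1989): D contrasts the mean pairwise diversity
pi with the segregating-site estimate S/a1, normalized by an estimated
standard deviation built from the constants a1, a2, b1, b2, c1, c2, e1,
e2; D > 0 indicates an excess of intermediate-frequency variants
(balancing selection or population contraction), D < 0 an excess of rare
variants.  Alignment columns with less than 95% site coverage are
removed before computing pi and S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

from .core_io import GAP, AlignmentBlock

#: Minimum fraction of non-gap residues for a column to enter the
#: neutrality-test computation.
SITE_COVERAGE = 0.95

__all__ = [
    "TrioCounts",
    "RelativeRateResult",
    "TajimaDInput",
    "TajimaDResult",
    "trio_counts",
    "relative_rate_test",
    "chi2_upper_tail",
    "harmonic_numbers",
    "watterson_theta",
    "tajima_d",
    "pairwise_diversity",
    "tajima_d_from_alignment",
]


@dataclass(frozen=True)
class TrioCounts:
    """Site-pattern counts from a gap-free three-sequence alignment.

    Every retained column belongs to exactly one category: identical in
    all three, a unique difference in one sequence, or all three
    divergent.  ``shared_pair`` exists for totals reconciliation and is
    structurally zero for three sequences (any two-against-one pattern is
    a unique difference of the odd sequence).
    """

    identical: int
    unique_a: int
    unique_b: int
    unique_c: int
    divergent_all: int
    shared_pair: int = 0

    @property
    def total_sites(self) -> int:
        return (self.identical + self.unique_a + self.unique_b + self.unique_c
                + self.divergent_all + self.shared_pair)


@dataclass(frozen=True)
class RelativeRateResult:
    chi2: float
    df: int
    p: float


def trio_counts(block: AlignmentBlock) -> TrioCounts:
    """Classify every gap-free column of a three-sequence alignment."""
    if len(block) != 3:
        raise ValueError(f"relative rate test needs exactly 3 sequences, got {len(block)}")
    ident = ua = ub = uc = div = 0
    for col in range(1, block.n_columns + 1):
        a, b, c = block.column(col)
        if GAP in (a, b, c):
            continue  # complete deletion
        if a == b == c:
            ident += 1
        elif a != b and b != c and a != c:
            div += 1
        elif b == c:  # a is the odd one out
            ua += 1
        elif a == c:
            ub += 1
        else:  # a == b
            uc += 1
    return TrioCounts(identical=ident, unique_a=ua, unique_b=ub,
                      unique_c=uc, divergent_all=div)


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """Upper-tail chi-square probability; for df=1 this equals erfc(sqrt(x/2))."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    return float(_chi2_dist.sf(x, df))


def relative_rate_test(counts: TrioCounts) -> RelativeRateResult:
    """Tajima's 1-df relative rate test from unique-difference counts."""
    na, nb = counts.unique_a, counts.unique_b
    if na + nb == 0:
        raise ValueError("relative rate test undefined: no unique differences in A or B")
    stat = (na - nb) ** 2 / (na + nb)
    return RelativeRateResult(chi2=stat, df=1, p=chi2_upper_tail(stat, 1))


@dataclass(frozen=True)
class TajimaDInput:
    """(m, n, S, pi): sequences, sites, segregating sites, per-site diversity."""

    m: int
    n: int
    S: int
    pi: float

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError(f"Tajima's D needs m >= 4 sequences, got {self.m}")
        if not 0 <= self.S <= self.n:
            raise ValueError(f"S={self.S} outside 0..n={self.n}")
        if self.pi < 0:
            raise ValueError("pi must be non-negative")


@dataclass(frozen=True)
class TajimaDResult:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    ps: float
    theta_per_site: float
    k_total: float
    D: float


def harmonic_numbers(m: int) -> tuple[float, float]:
    """a1 = sum_{i<m} 1/i and a2 = sum_{i<m} 1/i^2 by direct summation."""
    if m < 2:
        raise ValueError(f"need m >= 2 sequences, got {m}")
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / (i * i) for i in range(1, m))
    return a1, a2


def watterson_theta(m: int, S: int, n: int) -> float:
    """Watterson's per-site diversity estimate Theta = (S/n)/a1."""
    if n < 1:
        raise ValueError("need at least one site")
    if S > n:
        raise ValueError(f"S={S} exceeds n={n}")
    a1, _ = harmonic_numbers(m)
    return (S / n) / a1


def tajima_d(inp: TajimaDInput) -> TajimaDResult:
    """Tajima's D with all intermediate constants, per the 1989 formulas."""
    m, n, S, pi = inp.m, inp.n, inp.S, inp.pi
    if S < 1:
        raise ValueError("Tajima's D undefined for S = 0")
    a1, a2 = harmonic_numbers(m)
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m * m + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    variance = e1 * S + e2 * S * (S - 1)
    if variance <= 0:
        raise ValueError(f"degenerate variance term {variance} for m={m}, S={S}")
    k_total = pi * n
    d = (k_total - S / a1) / math.sqrt(variance)
    return TajimaDResult(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
                         ps=S / n, theta_per_site=(S / n) / a1,
                         k_total=k_total, D=d)


def pairwise_diversity(
    block: AlignmentBlock, min_coverage: float = SITE_COVERAGE
) -> tuple[float, int, int]:
    """Per-site diversity pi, segregating sites S and retained column count.

    Columns whose non-gap fraction falls below ``min_coverage`` are
    removed.  pi is the mean over all m(m-1)/2 sequence pairs of the
    per-site mismatch fraction on retained columns where both members
    have a residue; S counts retained columns with at least two residue
    states.
    """
    m = len(block)
    retained = [
        col for col in range(1, block.n_columns + 1)
        if sum(c != GAP for c in block.column(col)) >= min_coverage * m
    ]
    if not retained:
        raise ValueError("no alignment columns pass the site-coverage filter")
    columns = [block.column(col) for col in retained]
    n_eff = len(retained)

    S = 0
    for column in columns:
        states = {c for c in column if c != GAP}
        if len(states) >= 2:
            S += 1

    total = 0.0
    n_pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            diffs = valid = 0
            for column in columns:
                ci, cj = column[i], column[j]
                if ci == GAP or cj == GAP:
                    continue
                valid += 1
                if ci != cj:
                    diffs += 1
            n_pairs += 1
            if valid:
                total += diffs / valid
    pi = total / n_pairs
    return pi, S, n_eff


def tajima_d_from_alignment(
    block: AlignmentBlock, min_coverage: float = SITE_COVERAGE
) -> TajimaDResult:
    """Convenience: coverage-filter an alignment, estimate pi and S, compute D."""
    pi, S, n_eff = pairwise_diversity(block, min_coverage)
    return tajima_d(TajimaDInput(m=len(block), n=n_eff, S=S, pi=pi))
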