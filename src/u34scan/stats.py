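"""Inferential toolkit: chi-square 2×2 association, two-sample KS, t-test and
Mann–Whitney group comparison, and the KS comparison of positional bin
profiles.

These are thin, contract-checked wrappers over scipy.stats, returning a
uniform :class:`TestResult` so every association the pipeline reports (codon
enrichment × protein fate, motif × fate, pentasequence counts between groups,
positional codon distributions) flows through one surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = feature present/absent and columns = group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p: float
    df: float | None = None
    n: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square test of association on a 2×2 table, df=1.

    The statistic is n(ad−bc)²/(r1·r2·c1·c2). No continuity correction by
    default; ``yates=True`` enables it for small tables. A zero margin makes
    the statistic undefined and raises.
    """
    if 0 in table.margins:
        raise ValueError("chi-square statistic undefined: a margin is zero")
    obs = np.array([[table.a, table.b], [table.c, table.d]])
    stat, p, df, _ = sps.chi2_contingency(obs, correction=yates)
    return TestResult("chi_square_2x2", float(stat), float(p), df=float(df), n=(table.total,))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample Kolmogorov–Smirnov test: D = sup|ECDF_x − ECDF_y|
    with the asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue), n=(x.size, y.size))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration for small samples (both n <= 20, no ties), the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann–Whitney requires non-empty samples")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), n=(x.size, y.size))


def t_test_two_sided(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample t-test (pooled variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test requires at least 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("t-test undefined: zero variance in both groups")
    res = sps.ttest_ind(x, y)
    return TestResult(
        "t_test_two_sided", float(res.statistic), float(res.pvalue),
        df=float(x.size + y.size - 2), n=(x.size, y.size),
    )


def compare_bin_profiles(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    pooled: bool = False,
) -> TestResult:
    """KS comparison of positional U34-codon distributions between two gene
    groups.

    Default: average the bin profiles within each group and run the
    two-sample KS test on the two mean-profile vectors. ``pooled=True``
    instead pools every gene's bin values per group (per-gene pooled-positions
    reading).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("bin-profile groups must be 2-D with equal bin counts")
    if pooled:
        return ks_two_sample(a.ravel(), b.ravel())
    return ks_two_sample(a.mean(axis=0), b.mean(axis=0))
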