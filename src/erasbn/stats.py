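"""Contingency-table and two-sample tests used by the selection protocol.

All tests are two-sided.  The chi-square test is Pearson's without continuity
correction; for 2x2 tables with any expected count below 5 the convention of
substituting Fisher's exact test is available via :func:`auto_count_test`.
The column-proportion "subset letters" reproduce the familiar annotated
contingency-table output: within each row, columns whose proportions do not
differ significantly (pairwise z-tests, Bonferroni-adjusted) share a letter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "pearson_chi2",
    "fisher_exact_2x2",
    "auto_count_test",
    "compare_groups_numeric",
    "column_proportion_subsets",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of nonnegative integer counts with labelled margins."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __init__(self, counts, row_labels=None, col_labels=None):
        a = np.asarray(counts)
        if a.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (a < 0).any() or not np.allclose(a, np.round(a)):
            raise ValueError("counts must be nonnegative integers")
        a = a.astype(np.int64)
        object.__setattr__(self, "counts", tuple(map(tuple, a.tolist())))
        r, c = a.shape
        object.__setattr__(
            self, "row_labels",
            tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(r)),
        )
        object.__setattr__(
            self, "col_labels",
            tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(c)),
        )
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match the matrix shape")

    def array(self) -> np.ndarray:
        return np.asarray(self.counts, np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test: statistic, df (if any), two-sided p."""

    method: str
    statistic: float
    df: int | None
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 when present")


class DegenerateTableError(ValueError):
    """Fewer than 2 informative rows or columns remain."""


def _trimmed(t: ContingencyTable) -> np.ndarray:
    a = t.array()
    a = a[a.sum(axis=1) > 0][:, a.sum(axis=0) > 0]
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise DegenerateTableError(
            "table degenerate after dropping all-zero rows/columns"
        )
    return a


def pearson_chi2(t: ContingencyTable) -> TestResult:
    """Pearson chi-square, no continuity correction, all-zero margins dropped."""
    a = _trimmed(t)
    stat, p, df, _ = sps.chi2_contingency(a, correction=False)
    return TestResult(method="pearson_chi2", statistic=float(stat), df=int(df),
                      p=float(p))


def fisher_exact_2x2(t: ContingencyTable) -> TestResult:
    """Fisher's exact test, two-sided by the point-probability method.

    The p-value sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the observed
    table (the usual statistical-package default).
    """
    a = t.array()
    if a.shape != (2, 2):
        raise ValueError("Fisher exact requires a 2x2 table")
    odds, p = sps.fisher_exact(a, alternative="two-sided")
    return TestResult(method="fisher_exact", statistic=float(odds), df=None,
                      p=float(p))


def auto_count_test(t: ContingencyTable) -> TestResult:
    """Chi-square, or Fisher's exact for a 2x2 with any expected count < 5."""
    a = _trimmed(t)
    if a.shape == (2, 2):
        expected = sps.contingency.expected_freq(a)
        if expected.min() < 5:
            return fisher_exact_2x2(ContingencyTable(a))
    stat, p, df, _ = sps.chi2_contingency(a, correction=False)
    return TestResult(method="pearson_chi2", statistic=float(stat), df=int(df),
                      p=float(p))


def compare_groups_numeric(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
    equal_var: bool = True,
) -> TestResult:
    """Two-sample location comparison.

    ``method="t"`` is the Student pooled-variance t-test (Welch via
    ``equal_var=False``); ``method="mann_whitney"`` is the U statistic with
    the tie-corrected normal approximation and continuity correction.
    """
    x = np.asarray([v for v in x if v is not None and np.isfinite(v)], float)
    y = np.asarray([v for v in y if v is not None and np.isfinite(v)], float)
    if method == "t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs >= 2 values per sample")
        if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
            # identical constant samples: no evidence of a difference
            return TestResult("t", 0.0, int(len(x) + len(y) - 2), 1.0)
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        df = len(x) + len(y) - 2 if equal_var else int(np.floor(res.df))
        return TestResult("t" if equal_var else "welch_t",
                          float(res.statistic), int(df), float(res.pvalue))
    if method == "mann_whitney":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("Mann-Whitney needs >= 1 value per sample")
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return TestResult("mann_whitney", float(res.statistic), None,
                          float(res.pvalue))
    raise ValueError(f"unknown method {method!r}")


def _two_proportion_z_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test p-value."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


def column_proportion_subsets(
    t: ContingencyTable, alpha: float = 0.05
) -> dict[str, dict[str, str]]:
    """Subset letters per (row, column), as in annotated contingency tables.

    For each row, every pair of columns is compared with a pooled
    two-proportion z-test on that row's share of the column total, with a
    Bonferroni adjustment over the column pairs.  Columns that are not
    significantly different share a letter; the letters of a row are the
    maximal cliques of the "not different" relation.

    Returns ``{row_label: {col_label: letters}}`` with letters like ``"a"``,
    ``"ab"``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    a = t.array()
    n_cols = a.shape[1]
    totals = a.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero column total")
    n_pairs = max(1, n_cols * (n_cols - 1) // 2)
    out: dict[str, dict[str, str]] = {}
    letters = "abcdefghijklmnopqrstuvwxyz"
    for ri, rlab in enumerate(t.row_labels):
        differ = np.zeros((n_cols, n_cols), bool)
        for i, j in itertools.combinations(range(n_cols), 2):
            p = _two_proportion_z_p(a[ri, i], totals[i], a[ri, j], totals[j])
            if p * n_pairs < alpha:
                differ[i, j] = differ[j, i] = True
        # maximal cliques of the complement ("no significant difference") graph
        cliques: list[set[int]] = []
        for i in range(n_cols):
            placed = False
            for cl in cliques:
                if all(not differ[i, j] for j in cl):
                    cl.add(i)
                    placed = True
            if not placed:
                cliques.append({i})
        row_letters = {c: "" for c in range(n_cols)}
        for li, cl in enumerate(cliques):
            for c in sorted(cl):
                row_letters[c] += letters[li]
        out[rlab] = {t.col_labels[c]: row_letters[c] for c in range(n_cols)}
    return out
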