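"""Statistical comparisons with explicit, reproducible contracts.

Thin wrappers over scipy.stats that pin down the conventions the analyses
rely on: Pearson chi-square without continuity correction, a two-sample
binned chi-square with expected-count-driven bin merging, two-sided
Mann-Whitney U (exact for small untied samples, tie-corrected normal
approximation otherwise), paired Wilcoxon signed-rank with zero differences
dropped, and Bonferroni adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "chi2_contingency",
    "chi2_binned",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "bonferroni",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome with the sample sizes that produced it."""

    statistic_name: str
    statistic_value: float
    p_value: float
    df: Optional[int] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")

    def with_correction(self, m: int) -> "TestResult":
        """Bonferroni-adjusted copy of this result (family size m)."""
        return TestResult(
            statistic_name=self.statistic_name,
            statistic_value=self.statistic_value,
            p_value=min(1.0, self.p_value * m),
            df=self.df,
            n1=self.n1,
            n2=self.n2,
            correction="bonferroni",
            extra={**self.extra, "uncorrected_p": self.p_value, "family_size": m},
        )


def chi2_contingency(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on an r x c contingency table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError(f"need an r x c table with r,c >= 2, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative cell counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic_name="chi2",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(res.dof),
        n1=int(arr[0].sum()),
        n2=int(arr[1].sum()) if arr.shape[0] > 1 else None,
    )


def chi2_binned(
    lengths_a: Sequence[float],
    lengths_b: Sequence[float],
    bin_width: float = 3.0,
    min_expected: float = 5.0,
) -> TestResult:
    """Two-sample chi-square on shared histograms of the two length samples.

    Both samples are binned on a common grid of ``bin_width``; adjacent bins
    are merged right-to-left until every expected cell reaches
    ``min_expected``; the resulting 2 x k table is tested with df = k - 1.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = math.floor(min(a.min(), b.min()) / bin_width) * bin_width
    hi = math.ceil((max(a.max(), b.max()) + 1e-9) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.asarray([lo, lo + bin_width])
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    cols = [np.array([x, y], dtype=float) for x, y in zip(ca, cb)]

    def expected_ok(columns: list) -> bool:
        tab = np.stack(columns, axis=1)
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        return bool((exp >= min_expected).all())

    # merge right-to-left: fold the rightmost offending column into its left
    # neighbour until all expected counts clear the threshold
    while len(cols) > 1 and not expected_ok(cols):
        tab = np.stack(cols, axis=1)
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        offending = np.nonzero((exp < min_expected).any(axis=0))[0]
        j = int(offending[-1])
        if j == 0:
            cols[1] = cols[0] + cols[1]
            del cols[0]
        else:
            cols[j - 1] = cols[j - 1] + cols[j]
            del cols[j]
    if len(cols) < 2:
        raise ValueError("insufficient spread: fewer than 2 bins after merging")
    table = np.stack(cols, axis=1)
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(
        statistic_name="chi2_binned",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(res.dof),
        n1=int(a.size),
        n2=int(b.size),
        extra={"bin_width": bin_width, "min_expected": min_expected,
               "n_bins": len(cols)},
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported U is the statistic of the first sample (scipy convention:
    number of (a, b) pairs with a > b, ties counted half), so two identical
    samples give U = n1*n2/2 and a stochastically smaller first sample gives
    U near 0.  The p-value is exact for small samples without ties and a
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(
        statistic_name="mann_whitney_U",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
    )


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (and logged) before ranking.  The p-value
    is exact for small samples without ties, otherwise a normal
    approximation; the normal Z score is reported alongside.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("paired samples must be non-empty and of equal length")
    d = a - b
    n_zero = int((d == 0).sum())
    if n_zero == a.size:
        raise ValueError("degenerate pairing: all differences are zero")
    if n_zero:
        logger.info("wilcoxon: dropped %d zero differences", n_zero)
    res = sps.wilcoxon(a, b, zero_method="wilcox", correction=False,
                       alternative="two-sided", method="auto")
    nz = d[d != 0]
    n = nz.size
    # normal-approximation Z for the signed-rank sum, reported for reference
    mean_t = n * (n + 1) / 4.0
    ranks = sps.rankdata(np.abs(nz))
    var_t = n * (n + 1) * (2 * n + 1) / 24.0
    ties = np.unique(ranks, return_counts=True)[1]
    var_t -= (ties**3 - ties).sum() / 48.0
    z = 0.0 if var_t == 0 else (float(res.statistic) - mean_t) / math.sqrt(var_t)
    return TestResult(
        statistic_name="wilcoxon_T",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        n1=n,
        extra={"z": z, "n_zero_dropped": n_zero},
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return [float(x) for x in np.minimum(1.0, p * m)]
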