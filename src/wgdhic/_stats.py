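"""Shared statistical result container and small wrappers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError


@dataclass
class TestResult:
    """Two-group comparison summary (Mann-Whitney U unless stated)."""

    statistic: float
    pvalue: float
    n1: int
    n2: int
    median1: float
    median2: float
    group1: str
    group2: str
    test: str = "mann-whitney-u"

    @property
    def direction(self) -> str:
        if self.median1 > self.median2:
            return f"{self.group1}>{self.group2}"
        if self.median1 < self.median2:
            return f"{self.group1}<{self.group2}"
        return f"{self.group1}=={self.group2}"

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "pvalue": float(self.pvalue),
            "n1": self.n1,
            "n2": self.n2,
            "median1": float(self.median1),
            "median2": float(self.median2),
            "group1": self.group1,
            "group2": self.group2,
            "direction": self.direction,
        }


def mann_whitney(x, y, group1: str = "group1", group2: str = "group2",
                 min_n: int = 3) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < min_n or len(y) < min_n:
        raise DataError(
            f"Mann-Whitney groups too small: {group1} n={len(x)}, {group2} n={len(y)}"
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n1=len(x),
        n2=len(y),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        group1=group1,
        group2=group2,
    )


def benjamini_hochberg(pvalues, alpha: float = 0.05) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]
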