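"""Test-retest stability statistics for two-occasion designs.

Used both for the two-week retest study (practice effects, reliability)
and for paired comparisons of testing environments.  Provides the paired
t-test with the paired-design Cohen's d (mean difference over SD of the
differences, identically t/sqrt(n)) and the intraclass correlation.  The
default ICC form is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the standard choice for test-retest
agreement; ICC(3,1) (consistency) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .screening import DegenerateDataError

__all__ = ["PairedSummary", "paired_summary", "paired_d_from_t", "icc", "pairs_from_table"]


@dataclass(frozen=True)
class PairedSummary:
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    mean_diff: float
    t: float
    p: float
    cohens_d: float
    n: int
    degenerate: bool = False  # zero difference variance with non-zero shift


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like of (t1, t2) values")
    # listwise exclusion of pairs with a missing occasion
    keep = ~np.isnan(arr).any(axis=1)
    return arr[keep, 0], arr[keep, 1]


def paired_summary(pairs: Sequence[Sequence[float]]) -> PairedSummary:
    """Paired t-test and paired-design effect size for (t1, t2) pairs.

    ``mean_diff`` is occasion 1 minus occasion 2; ``t = mean_diff /
    (sd_diff / sqrt(n))`` with n-1 df and ``cohens_d = mean_diff /
    sd_diff = t / sqrt(n)``.  A constant non-zero shift has no difference
    variance: the summary is returned with infinite t/d and flagged
    ``degenerate``; a zero shift with zero variance raises.
    """
    t1, t2 = _as_pairs(pairs)
    n = len(t1)
    if n < 2:
        raise ValueError("paired summary requires n >= 2 complete pairs")
    diff = t1 - t2
    sd_diff = diff.std(ddof=1)
    mean_diff = float(diff.mean())
    if sd_diff == 0:
        if mean_diff == 0:
            raise DegenerateDataError("all pairs identical: zero difference variance")
        inf = math.inf if mean_diff > 0 else -math.inf
        return PairedSummary(
            mean1=float(t1.mean()), sd1=float(t1.std(ddof=1)),
            mean2=float(t2.mean()), sd2=float(t2.std(ddof=1)),
            mean_diff=mean_diff, t=inf, p=0.0, cohens_d=inf, n=n, degenerate=True,
        )
    t_stat, p = stats.ttest_rel(t1, t2)
    return PairedSummary(
        mean1=float(t1.mean()), sd1=float(t1.std(ddof=1)),
        mean2=float(t2.mean()), sd2=float(t2.std(ddof=1)),
        mean_diff=mean_diff, t=float(t_stat), p=float(p),
        cohens_d=mean_diff / float(sd_diff), n=n,
    )


def paired_d_from_t(t: float, n: int) -> float:
    """Paired Cohen's d recovered from a reported t and n: d = t/sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return t / math.sqrt(n)


def icc(
    pairs: Sequence[Sequence[float]],
    form: Literal["2,1", "3,1"] = "2,1",
) -> float:
    """Intraclass correlation for a two-occasion design.

    ICC(2,1), the default, treats occasions as a random effect and
    measures absolute agreement of single measurements:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    ICC(3,1) treats occasions as fixed (consistency):

        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    with MSR/MSC/MSE the subject, occasion and residual mean squares of
    the two-way layout (k = 2 occasions, n subjects).
    """
    t1, t2 = _as_pairs(pairs)
    n = len(t1)
    if n < 3:
        raise ValueError("ICC requires n >= 3 complete pairs")
    data = np.column_stack([t1, t2])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise DegenerateDataError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if form == "2,1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "3,1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be '2,1' or '3,1'")
    if denom == 0:
        raise DegenerateDataError("zero denominator in ICC")
    return float((msr - mse) / denom)


def pairs_from_table(df, col1: str = "t1", col2: str = "t2") -> np.ndarray:
    """Extract an (n, 2) pair array from a DataFrame of paired measurements."""
    return np.column_stack([np.asarray(df[col1], float), np.asarray(df[col2], float)])
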