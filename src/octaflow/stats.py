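"""Statistical procedures for the group comparisons and correlation grid.

Two-group t tests (pooled and Welch, from raw data or from published
summary statistics), Pearson's chi-squared for 2x2 tables, the paired t
test, Pearson correlation, partial correlation by least-squares
residualization, and coefficient-of-variation repeatability summaries.
All p-values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "PartialCorrelationResult",
    "CollinearityError",
    "t_test_from_summaries",
    "t_test_raw",
    "chi2_2x2",
    "paired_t",
    "pearson_correlation",
    "partial_correlation",
    "coefficient_of_variation",
    "cv_summary",
]


class TestMethod(str, Enum):
    POOLED_T = "pooled_t"
    WELCH_T = "welch_t"
    CHI2_PEARSON = "chi2_pearson"
    PAIRED_T = "paired_t"


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD triple, as printed in a demographics table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_data(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: TestMethod
    mean_difference: float | None = None


@dataclass(frozen=True)
class PartialCorrelationResult:
    coefficient: float
    p_value: float
    n: int
    k: int  # number of covariates controlled for


class CollinearityError(ValueError):
    """Covariate matrix is rank-deficient; carries the offending columns."""

    def __init__(self, columns: list[int]):
        self.columns = columns
        super().__init__(f"collinear covariate column(s): {columns}")


def _choose_variant_from_summaries(a: GroupSummary, b: GroupSummary, alpha=0.05) -> str:
    """Variance-ratio (F) proxy for Levene when only summaries are known."""
    if a.sd == 0 or b.sd == 0:
        return "pooled" if a.sd == b.sd else "welch"
    f = (a.sd / b.sd) ** 2
    dfn, dfd = a.n - 1, b.n - 1
    if f < 1:
        f, dfn, dfd = 1 / f, dfd, dfn
    p = 2 * sps.f.sf(f, dfn, dfd)
    return "welch" if min(p, 1.0) < alpha else "pooled"


def t_test_from_summaries(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> TestResult:
    """Independent two-sample t test from printed group summaries.

    ``variant`` is ``"pooled"`` (equal-variance, df = n_a + n_b - 2),
    ``"welch"`` (Welch–Satterthwaite df), or ``"auto"`` which chooses by an
    F test on the variance ratio at alpha = 0.05 (the summary-statistics
    proxy for Levene's test).
    """
    if variant == "auto":
        variant = _choose_variant_from_summaries(a, b)
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        method = TestMethod.POOLED_T if variant == "pooled" else TestMethod.WELCH_T
        return TestResult(0.0, a.n + b.n - 2, 1.0, method, 0.0)
    stat, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = a.n + b.n - 2
        method = TestMethod.POOLED_T
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = TestMethod.WELCH_T
    return TestResult(float(stat), float(df), float(p), method, a.mean - b.mean)


def t_test_raw(x: np.ndarray, y: np.ndarray, variant: str = "pooled") -> TestResult:
    """Independent two-sample t test on raw vectors.

    ``variant="auto"`` runs Levene's test (mean-centered, as in SPSS) at
    alpha = 0.05 to pick pooled vs Welch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if variant == "auto":
        _, p_lev = sps.levene(x, y, center="mean")
        variant = "welch" if p_lev < 0.05 else "pooled"
    return t_test_from_summaries(
        GroupSummary.from_data(x), GroupSummary.from_data(y), variant
    )


def chi2_2x2(table: np.ndarray) -> TestResult:
    """Pearson's chi-squared test on a 2x2 table, without continuity
    correction (df = 1)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("all row and column marginals must be positive")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, 1.0, p, TestMethod.CHI2_PEARSON)


def paired_t(before: np.ndarray, after: np.ndarray) -> TestResult:
    """Paired t test: one-sample t on the within-pair differences."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or len(before) < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = after - before
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    n = len(d)
    if sd == 0:
        # all differences identical: p = 1 for zero shift, else p -> 0
        p = 1.0 if md == 0 else 0.0
        stat = 0.0 if md == 0 else np.inf * np.sign(md)
        return TestResult(float(stat), n - 1, p, TestMethod.PAIRED_T, md)
    stat = md / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(stat), df=n - 1))
    return TestResult(float(stat), n - 1, p, TestMethod.PAIRED_T, md)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> PartialCorrelationResult:
    """Product-moment correlation with a t-based two-tailed p (df = n-2)."""
    return partial_correlation(x, y, covariates=None)


def _check_rank(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # greedily identify columns that do not increase the rank
        bad, cols = [], []
        for j in range(design.shape[1]):
            trial = design[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(j - 1)  # index among covariates (0 = intercept col 1)
            else:
                cols.append(j)
        raise CollinearityError(bad)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> PartialCorrelationResult:
    """Correlation between x and y after removing a linear covariate effect.

    Both variables are residualized on [intercept | covariates] by least
    squares; the coefficient is the Pearson correlation of the residuals and
    the p-value comes from t = r*sqrt((n-2-k)/(1-r^2)) with df = n - 2 - k.
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (got n={n}, k={k})")
    design = np.column_stack([np.ones(n), z])
    _check_rank(design)
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(t), df=df))
    return PartialCorrelationResult(coefficient=r, p_value=p, n=n, k=k)


def coefficient_of_variation(replicates: np.ndarray) -> float:
    """Per-eye repeatability: CV% = 100 * sample SD / mean of replicates."""
    x = np.asarray(replicates, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 replicate measurements")
    m = float(np.mean(x))
    if m == 0:
        raise ValueError("CV undefined for zero-mean replicates")
    return 100.0 * float(np.std(x, ddof=1)) / m


def cv_summary(per_eye_cvs: np.ndarray) -> tuple[float, float]:
    """Mean and SD of per-eye CVs, the repeatability summary of a device
    validation set."""
    cvs = np.asarray(per_eye_cvs, dtype=float)
    return float(np.mean(cvs)), float(np.std(cvs, ddof=1))
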