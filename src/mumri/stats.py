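"""Cohort statistics over motor unit metric tables.

Operations: Shapiro-Wilk normality, one-way ANOVA across muscles, unpaired
two-tailed t-test between age bands (<40 vs >=40 years by default),
inter-observer agreement (two-way mixed absolute-agreement ICC and
Bland-Altman bias / coefficient of repeatability), and Pearson correlation.

A metric table is an ordinary DataFrame with one row per (unit, observer,
scan): columns such as ``subject``, ``unit``, ``observer``, ``scan``,
``age``, ``sex``, ``muscle`` plus metric columns (``csa_mm2`` ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConsistencyError, DegenerateInputError

KEY_COLUMNS = ("subject", "unit", "observer", "scan")


class NormalityResult(NamedTuple):
    statistic: float  # Shapiro-Wilk W
    p_value: float


@dataclass
class GroupComparison:
    test: str  # "anova" or "t-test"
    statistic: float
    df: tuple[float, ...]
    p_value: float


@dataclass
class AgreementStats:
    """Inter-observer agreement for one metric.

    ``icc`` is the two-way mixed-effects, absolute-agreement intraclass
    correlation (single measures by default); ``bias`` the mean paired
    difference (observer B - observer A); ``coefficient_of_repeatability``
    1.96 x SD of the paired differences.
    """

    icc: float
    bias: float
    coefficient_of_repeatability: float


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float


def validate_metric_table(table: pd.DataFrame) -> None:
    """Reject duplicate (subject, unit, observer, scan) keys."""
    keys = [k for k in KEY_COLUMNS if k in table.columns]
    if keys and table.duplicated(subset=keys).any():
        raise ConsistencyError(f"duplicate {keys} keys in metric table")


def normality_test(values) -> NormalityResult:
    """Shapiro-Wilk test of normality; undefined for constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("normality undefined for constant input")
    w, p = sps.shapiro(x)
    return NormalityResult(float(w), float(p))


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    grouping: str = "muscle",
    age_cut: float = 40.0,
) -> GroupComparison:
    """Compare a metric between muscles (one-way ANOVA) or between age
    bands below / at-or-above ``age_cut`` years (unpaired two-tailed
    Student's t-test).
    """
    if grouping == "muscle":
        groups = [g[metric].to_numpy(float) for _, g in table.groupby("muscle")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
        f, p = sps.f_oneway(*groups)
        k, n = len(groups), sum(len(g) for g in groups)
        return GroupComparison("anova", float(f), (k - 1, n - k), float(p))
    if grouping == "age":
        young = table.loc[table["age"] < age_cut, metric].to_numpy(float)
        old = table.loc[table["age"] >= age_cut, metric].to_numpy(float)
        if len(young) < 2 or len(old) < 2:
            raise ValueError("t-test needs >= 2 values per age band")
        t, p = sps.ttest_ind(young, old, equal_var=True)
        return GroupComparison("t-test", float(t), (len(young) + len(old) - 2,), float(p))
    raise ValueError(f"unknown grouping {grouping!r} (use 'muscle' or 'age')")


def icc_absolute_agreement(ratings: np.ndarray, measures: str = "single") -> float:
    """Two-way (mixed-effects) absolute-agreement ICC from mean squares.

    ``ratings`` is (n subjects, k raters).  With row (subject) mean square
    MSR, column (rater) mean square MSC and residual mean square MSE::

        single:  (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        average: (MSR - MSE) / (MSR + (MSC - MSE) / n)
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3 or y.shape[1] < 2:
        raise ValueError("ICC needs >= 3 subjects and >= 2 raters")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    if measures == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif measures == "average":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError("measures must be 'single' or 'average'")
    if denom <= 0:
        raise DegenerateInputError("ICC undefined: no between-subject variance")
    return float((msr - mse) / denom)


def agreement(observer_a, observer_b, measures: str = "single") -> AgreementStats:
    """Inter-observer agreement: ICC plus Bland-Altman bias and coefficient
    of repeatability (1.96 x SD of the paired differences).
    """
    a = np.asarray(observer_a, dtype=float)
    b = np.asarray(observer_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("agreement needs >= 3 complete pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("agreement needs complete (non-missing) pairs")
    icc = icc_absolute_agreement(np.column_stack([a, b]), measures)
    diff = b - a
    bias = float(diff.mean())
    cr = float(1.96 * diff.std(ddof=1))
    return AgreementStats(icc, bias, cr)


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlation needs finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(r * r), float(p))


def bland_altman_plot(observer_a, observer_b, path, metric_name: str = "metric") -> None:
    """Bland-Altman plot (paired differences vs pair means) saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(observer_a, float)
    b = np.asarray(observer_b, float)
    res = agreement(a, b)
    mean = (a + b) / 2
    diff = b - a
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18)
    ax.axhline(res.bias, color="k", lw=1, label=f"bias {res.bias:.2f}")
    for lim in (res.bias - res.coefficient_of_repeatability, res.bias + res.coefficient_of_repeatability):
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel(f"pair mean ({metric_name})")
    ax.set_ylabel("difference (B - A)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
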