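"""Population-level statistics: group comparisons, inverse regression,
outlier flagging, and the mix-norm versus Reynolds-number relationship.

Group differences use two-tailed Mann-Whitney U tests (exact
permutation distribution for small untied samples, tie-corrected
normal approximation otherwise) at a critical p of 0.05, mirroring the
study's analysis; no multiple-testing correction is applied (none was
in the original analysis; noted in the report metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
AGE_CUT = 65.0


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    labels: tuple
    n: tuple
    mean: tuple
    sd: tuple
    median: tuple
    iqr: tuple
    u_statistic: float
    p_value: float
    significant: bool
    method: str
    outliers: tuple = ((), ())
    quartile_method: str = "median-exclusive"


@dataclass
class InverseFit:
    """No-intercept least squares of U = a/D."""

    a: float
    r_squared: float
    residuals: np.ndarray = field(repr=False)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def mann_whitney(x, y, labels=("x", "y")) -> GroupComparison:
    """Two-tailed Mann-Whitney U comparison of two samples.

    Exact permutation p-value when min(n) <= 8 and there are no ties;
    tie-corrected normal approximation otherwise.  Identical samples
    (zero rank variance) return p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        res_u = sps.mannwhitneyu(x, y, method="asymptotic").statistic
        u, p, method = float(res_u), 1.0, "degenerate"
    elif min(x.size, y.size) <= 8 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u, p, method = float(res.statistic), float(res.pvalue), "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
    p = min(p, 1.0)
    return GroupComparison(
        labels=tuple(labels),
        n=(x.size, y.size),
        mean=(float(x.mean()), float(y.mean())),
        sd=(float(x.std(ddof=1)) if x.size > 1 else 0.0,
            float(y.std(ddof=1)) if y.size > 1 else 0.0),
        median=(float(np.median(x)), float(np.median(y))),
        iqr=(_iqr(x), _iqr(y)),
        u_statistic=u,
        p_value=p,
        significant=p < ALPHA,
        method=method,
        outliers=(tuple(flag_outliers(x)) if x.size >= 4 else (),
                  tuple(flag_outliers(y)) if y.size >= 4 else ()),
    )


def _quartiles(sample: np.ndarray) -> tuple[float, float]:
    """Median-exclusive (Tukey hinge) quartiles."""
    s = np.sort(np.asarray(sample, dtype=float))
    n = s.size
    half = n // 2
    return float(np.median(s[:half])), float(np.median(s[-half:]))


def _iqr(sample) -> float:
    sample = np.asarray(sample)
    if sample.size < 4:
        return float("nan")
    q1, q3 = _quartiles(sample)
    return q3 - q1


def flag_outliers(sample, rule: str = "iqr") -> np.ndarray:
    """Indices of outlying values.

    rule="iqr" flags values strictly outside [Q1, Q3] (the literal
    interquartile-range rule used in the study); rule="tukey" uses the
    conventional 1.5 x IQR fences.  Quartiles are median-exclusive.
    """
    s = np.asarray(sample, dtype=float)
    if s.size < 4:
        raise StatsError("need at least 4 values to flag outliers")
    q1, q3 = _quartiles(s)
    if rule == "iqr":
        lo, hi = q1, q3
    elif rule == "tukey":
        k = 1.5 * (q3 - q1)
        lo, hi = q1 - k, q3 + k
    else:
        raise StatsError("rule must be 'iqr' or 'tukey'")
    return np.where((s < lo) | (s > hi))[0]


def fit_inverse(diameters, velocities) -> InverseFit:
    """Least-squares coefficient of U = a/D (no intercept).

    a = sum(U/D) / sum(1/D^2); R^2 is computed against the mean-of-U
    baseline and may be negative when the inverse model fits worse
    than a constant.
    """
    d = np.asarray(diameters, dtype=float)
    u = np.asarray(velocities, dtype=float)
    if d.size != u.size or d.size < 2:
        raise StatsError("need n >= 2 paired samples")
    if (d <= 0).any():
        raise StatsError("all diameters must be positive")
    inv = 1.0 / d
    a = float(np.sum(u * inv) / np.sum(inv**2))
    resid = u - a * inv
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return InverseFit(a=a, r_squared=r2, residuals=resid)


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y = slope*x + intercept with standard R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise StatsError("need n >= 2 paired samples")
    if np.allclose(x, x[0]):
        raise StatsError("degenerate regressor (no variance in x)")
    res = sps.linregress(x, y)
    if np.allclose(y, y[0]):
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue**2))


def split_groups(subjects) -> dict:
    """Sex and age subgroup assignments (age >= 65 is the older group).

    ``subjects`` is an iterable with .sex, .age, .id attributes or a
    DataFrame with those columns; subjects missing age are excluded
    with a warning entry.
    """
    import pandas as pd

    if isinstance(subjects, pd.DataFrame):
        rows = subjects.to_dict("records")
    else:
        rows = [dict(id=s.id, sex=s.sex, age=s.age) for s in subjects]
    out = {"male": [], "female": [], "young": [], "older": [], "missing_age": []}
    for r in rows:
        (out["male"] if str(r["sex"]).upper().startswith("M") else out["female"]).append(r["id"])
        age = r.get("age")
        if age is None or (isinstance(age, float) and np.isnan(age)):
            out["missing_age"].append(r["id"])
        elif age >= AGE_CUT:
            out["older"].append(r["id"])
        else:
            out["young"].append(r["id"])
    return out
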