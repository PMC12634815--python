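"""Population statistics: Mann-Whitney U (with an enumeration oracle),
the inverse regression U = a/D, outlier flagging and group splits."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from aqflow.stats import (
    StatsError,
    fit_inverse,
    flag_outliers,
    linear_fit,
    mann_whitney,
    split_groups,
)


def _exact_p_oracle(x, y):
    """Two-tailed exact p by exhaustive enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    stats = []
    for comb in combinations(range(len(pooled)), n):
        stats.append(ranks[list(comb)].sum())
    stats = np.array(stats)
    return np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)


def test_mann_whitney_small_sample_example():
    res = mann_whitney([1, 2], [3, 4])
    assert res.u_statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3, rel=1e-12)
    assert res.method == "exact"
    assert not res.significant


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(5):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(_exact_p_oracle(x, y), abs=1e-12)


def test_mann_whitney_symmetry_and_identity():
    rng = np.random.default_rng(2)
    x = rng.normal(size=12)
    y = rng.normal(size=15)
    assert mann_whitney(x, y).p_value == pytest.approx(
        mann_whitney(y, x).p_value, rel=1e-12
    )
    same = np.full(10, 3.3)
    res = mann_whitney(same, same)
    assert res.p_value == 1.0


def test_exact_vs_asymptotic_agreement():
    """Normal approximation within 0.03 of the exact p for small samples."""
    rng = np.random.default_rng(9)
    for _ in range(10):
        x = rng.normal(size=7)
        y = rng.normal(size=8)
        exact = mann_whitney(x, y).p_value  # exact path (untied, small)
        approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert abs(exact - approx) < 0.03


def test_mann_whitney_empty_raises():
    with pytest.raises(StatsError):
        mann_whitney([], [1.0])


def test_fit_inverse_exact_recovery():
    d = np.linspace(1.5, 4.5, 20)
    fit = fit_inverse(d, 26.4 / d)
    assert fit.a == pytest.approx(26.4, rel=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_inverse_scaling_homogeneity():
    rng = np.random.default_rng(1)
    d = rng.uniform(2, 4, 30)
    u = 26.4 / d + rng.normal(0, 2, 30)
    a1 = fit_inverse(d, u).a
    a2 = fit_inverse(d, 3.0 * u).a
    assert a2 == pytest.approx(3.0 * a1, rel=1e-12)


def test_fit_inverse_constant_velocity_poor_fit():
    """A forced inverse fit to constant U does worse than the mean."""
    d = np.linspace(1.0, 5.0, 25)
    fit = fit_inverse(d, np.full(25, 10.0))
    assert fit.r_squared <= 0.0


def test_fit_inverse_errors():
    with pytest.raises(StatsError):
        fit_inverse([2.0], [10.0])
    with pytest.raises(StatsError):
        fit_inverse([2.0, -1.0], [10.0, 12.0])


def test_flag_outliers_literal_iqr_rule():
    """{1,2,3,4}: hinges 1.5 and 3.5, so 1 and 4 fall outside [Q1,Q3]."""
    idx = flag_outliers([1, 2, 3, 4])
    assert set(idx) == {0, 3}


def test_flag_outliers_constant_sample():
    assert flag_outliers([5.0] * 6).size == 0


def test_flag_outliers_permutation_invariance():
    rng = np.random.default_rng(4)
    x = rng.normal(size=25)
    perm = rng.permutation(25)
    flagged = set(x[flag_outliers(x)])
    flagged_perm = set(x[perm][flag_outliers(x[perm])])
    assert flagged == flagged_perm


def test_flag_outliers_tukey_rule_wider():
    x = [1, 2, 3, 4]
    assert flag_outliers(x, rule="tukey").size == 0
    y = [1, 2, 3, 4, 5, 6, 7, 8, 100]
    assert list(flag_outliers(y, rule="tukey")) == [8]


def test_split_groups_age_boundary():
    class S:
        def __init__(self, id, sex, age):
            self.id, self.sex, self.age = id, sex, age

    groups = split_groups([S("a", "M", 64.0), S("b", "F", 65.0), S("c", "F", 30.0)])
    assert groups["young"] == ["a", "c"]
    assert groups["older"] == ["b"]
    assert groups["male"] == ["a"]
    assert set(groups["young"] + groups["older"]) == {"a", "b", "c"}


def test_split_groups_single_sex():
    class S:
        def __init__(self, id):
            self.id, self.sex, self.age = id, "M", 40.0

    groups = split_groups([S("a"), S("b")])
    assert groups["female"] == []


def test_linear_fit_exact_recovery():
    x = np.linspace(5, 90, 30)
    fit = linear_fit(x, 0.006 * x + 0.208)
    assert fit.slope == pytest.approx(0.006, rel=1e-10)
    assert fit.intercept == pytest.approx(0.208, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_linear_fit_constant_response():
    fit = linear_fit([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
    assert fit.slope == 0.0
    assert fit.r_squared == 0.0


def test_linear_fit_order_invariance():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 100, 40)
    y = 0.006 * x + rng.normal(0, 0.05, 40)
    f1 = linear_fit(x, y)
    perm = rng.permutation(40)
    f2 = linear_fit(x[perm], y[perm])
    assert f1.slope == pytest.approx(f2.slope, rel=1e-12)


def test_linear_fit_degenerate_regressor():
    with pytest.raises(StatsError):
        linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
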