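"""DCMS combination: rank p-values, robust correlation, calibration, FDR."""

import numpy as np
import pytest

from dcmscan.dcms import (bh_adjust, calibrate_dcms, dcms,
                          robust_correlation_mcd, stat_to_pvalue)


# ------------------------------------------------- fractional-rank p-values

def test_right_tail_worked_example():
    # values 3 > 2 > 1: the largest has p = 1/4, the smallest 3/4
    p = stat_to_pvalue([3.0, 1.0, 2.0], "right")
    assert np.allclose(p, [1 / 4, 3 / 4, 2 / 4])


def test_left_tail_worked_example():
    p = stat_to_pvalue([3.0, 1.0, 2.0], "left")
    assert np.allclose(p, [3 / 4, 1 / 4, 2 / 4])


def test_left_and_right_tails_sum_to_one_for_distinct_values(rng):
    v = rng.normal(size=50)
    pl = stat_to_pvalue(v, "left")
    pr = stat_to_pvalue(v, "right")
    assert np.allclose(pl + pr, 1.0, atol=1e-15)


def test_tied_values_share_a_p_value():
    p = stat_to_pvalue([5.0, 5.0, 1.0], "right")
    assert p[0] == p[1] == pytest.approx(2 / 4)
    assert p[2] == pytest.approx(3 / 4)


def test_all_identical_values_warn_and_give_n_over_n_plus_one():
    with pytest.warns(UserWarning, match="identical"):
        p = stat_to_pvalue([2.0, 2.0, 2.0], "right")
    assert np.allclose(p, 3 / 4)


def test_pvalues_always_strictly_inside_unit_interval(rng):
    for tail in ("left", "right"):
        p = stat_to_pvalue(rng.normal(size=200), tail)
        assert (p > 0).all() and (p < 1).all()


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        stat_to_pvalue([1.0], "right")
    with pytest.raises(ValueError):
        stat_to_pvalue([1.0, np.nan], "right")
    with pytest.raises(ValueError):
        stat_to_pvalue([1.0, 2.0], "both")


# ----------------------------------------------------------- DCMS score ---

def test_single_statistic_reduces_to_logit():
    p = np.array([0.1, 0.5, 0.9])
    got = dcms(p[:, None], np.ones((1, 1)))
    assert np.array_equal(got, np.log10((1 - p) / p))


def test_identity_correlation_gives_plain_sum(rng):
    p = rng.uniform(0.01, 0.99, size=(30, 4))
    got = dcms(p, np.eye(4))
    want = np.log10((1 - p) / p).sum(axis=1)
    assert np.allclose(got, want, atol=1e-12)


def test_duplicated_statistic_counts_once():
    # a statistic entered twice with correlation 1 gets weight 2 on each
    # copy, so the pair contributes exactly one logit
    p = np.array([0.2, 0.6])
    single = dcms(p[:, None], np.ones((1, 1)))
    doubled = dcms(np.column_stack([p, p]), np.ones((2, 2)))
    assert np.array_equal(single, doubled)


def test_pvalues_on_boundary_rejected():
    with pytest.raises(ValueError):
        dcms(np.array([[0.0], [0.5]]), np.ones((1, 1)))
    with pytest.raises(ValueError):
        dcms(np.array([[1.0], [0.5]]), np.ones((1, 1)))


def test_dcms_is_permutation_equivariant(rng):
    p = rng.uniform(0.01, 0.99, size=(40, 3))
    r = np.eye(3) * 0.5 + 0.5
    perm = rng.permutation(40)
    assert np.array_equal(dcms(p, r)[perm], dcms(p[perm], r))


# --------------------------------------------------- MCD robust correlation

def _contaminated_sample(rng, n=500, frac=0.05, r_true=0.5, r_out=-0.9):
    cov = np.array([[1.0, r_true], [r_true, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=n)
    k = int(frac * n)
    out_cov = np.array([[1.0, r_out], [r_out, 1.0]])
    X[:k] = 3.0 * rng.multivariate_normal([0, 0], out_cov, size=k)
    return X


def test_alpha_one_equals_classical_correlation(rng):
    X = rng.normal(size=(200, 3))
    got = robust_correlation_mcd(X, alpha=1.0).r
    assert np.allclose(got, np.corrcoef(X, rowvar=False), atol=1e-10)


def test_exactly_dependent_columns_give_correlation_one(rng):
    x = rng.normal(size=300)
    X = np.column_stack([x, 2.0 * x + 1.0])
    res = robust_correlation_mcd(X, alpha=0.75, nsamp=200, seed=1)
    assert res.r[0, 1] == pytest.approx(1.0, abs=1e-8)


def test_mcd_resists_contamination_better_than_classical():
    wins = 0
    for rep in range(5):
        rng = np.random.default_rng(1000 + rep)
        X = _contaminated_sample(rng)
        robust = robust_correlation_mcd(X, alpha=0.75, nsamp=1000,
                                        seed=rep).r[0, 1]
        classical = np.corrcoef(X, rowvar=False)[0, 1]
        if abs(robust - 0.5) < abs(classical - 0.5):
            wins += 1
    assert wins >= 4


def test_mcd_agrees_with_sklearn_reference_on_contaminated_data():
    sklearn = pytest.importorskip("sklearn.covariance")
    rng = np.random.default_rng(7)
    X = _contaminated_sample(rng)
    ours = robust_correlation_mcd(X, alpha=0.75, nsamp=2000, seed=7).r[0, 1]
    ref_cov = sklearn.MinCovDet(support_fraction=0.75,
                                random_state=7).fit(X).covariance_
    sd = np.sqrt(np.diag(ref_cov))
    ref = (ref_cov / np.outer(sd, sd))[0, 1]
    assert abs(ours - ref) < 0.15


def test_rows_with_missing_values_are_dropped(rng):
    X = rng.normal(size=(100, 2))
    X[::10, 0] = np.nan
    res = robust_correlation_mcd(X, alpha=1.0)
    clean = X[~np.isnan(X).any(axis=1)]
    assert np.allclose(res.r, np.corrcoef(clean, rowvar=False), atol=1e-10)
    assert len(res.support) == len(clean)


def test_too_few_rows_or_bad_alpha_rejected(rng):
    with pytest.raises(ValueError):
        robust_correlation_mcd(rng.normal(size=(2, 3)))
    with pytest.raises(ValueError):
        robust_correlation_mcd(rng.normal(size=(100, 2)), alpha=1.5)


def test_zero_variance_column_falls_back_to_classical_with_flag(rng):
    x = rng.normal(size=200)
    zero_heavy = np.zeros(200)
    zero_heavy[:10] = rng.normal(size=10)  # point mass dominates any h-subset
    X = np.column_stack([x, zero_heavy])
    with pytest.warns(UserWarning, match="degenerate"):
        res = robust_correlation_mcd(X, alpha=0.75, nsamp=500, seed=3)
    assert res.degenerate
    assert np.isfinite(res.r).all()


# ------------------------------------------------------- Huber calibration

def test_symmetric_sample_calibrates_to_zero_location():
    x = np.concatenate([np.linspace(-3, 3, 101)] * 3)
    cal, p = calibrate_dcms(x)
    assert cal.mu_hat == pytest.approx(0.0, abs=1e-6)
    assert p[x == 0][0] == pytest.approx(0.5, abs=1e-6)


def test_calibrated_pvalues_decrease_in_the_score(rng):
    x = np.sort(rng.normal(size=100))
    _, p = calibrate_dcms(x)
    assert (np.diff(p) <= 0).all()


def test_gross_outliers_barely_move_the_huber_location(rng):
    x = rng.normal(size=1000)
    x_out = x.copy()
    x_out[:20] += 50.0
    cal_clean, _ = calibrate_dcms(x)
    cal_out, _ = calibrate_dcms(x_out)
    assert abs(cal_out.mu_hat - cal_clean.mu_hat) < 0.05
    mean_shift = x_out.mean() - x.mean()
    assert abs(cal_out.mu_hat - cal_clean.mu_hat) < mean_shift / 5


def test_degenerate_scores_raise():
    with pytest.raises(ValueError):
        calibrate_dcms(np.full(50, 1.25))


def test_too_few_finite_scores_raise():
    with pytest.raises(ValueError):
        calibrate_dcms(np.array([1.0, 2.0, np.nan] * 3))


# ----------------------------------------------------------------- BH FDR

def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q[order[i]] = running
    return q


def test_bh_worked_example():
    q = bh_adjust([0.01, 0.04, 0.03, 0.005])
    assert np.allclose(q, bh_oracle([0.01, 0.04, 0.03, 0.005]))
    assert q[3] == pytest.approx(0.02)  # 0.005 * 4 / 1


def test_bh_matches_brute_force_on_random_pvalues(rng):
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 200)))
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_preserves_pvalue_ordering(rng):
    p = rng.uniform(size=100)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()
    assert (q >= p).all() and (q <= 1).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, -0.1])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.1])
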