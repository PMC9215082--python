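"""De-correlated composite of multiple signals (DCMS).

Each per-window statistic is turned into a one-sided fractional-rank
empirical p-value, logit-transformed (log10((1−p)/p)) and summed with each
statistic down-weighted by its total absolute correlation with all
statistics — estimated robustly by the minimum covariance determinant so
that the handful of true sweep windows cannot distort the weights.  The
resulting DCMS score is calibrated to a normal with an intercept-only Huber
M-estimate of location and scale, giving an upper-tail p-value per window,
and Benjamini–Hochberg adjustment yields q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

DEFAULT_TAILS = {"pi": "left", "clr": "left", "fst": "right", "xpehh": "right"}
#: tails used by the sweep-recovery experiments (high CLR indicates a sweep)
RECOVERY_TAILS = {"pi": "left", "clr": "right", "fst": "right", "xpehh": "right"}


def stat_to_pvalue(values, tail):
    """Fractional-rank empirical one-sided p-values in (0, 1).

    right tail: p_i = #{j : v_j >= v_i}/(n+1); left tail mirrors.  Ties share
    a p-value; the n+1 denominator keeps p strictly inside (0, 1).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2 or not np.isfinite(values).all():
        raise ValueError("need at least two finite values")
    if tail == "right":
        ge = n - rankdata(values, method="min") + 1
        p = ge / (n + 1.0)
    elif tail == "left":
        le = rankdata(values, method="max")
        p = le / (n + 1.0)
    else:
        raise ValueError("tail must be 'left' or 'right'")
    if np.ptp(values) == 0:
        import warnings
        warnings.warn("all values identical; p-values are uninformative")
    return p


@dataclass
class RobustCorrelation:
    r: np.ndarray
    alpha: float
    nsamp: int
    support: np.ndarray  # indices of the determinant-minimising subset
    degenerate: bool = False  # exact fit hit; classical correlation returned


def _cov_to_corr(cov):
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


def _subset_cov(X, idx):
    sub = X[idx]
    return sub.mean(axis=0), np.cov(sub, rowvar=False)


def _c_step(X, mean, cov, h):
    """One concentration step: h points of smallest Mahalanobis distance."""
    diff = X - mean
    inv = np.linalg.pinv(cov)
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    idx = np.argpartition(d2, h - 1)[:h]
    return idx


def robust_correlation_mcd(stat_matrix, alpha=0.75, nsamp=50_000, seed=0,
                           max_csteps=30) -> RobustCorrelation:
    """FAST-MCD correlation matrix of the statistics across windows.

    Rows with any missing value are excluded (complete-case).  ``nsamp``
    random (T+1)-point starts are refined by two concentration steps; the
    ten most concentrated candidates are iterated to a local determinant
    minimum and the best subset's covariance, converted to a correlation
    matrix, is returned.  ``alpha`` is the subset fraction; alpha = 1 is the
    classical estimator.
    """
    X = np.asarray(stat_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, t = X.shape
    h = int(np.ceil(alpha * n))
    if h > n:
        raise ValueError("alpha implies a subset larger than the data")
    if n < t + 1:
        raise ValueError("need more complete windows than statistics")
    if h >= n:
        r = _cov_to_corr(np.cov(X, rowvar=False))
        return RobustCorrelation(r, alpha, nsamp, np.arange(n))
    if h < t + 1:
        raise ValueError("too few complete windows for this alpha; "
                         "use a smaller alpha or more windows")

    rng = np.random.default_rng(seed)

    # two concentration steps for every random (t+1)-start, vectorised in
    # chunks; keep the few most concentrated candidates per chunk
    candidates = []  # (det, support)
    chunk = 2048
    done = 0
    while done < nsamp:
        c = min(chunk, nsamp - done)
        starts = np.argpartition(rng.random((c, n)), t, axis=1)[:, :t + 1]
        sub = X[starts]  # (c, t+1, t)
        means = sub.mean(axis=1)
        d = sub - means[:, None, :]
        covs = np.matmul(d.transpose(0, 2, 1), d) / t
        idx = None
        for _ in range(2):
            try:
                inv = np.linalg.inv(covs)
            except np.linalg.LinAlgError:
                inv = np.linalg.pinv(covs)
            diff = X[None, :, :] - means[:, None, :]
            d2 = (np.matmul(diff, inv) * diff).sum(axis=2)
            idx = np.argpartition(d2, h - 1, axis=1)[:, :h]
            sel = X[idx]  # (c, h, t)
            means = sel.mean(axis=1)
            d = sel - means[:, None, :]
            covs = np.matmul(d.transpose(0, 2, 1), d) / (h - 1)
        dets = np.linalg.det(covs)
        for s in np.argsort(dets)[:3]:
            candidates.append((dets[s], np.sort(idx[s])))
        done += c

    candidates.sort(key=lambda c: c[0])
    best_det, best_support, best_cov = np.inf, None, None
    for _, idx in candidates[:10]:
        mean, cov = _subset_cov(X, idx)
        det = np.linalg.det(cov)
        for _ in range(max_csteps):
            new = np.sort(_c_step(X, mean, cov, h))
            if np.array_equal(new, idx):
                break
            idx = new
            mean, cov = _subset_cov(X, idx)
            det = np.linalg.det(cov)
        if det < best_det:
            best_det, best_support, best_cov = det, idx, cov
    r = _cov_to_corr(best_cov)
    if not np.isfinite(r).all():
        # exact fit: >= h windows lie on a hyperplane (e.g. a statistic with
        # a point mass shares one value across the subset), so the MCD
        # correlation is undefined; fall back to the classical estimate
        import warnings
        warnings.warn("MCD subset is degenerate (zero-variance statistic); "
                      "using the classical correlation matrix")
        r = _cov_to_corr(np.cov(X, rowvar=False))
        return RobustCorrelation(r, alpha, nsamp, np.arange(n), degenerate=True)
    return RobustCorrelation(r, alpha, nsamp, best_support)


def dcms(p_matrix, corr: RobustCorrelation | np.ndarray):
    """DCMS_i = Σ_t log10((1−p_it)/p_it) / Σ_s |r_st|."""
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    r = corr.r if isinstance(corr, RobustCorrelation) else np.asarray(corr, dtype=float)
    weights = np.abs(r).sum(axis=0)
    scores = np.log10((1.0 - p) / p)
    return (scores / weights).sum(axis=1)


@dataclass
class DCMSCalibration:
    mu_hat: float
    sigma_hat: float
    huber_k: float = 1.345


def calibrate_dcms(dcms_values, huber_k=1.345):
    """Huber intercept-only fit; upper-tail normal p per window.

    Iteratively reweighted least squares with tuning constant ``huber_k``
    and MAD scale, as in the standard robust linear model with a constant
    design.  Returns (DCMSCalibration, p_values).
    """
    x = np.asarray(dcms_values, dtype=float)
    if np.isfinite(x).sum() < 10:
        raise ValueError("need at least 10 finite DCMS values to calibrate")
    res = sm.RLM(x, np.ones((x.size, 1)),
                 M=sm.robust.norms.HuberT(t=huber_k)).fit(conv="coefs", tol=1e-8)
    mu = float(res.params[0])
    sigma = float(res.scale)
    # constant input yields a float-fuzz scale (~1e-16), not an exact zero
    if (not np.isfinite(mu) or not np.isfinite(sigma)
            or sigma <= max(abs(mu), 1.0) * 1e-12):
        raise ValueError("robust scale is zero; DCMS values are degenerate")
    cal = DCMSCalibration(mu, sigma, huber_k)
    return cal, norm.sf((x - mu) / sigma)


def bh_adjust(p_values):
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
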