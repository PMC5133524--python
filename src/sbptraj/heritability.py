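"""Pedigree-based REML estimation of narrow-sense heritability.

Variance-component model y = Xb + g + e with cov(g) = 2*Phi*sigma_g^2 and
cov(e) = I*sigma_e^2.  A single eigendecomposition of A = 2*Phi reduces the
restricted likelihood to a one-dimensional profile in h2 = sigma_g^2 /
(sigma_g^2 + sigma_e^2), optimised on [0, 1].  The test of sigma_g^2 = 0
uses the 50:50 chi-square(0)/chi-square(1) boundary mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix


@dataclass
class HeritabilityResult:
    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _profile_reml(
    h2: float, yt: np.ndarray, xt: np.ndarray, d: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Profile restricted log-likelihood at h2 (sigma_p^2 profiled out).

    Returns (loglik, sigma_p2_hat, beta_hat) working in the eigenbasis of A,
    where the rotated covariance is diag(h2 * d + 1 - h2) * sigma_p^2.
    """
    n, p = xt.shape
    w = h2 * d + (1.0 - h2)
    wi = 1.0 / w
    xtw = xt * wi[:, None]
    xx = xt.T @ xtw
    sign, logdet_xx = np.linalg.slogdet(xx)
    if sign <= 0:
        return -np.inf, np.nan, np.full(p, np.nan)
    beta = np.linalg.solve(xx, xtw.T @ yt)
    r = yt - xt @ beta
    rss = float(r @ (wi * r))
    sigma_p2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(sigma_p2)
        + np.log(w).sum()
        + logdet_xx
        + (n - p)
        + (n - p) * np.log(2.0 * np.pi)
    )
    return float(ll), sigma_p2, beta


def estimate_h2(
    trait: np.ndarray,
    covariates: np.ndarray | None,
    K: KinshipMatrix,
) -> HeritabilityResult:
    """REML heritability of a quantitative (or 0/1) trait on a pedigree.

    Parameters
    ----------
    trait : array (n,)
        Trait values aligned to ``K.ids``; NaN entries are dropped (with the
        matching kinship rows/columns).
    covariates : array (n, c) or None
        Fixed-effect design without intercept (an intercept is always added).
    K : KinshipMatrix
        Pedigree kinship over the same individuals, same order.
    """
    y = np.asarray(trait, dtype=float)
    n_all = len(K.ids)
    if y.shape != (n_all,):
        raise ValueError("trait not aligned to kinship ordering")
    X = np.ones((n_all, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X, cov])
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    y, X = y[keep], X[keep]
    A = K.relationship[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular covariate matrix")
    if n <= p + 1:
        raise ValueError("too few individuals for REML")

    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ X

    hmax = 1.0 if d.min() > 1e-8 else 1.0 - 1e-8

    def neg(h2: float) -> float:
        return -_profile_reml(h2, yt, xt, d)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, hmax), method="bounded")
    # guard the boundaries: bounded Brent never evaluates the endpoints
    cands = [(neg(0.0), 0.0), (res.fun, float(res.x)), (neg(hmax), hmax)]
    fbest, h2 = min(cands, key=lambda t: t[0])
    ll, sigma_p2, _ = _profile_reml(h2, yt, xt, d)
    ll0, _, _ = _profile_reml(0.0, yt, xt, d)

    # SE from the observed information of the 1-D profile likelihood
    eps = 1e-4
    lo, hi = max(h2 - eps, 0.0), min(h2 + eps, hmax)
    f0 = _profile_reml(lo, yt, xt, d)[0]
    f1 = _profile_reml((lo + hi) / 2.0, yt, xt, d)[0]
    f2 = _profile_reml(hi, yt, xt, d)[0]
    step = (hi - lo) / 2.0
    d2 = (f0 - 2.0 * f1 + f2) / step**2 if step > 0 else np.nan
    se = float(np.sqrt(-1.0 / d2)) if np.isfinite(d2) and d2 < 0 else np.nan

    lr = 2.0 * (ll - ll0)
    p_val = 1.0 if lr <= 0 else float(0.5 * stats.chi2.sf(lr, df=1))
    h2 = min(h2, 1.0)
    return HeritabilityResult(
        h2=h2,
        se=se,
        sigma_g2=h2 * sigma_p2,
        sigma_e2=(1.0 - h2) * sigma_p2,
        loglik=ll,
        p_value=p_val,
    )
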