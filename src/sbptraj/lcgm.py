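"""Censored-normal latent-class growth modelling of SBP trajectories.

A finite mixture of polynomial age trajectories: given class k, an
individual's repeated SBP measures are independent censored-normal
observations around the class curve (quadratic in standardised age by
default) plus per-visit covariate effects shared across classes.  Fitting is
by EM over individual-level responsibilities with a weighted (censored)
regression M-step; model selection maximises BIC subject to a minimum
hard-assigned group size, after which per-class polynomial orders are pruned
by Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .simulate import AGE_CENTER, AGE_SCALE, LongitudinalPhenotypes

MIN_GROUP_SIZE = 25  # hard-assigned classes must exceed this


class InfeasibleConfigError(ValueError):
    """Requested class count cannot satisfy the minimum-group-size rule."""


def censored_normal_loglik(y, mu, sigma, y_min=-np.inf, y_max=np.inf):
    """Log-density of a censored normal observation (vectorised).

    Interior values get the normal log-pdf; values at or below ``y_min`` get
    the lower-tail point mass log Phi((y_min - mu) / sigma); values at or
    above ``y_max`` get the upper-tail mass log(1 - Phi((y_max - mu) / sigma)).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(y).all() or not np.isfinite(mu).all():
        raise ValueError("y and mu must be finite")
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("sigma must be finite and positive")
    if not y_min < y_max:
        raise ValueError("need y_min < y_max")
    out = stats.norm.logpdf(y, loc=mu, scale=sigma)
    if np.isfinite(y_min):
        lo = y <= y_min
        if lo.any():
            out = np.where(lo, stats.norm.logcdf((y_min - mu) / sigma), out)
    if np.isfinite(y_max):
        hi = y >= y_max
        if hi.any():
            out = np.where(hi, stats.norm.logsf((y_max - mu) / sigma), out)
    return out


@dataclass
class TrajectoryModel:
    """Fitted latent-class growth model."""

    K: int
    class_terms: tuple[tuple[int, ...], ...]  # polynomial orders kept per class
    coefs: tuple[np.ndarray, ...]  # per class, aligned to class_terms
    pi: np.ndarray
    covariates: tuple[str, ...]
    cov_names: tuple[str, ...]  # expanded per-visit covariate columns
    cov_coefs: np.ndarray
    sigma: float
    bounds: tuple[float, float]
    loglik: float
    bic: float
    n_individuals: int
    n_params: int
    ll_trace: np.ndarray = field(repr=False)
    converged: bool = True
    coef_se: tuple[np.ndarray, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi <= 0).any():
            raise ValueError("mixing proportions must be positive and sum to 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def class_curve(self, k: int, age: np.ndarray) -> np.ndarray:
        """Mean trajectory of class ``k`` (0-based) at raw ages."""
        c = (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE
        mu = np.zeros_like(c)
        for t, b in zip(self.class_terms[k], self.coefs[k]):
            mu += b * c**t
        return mu

    def raw_age_coefs(self, k: int) -> np.ndarray:
        """Class-k polynomial re-expressed on the raw-age scale (deg 2)."""
        b = np.zeros(3)
        for t, v in zip(self.class_terms[k], self.coefs[k]):
            b[t] = v
        b0, b1, b2 = b
        a, s = AGE_CENTER, AGE_SCALE
        return np.array(
            [
                b0 - b1 * a / s + b2 * a**2 / s**2,
                b1 / s - 2 * b2 * a / s**2,
                b2 / s**2,
            ]
        )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "class_terms": [list(t) for t in self.class_terms],
            "coefs": [list(map(float, c)) for c in self.coefs],
            "pi": list(map(float, self.pi)),
            "covariates": list(self.covariates),
            "cov_names": list(self.cov_names),
            "cov_coefs": list(map(float, self.cov_coefs)),
            "sigma": float(self.sigma),
            "bounds": [float(self.bounds[0]), float(self.bounds[1])],
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n_individuals": int(self.n_individuals),
            "n_params": int(self.n_params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryModel":
        return cls(
            K=d["K"],
            class_terms=tuple(tuple(t) for t in d["class_terms"]),
            coefs=tuple(np.asarray(c, dtype=float) for c in d["coefs"]),
            pi=np.asarray(d["pi"], dtype=float),
            covariates=tuple(d["covariates"]),
            cov_names=tuple(d["cov_names"]),
            cov_coefs=np.asarray(d["cov_coefs"], dtype=float),
            sigma=d["sigma"],
            bounds=(d["bounds"][0], d["bounds"][1]),
            loglik=d["loglik"],
            bic=d["bic"],
            n_individuals=d["n_individuals"],
            n_params=d["n_params"],
            ll_trace=np.array([d["loglik"]]),
        )


@dataclass
class ClassAssignment:
    """Posterior class membership with hard labels and optional ranks."""

    individual_ids: np.ndarray
    posterior: np.ndarray = field(repr=False)
    hard: np.ndarray = field(repr=False)  # 1..K, argmax posterior
    rank: np.ndarray | None = field(default=None, repr=False)  # 1..K ordinal

    def __post_init__(self) -> None:
        if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")
        if not (self.hard == self.posterior.argmax(axis=1) + 1).all():
            raise ValueError("hard labels must be the posterior argmax")

    @property
    def K(self) -> int:
        return self.posterior.shape[1]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"individual_id": self.individual_ids, "class": self.hard})
        if self.rank is not None:
            out["rank"] = self.rank
        for k in range(self.K):
            out[f"p{k + 1}"] = self.posterior[:, k]
        return out


# ---------------------------------------------------------------------------
# data preparation


class _Prepared:
    """Observation-level arrays sorted so individuals are contiguous."""

    def __init__(
        self, ph: LongitudinalPhenotypes, covariates: tuple[str, ...]
    ) -> None:
        tab = ph.table
        codes, uniques = pd.factorize(tab["individual_id"], sort=True)
        order = np.argsort(codes, kind="mergesort")
        self.ids = np.asarray(uniques, dtype=object)
        self.ind = codes[order]
        self.y = tab["sbp"].to_numpy()[order]
        self.c = ((tab["age"].to_numpy() - AGE_CENTER) / AGE_SCALE)[order]
        self.n = len(self.ids)
        self.n_obs = len(self.y)
        self.starts = np.searchsorted(self.ind, np.arange(self.n))
        visits = tab["visit"].to_numpy()[order]
        cols, names = [], []
        for name in covariates:
            if name == "sex":
                val = (tab["sex"].to_numpy()[order] == "male").astype(float)
            elif name == "smoking":
                val = tab["smoking"].to_numpy()[order].astype(float)
            else:
                raise ValueError(f"unsupported covariate {name!r}")
            for v in np.unique(visits):
                cols.append(val * (visits == v))
                names.append(f"{name}@visit{v}")
        self.cov = (
            np.column_stack(cols) if cols else np.empty((self.n_obs, 0))
        )
        self.cov_names = tuple(names)

    def per_individual_ls(self) -> np.ndarray:
        """(intercept, slope) of each individual's own SBP-on-age line."""
        feats = np.empty((self.n, 2))
        for i in range(self.n):
            s = self.starts[i]
            e = self.starts[i + 1] if i + 1 < self.n else self.n_obs
            yy, cc = self.y[s:e], self.c[s:e]
            if e - s >= 2 and np.ptp(cc) > 0:
                b1 = np.cov(cc, yy, ddof=0)[0, 1] / np.var(cc)
                feats[i] = yy.mean() - b1 * cc.mean(), b1
            else:
                feats[i] = yy.mean(), 0.0
        return feats

    def reduce_by_individual(self, obs_vals: np.ndarray) -> np.ndarray:
        return np.add.reduceat(obs_vals, self.starts, axis=0)


def _class_mu(prep: _Prepared, class_terms, coefs, cov_coefs) -> np.ndarray:
    """Observation x class mean matrix."""
    K = len(class_terms)
    mu = np.empty((prep.n_obs, K))
    cov_part = prep.cov @ cov_coefs if prep.cov.shape[1] else 0.0
    for k in range(K):
        m = np.zeros(prep.n_obs)
        for t, b in zip(class_terms[k], coefs[k]):
            m += b * prep.c**t
        mu[:, k] = m + cov_part
    return mu


def _obs_loglik(prep, class_terms, coefs, cov_coefs, sigma, bounds) -> np.ndarray:
    mu = _class_mu(prep, class_terms, coefs, cov_coefs)
    if np.isinf(bounds[0]) and np.isinf(bounds[1]):
        z = (prep.y[:, None] - mu) / sigma
        return -0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    return censored_normal_loglik(
        prep.y[:, None], mu, sigma, bounds[0], bounds[1]
    )


def _stack_design(prep: _Prepared, class_terms) -> np.ndarray:
    """Block design for the stacked weighted M-step regression."""
    K = len(class_terms)
    n_poly = sum(len(t) for t in class_terms)
    P = n_poly + prep.cov.shape[1]
    Z = np.zeros((K * prep.n_obs, P))
    col = 0
    for k in range(K):
        rows = slice(k * prep.n_obs, (k + 1) * prep.n_obs)
        for t in class_terms[k]:
            Z[rows, col] = prep.c**t
            col += 1
    for j in range(prep.cov.shape[1]):
        Z[:, n_poly + j] = np.tile(prep.cov[:, j], K)
    return Z


def _unpack(theta, class_terms, n_cov):
    coefs, pos = [], 0
    for t in class_terms:
        coefs.append(np.asarray(theta[pos : pos + len(t)]))
        pos += len(t)
    return tuple(coefs), np.asarray(theta[pos : pos + n_cov])


def _em_fit(
    prep: _Prepared,
    class_terms,
    bounds,
    resp0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """Run EM from initial responsibilities; returns parameter dict or None."""
    K = len(class_terms)
    Z = _stack_design(prep, class_terms)
    n_cov = prep.cov.shape[1]
    ystack = np.tile(prep.y, K)
    finite_bounds = np.isfinite(bounds[0]) or np.isfinite(bounds[1])

    resp = resp0
    theta = None
    sigma = None
    ll_trace = []
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # ---- M-step: weighted (censored) regression + proportions
        pi = resp.mean(axis=0)
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
        w_obs = resp[prep.ind]  # n_obs x K
        w = w_obs.T.reshape(-1)  # stacked to match Z
        Zw = Z * w[:, None]
        try:
            theta_new = np.linalg.solve(Z.T @ Zw, Zw.T @ ystack)
        except np.linalg.LinAlgError:
            sw = np.sqrt(w)
            theta_new, *_ = np.linalg.lstsq(
                Z * sw[:, None], ystack * sw, rcond=None
            )
        r = ystack - Z @ theta_new
        sigma_new = float(np.sqrt((w * r**2).sum() / w.sum()))
        sigma_new = max(sigma_new, 1e-6)
        if finite_bounds:
            # generalised M-step: polish by direct weighted censored-normal
            # likelihood ascent, keeping the previous point if no better
            def nq(p):
                th, lsig = p[:-1], p[-1]
                co, cc = _unpack(th, class_terms, n_cov)
                ll = _obs_loglik(prep, class_terms, co, cc, np.exp(lsig), bounds)
                return -(w_obs * ll).sum()

            x0 = np.append(theta_new, np.log(sigma_new))
            if theta is not None:
                x_prev = np.append(theta, np.log(sigma))
                if nq(x_prev) < nq(x0):
                    x0 = x_prev
            res = optimize.minimize(nq, x0, method="L-BFGS-B")
            x_best = res.x if res.fun <= nq(x0) else x0
            theta_new = x_best[:-1]
            sigma_new = float(np.exp(x_best[-1]))
        theta, sigma = theta_new, sigma_new

        # ---- E-step
        coefs, cov_coefs = _unpack(theta, class_terms, n_cov)
        ll_obs = _obs_loglik(prep, class_terms, coefs, cov_coefs, sigma, bounds)
        Lik = prep.reduce_by_individual(ll_obs)  # n x K
        logr = np.log(pi)[None, :] + Lik
        ll = float(logsumexp(logr, axis=1).sum())
        resp = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
        ll_trace.append(ll)
        if np.isfinite(ll_prev) and ll - ll_prev < tol * max(abs(ll), 1.0):
            converged = True
            break
        ll_prev = ll
    coefs, cov_coefs = _unpack(theta, class_terms, n_cov)
    return {
        "pi": pi,
        "coefs": coefs,
        "cov_coefs": cov_coefs,
        "sigma": sigma,
        "loglik": ll_trace[-1],
        "ll_trace": np.asarray(ll_trace),
        "resp": resp,
        "converged": converged,
        "Z": Z,
    }


def _init_resp(prep: _Prepared, K: int, rng: np.random.Generator, jitter: float):
    feats = prep.per_individual_ls()
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    fz = (feats - feats.mean(axis=0)) / sd
    if jitter > 0:
        fz = fz + rng.normal(0.0, jitter, size=fz.shape)
    km = KMeans(
        n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1))
    ).fit(fz)
    resp = np.full((prep.n, K), 0.05 / max(K - 1, 1))
    resp[np.arange(prep.n), km.labels_] = 0.95
    if K == 1:
        resp[:] = 1.0
    return resp / resp.sum(axis=1, keepdims=True)


def _n_params(class_terms, K, n_cov) -> int:
    return sum(len(t) for t in class_terms) + (K - 1) + 1 + n_cov


def fit_lcgm(
    ph: LongitudinalPhenotypes,
    K: int,
    order: int = 2,
    covariates: tuple[str, ...] = (),
    bounds: tuple[float, float] = (-np.inf, np.inf),
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    class_terms: tuple[tuple[int, ...], ...] | None = None,
    resp_init: np.ndarray | None = None,
) -> TrajectoryModel:
    """Fit a K-class censored-normal growth mixture by multistart EM.

    ``order`` (<= 2) sets the common polynomial degree; ``class_terms``
    optionally overrides the per-class retained orders (used by pruning).
    BIC follows the "higher is better" convention: loglik - p/2 * log(n),
    with n the number of individuals.
    """
    if not 0 <= order <= 2:
        raise ValueError("order must be 0, 1, or 2")
    if K < 1:
        raise ValueError("K must be >= 1")
    prep = _Prepared(ph, tuple(covariates))
    if prep.n <= MIN_GROUP_SIZE * K:
        raise InfeasibleConfigError(
            f"K={K} infeasible: {prep.n} individuals cannot form {K} groups "
            f"of more than {MIN_GROUP_SIZE}"
        )
    if class_terms is None:
        class_terms = tuple(tuple(range(order + 1)) for _ in range(K))
    rng = np.random.default_rng(seed)

    best = None
    if resp_init is not None:
        starts = [resp_init]
    else:
        starts = [
            _init_resp(prep, K, rng, jitter=0.0 if s == 0 else 0.5)
            for s in range(n_starts if K > 1 else 1)
        ]
    for resp0 in starts:
        fit = _em_fit(prep, class_terms, bounds, resp0, max_iter, tol)
        if best is None or fit["loglik"] > best["loglik"]:
            best = fit

    n_cov = prep.cov.shape[1]
    p = _n_params(class_terms, K, n_cov)
    bic = best["loglik"] - 0.5 * p * np.log(prep.n)

    # Wald SEs from the converged weighted regression (responsibilities fixed)
    w = best["resp"][prep.ind].T.reshape(-1)
    Z = best["Z"]
    ztz = Z.T @ (Z * w[:, None])
    try:
        cov_theta = best["sigma"] ** 2 * np.linalg.inv(ztz)
        se_all = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_all = np.full(Z.shape[1], np.nan)
    coef_se, pos = [], 0
    for t in class_terms:
        coef_se.append(se_all[pos : pos + len(t)])
        pos += len(t)

    return TrajectoryModel(
        K=K,
        class_terms=class_terms,
        coefs=best["coefs"],
        pi=best["pi"],
        covariates=tuple(covariates),
        cov_names=prep.cov_names,
        cov_coefs=best["cov_coefs"],
        sigma=best["sigma"],
        bounds=(float(bounds[0]), float(bounds[1])),
        loglik=best["loglik"],
        bic=bic,
        n_individuals=prep.n,
        n_params=p,
        ll_trace=best["ll_trace"],
        converged=best["converged"],
        coef_se=tuple(coef_se),
    )


def assign_classes(
    model: TrajectoryModel, ph: LongitudinalPhenotypes
) -> ClassAssignment:
    """Posterior class probabilities by Bayes' rule; hard label = argmax."""
    prep = _Prepared(ph, model.covariates)
    ll_obs = _obs_loglik(
        prep, model.class_terms, model.coefs, model.cov_coefs, model.sigma,
        model.bounds,
    )
    Lik = prep.reduce_by_individual(ll_obs)
    logr = np.log(model.pi)[None, :] + Lik
    post = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
    return ClassAssignment(
        individual_ids=prep.ids, posterior=post, hard=post.argmax(axis=1) + 1
    )


def select_num_classes(
    ph: LongitudinalPhenotypes,
    K_range=range(1, 7),
    order: int = 2,
    covariates: tuple[str, ...] = (),
    bounds: tuple[float, float] = (-np.inf, np.inf),
    seed: int = 0,
    **fit_kwargs,
) -> TrajectoryModel:
    """Fit each K, drop solutions violating the group-size rule, max the BIC.

    A solution is infeasible when any hard-assigned group has
    ``MIN_GROUP_SIZE`` (25) or fewer members.  Ties in BIC break toward the
    smaller K.  Raises with per-K diagnostics if nothing survives.
    """
    results: dict[int, str] = {}
    best = None
    for K in K_range:
        try:
            m = fit_lcgm(
                ph, K, order=order, covariates=covariates, bounds=bounds,
                seed=seed + K, **fit_kwargs,
            )
        except InfeasibleConfigError as e:
            results[K] = f"infeasible: {e}"
            continue
        counts = np.bincount(
            assign_classes(m, ph).hard, minlength=K + 1
        )[1:]
        if counts.min() <= MIN_GROUP_SIZE:
            results[K] = f"group-size violation (min group {counts.min()})"
            continue
        results[K] = f"ok (BIC {m.bic:.2f})"
        if best is None or m.bic > best.bic:
            best = m
    if best is None:
        raise InfeasibleConfigError(f"no feasible class count: {results}")
    return best


def prune_polynomial_orders(
    model: TrajectoryModel,
    ph: LongitudinalPhenotypes,
    alpha: float = 0.05,
    seed: int = 0,
) -> TrajectoryModel:
    """Drop non-significant highest-order polynomial terms class by class.

    Iteratively removes the least significant (Wald p > alpha) highest-order
    term among classes and refits, until every class's highest retained term
    is significant.  Intercepts are never dropped; K is unchanged.
    """
    current = model
    while True:
        worst_p, worst_k = -1.0, -1
        for k in range(current.K):
            terms = current.class_terms[k]
            if len(terms) <= 1:
                continue
            j = int(np.argmax(terms))  # highest order position
            se = current.coef_se[k][j] if current.coef_se is not None else np.nan
            if not np.isfinite(se) or se <= 0:
                continue
            z = current.coefs[k][j] / se
            pval = 2.0 * stats.norm.sf(abs(z))
            if pval > alpha and pval > worst_p:
                worst_p, worst_k = pval, k
        if worst_k < 0:
            return current
        terms = list(current.class_terms[worst_k])
        terms.remove(max(terms))
        new_terms = tuple(
            tuple(terms) if k == worst_k else current.class_terms[k]
            for k in range(current.K)
        )
        current = fit_lcgm(
            ph,
            current.K,
            covariates=current.covariates,
            bounds=current.bounds,
            seed=seed,
            class_terms=new_terms,
            resp_init=None,
            n_starts=3,
        )


def rank_classes(
    assign: ClassAssignment,
    hy_years: pd.Series,
    last_sbp: pd.Series | None = None,
) -> tuple[ClassAssignment, np.ndarray]:
    """Relabel classes 1..K by ascending class-mean hypertensive years.

    ``hy_years`` maps individual_id -> cumulative hypertensive years; ties in
    the class mean break by class-mean ``last_sbp`` (SBP at the final visit)
    when given, else by original class index.  Returns the assignment with
    ordinal ranks plus the rank-of-class mapping (index k-1 -> rank).
    """
    K = assign.K
    yrs = hy_years.reindex(assign.individual_ids)
    if yrs.isna().any():
        raise ValueError("hypertensive years missing for some assigned individuals")
    means = np.array(
        [yrs.to_numpy()[assign.hard == k + 1].mean() for k in range(K)]
    )
    if last_sbp is not None:
        tie = last_sbp.reindex(assign.individual_ids).to_numpy()
        tie_means = np.array(
            [tie[assign.hard == k + 1].mean() for k in range(K)]
        )
    else:
        tie_means = np.arange(K, dtype=float)
    order = np.lexsort((tie_means, means))  # class indices sorted ascending
    rank_of_class = np.empty(K, dtype=int)
    rank_of_class[order] = np.arange(1, K + 1)
    ranked = replace(assign, rank=rank_of_class[assign.hard - 1])
    return ranked, rank_of_class
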