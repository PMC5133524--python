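"""Lagged path-model screen for trajectory covariates.

A recursive system of per-visit regressions: SBP at visit 1 on covariates and
one SNP; SBP at each later visit additionally on SBP at the immediately
preceding visit (the lag path).  Coefficients are estimated equation by
equation by least squares with family-clustered sandwich standard errors;
indirect covariate effects are products of path coefficients with
delta-method SEs.  Model adequacy is summarised by RMSEA / CFI / TLI from
likelihood-ratio discrepancies against the saturated recursive system, and a
covariate is retained for trajectory modelling when it is significant at
two or more time points in two or more SNP models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LongitudinalPhenotypes

MIN_GENOTYPE_COUNT = 30


class SNPSkipped(Exception):
    """SNP fails the per-genotype minimum-count precondition; skip it."""


def to_wide(
    ph: LongitudinalPhenotypes, n_visits: int | None = None
) -> pd.DataFrame:
    """Complete-case wide table: one row per individual, sbp1..sbpT columns.

    Individuals missing any of the ``n_visits`` design visits (default: the
    maximum visit index present) are dropped — the path model needs the full
    visit grid.
    """
    tab = ph.table
    if n_visits is None:
        n_visits = int(tab["visit"].max())
    wide = tab.pivot_table(
        index="individual_id", columns="visit", values="sbp", aggfunc="first"
    )
    wide = wide.reindex(columns=range(1, n_visits + 1))
    wide.columns = [f"sbp{v}" for v in range(1, n_visits + 1)]
    per_ind = tab.drop_duplicates("individual_id").set_index("individual_id")
    wide["male"] = (per_ind["sex"] == "male").astype(float)
    wide["smoking"] = per_ind["smoking"].astype(float)
    wide["family_id"] = per_ind["family_id"]
    return wide.dropna(subset=[f"sbp{v}" for v in range(1, n_visits + 1)])


def ols_cluster(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS with a cluster-robust sandwich covariance (no small-sample factor).

    With singleton clusters the sandwich reduces exactly to the HC0
    heteroskedasticity-robust covariance.  Returns (beta, se, loglik) where
    loglik is the Gaussian ML log-likelihood at the MLE residual variance.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    u = y - X @ beta
    meat = np.zeros((p, p))
    for g in np.unique(groups):
        xg_ug = X[groups == g].T @ u[groups == g]
        meat += np.outer(xg_ug, xg_ug)
    cov = xtx_inv @ meat @ xtx_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    s2 = float(u @ u) / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    return beta, se, ll


@dataclass
class PathModelFit:
    """Estimates for the recursive lagged system of one SNP model."""

    coef_table: pd.DataFrame = field(repr=False)  # visit, term, coef, se, p
    indirect_table: pd.DataFrame = field(repr=False)
    loglik_model: float = 0.0
    loglik_saturated: float = 0.0
    loglik_independence: float = 0.0
    df_model: int = 0  # saturated params - model params
    df_independence: int = 0
    n: int = 0
    n_visits: int = 0

    def p_of(self, term: str, visit: int) -> float:
        row = self.coef_table[
            (self.coef_table["term"] == term) & (self.coef_table["visit"] == visit)
        ]
        return float(row["p"].iloc[0])

    def lag_coefs(self) -> pd.DataFrame:
        return self.coef_table[self.coef_table["term"] == "lag"]


def _check_genotype_counts(snp: np.ndarray, min_count: int) -> None:
    vals, counts = np.unique(snp[~np.isnan(snp)], return_counts=True)
    for v, c in zip(vals, counts):
        if c < min_count:
            raise SNPSkipped(
                f"genotype {v:g} has {c} carriers (< {min_count})"
            )


def fit_lagged_path_model(
    wide: pd.DataFrame,
    snp: np.ndarray | None,
    covariates: tuple[str, ...] = ("male", "smoking"),
    cluster: str = "family_id",
    min_genotype_count: int = MIN_GENOTYPE_COUNT,
) -> PathModelFit:
    """Fit the recursive lagged path system for one SNP.

    ``wide`` comes from :func:`to_wide`; ``snp`` is a per-individual dosage
    vector aligned to its rows (or None for a covariates-only model).
    Raises :class:`SNPSkipped` when any genotype class has fewer than 30
    carriers.
    """
    sbp_cols = [c for c in wide.columns if c.startswith("sbp")]
    T = len(sbp_cols)
    if T < 2:
        raise ValueError("need at least 2 visits")
    for c in covariates:
        if c not in wide.columns:
            raise ValueError(f"covariate {c!r} missing from wide table")
    if snp is not None:
        snp = np.asarray(snp, dtype=float)
        _check_genotype_counts(snp, min_genotype_count)
    groups = wide[cluster].to_numpy()
    n = len(wide)
    Y = wide[sbp_cols].to_numpy()
    C = wide[list(covariates)].to_numpy() if covariates else np.empty((n, 0))

    rows = []
    ll_model = ll_sat = ll_ind = 0.0
    p_model = p_sat = p_ind = 0
    for t in range(1, T + 1):
        y = Y[:, t - 1]
        terms = ["const"]
        Xcols = [np.ones(n)]
        if t >= 2:
            terms.append("lag")
            Xcols.append(Y[:, t - 2])
        for j, c in enumerate(covariates):
            terms.append(c)
            Xcols.append(C[:, j])
        if snp is not None:
            terms.append("snp")
            Xcols.append(snp)
        X = np.column_stack(Xcols)
        beta, se, ll = ols_cluster(y, X, groups)
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        for term, b, s, p in zip(terms, beta, se, pvals):
            rows.append((t, term, b, s, p))
        ll_model += ll
        p_model += X.shape[1] + 1  # + residual variance

        # saturated factorisation: regress on all earlier visits
        Xs = np.column_stack([np.ones(n), Y[:, : t - 1], C] + (
            [snp[:, None]] if snp is not None else []
        ))
        _, _, lls = ols_cluster(y, Xs, groups)
        ll_sat += lls
        p_sat += Xs.shape[1] + 1

        # independence baseline: intercept only
        _, _, lli = ols_cluster(y, np.ones((n, 1)), groups)
        ll_ind += lli
        p_ind += 2

    coef_table = pd.DataFrame(rows, columns=["visit", "term", "coef", "se", "p"])

    # cumulative indirect effect of each covariate into visit t: the sum of
    # all lag-mediated chains I_t = sum_{s<t} gamma_s * prod_{u=s+1..t} lambda_u,
    # with a delta-method SE treating per-equation estimates as independent
    ind_rows = []
    ct = coef_table.set_index(["visit", "term"])
    lam = {t: ct.loc[(t, "lag"), "coef"] for t in range(2, T + 1)}
    lam_se = {t: ct.loc[(t, "lag"), "se"] for t in range(2, T + 1)}
    for c in covariates:
        g = {s: ct.loc[(s, c), "coef"] for s in range(1, T + 1)}
        g_se = {s: ct.loc[(s, c), "se"] for s in range(1, T + 1)}
        for t in range(2, T + 1):
            eff = 0.0
            dg = {s: 0.0 for s in range(1, t)}  # d I_t / d gamma_s
            dl = {u: 0.0 for u in range(2, t + 1)}  # d I_t / d lambda_u
            for s in range(1, t):
                chain = np.prod([lam[u] for u in range(s + 1, t + 1)])
                eff += g[s] * chain
                dg[s] += chain
                for u in range(s + 1, t + 1):
                    rest = np.prod(
                        [lam[v] for v in range(s + 1, t + 1) if v != u]
                    )
                    dl[u] += g[s] * rest
            var = sum(dg[s] ** 2 * g_se[s] ** 2 for s in dg)
            var += sum(dl[u] ** 2 * lam_se[u] ** 2 for u in dl)
            se_eff = float(np.sqrt(var))
            zst = eff / se_eff if se_eff > 0 else 0.0
            ind_rows.append(
                (t, c, eff, se_eff, 2.0 * stats.norm.sf(abs(zst)))
            )
    indirect = pd.DataFrame(
        ind_rows, columns=["visit", "term", "coef", "se", "p"]
    )
    return PathModelFit(
        coef_table=coef_table,
        indirect_table=indirect,
        loglik_model=ll_model,
        loglik_saturated=ll_sat,
        loglik_independence=ll_ind,
        df_model=p_sat - p_model,
        df_independence=p_sat - p_ind,
        n=n,
        n_visits=T,
    )


@dataclass
class FitIndices:
    rmsea: float
    cfi: float
    tli: float
    model_ok: bool
    df_zero_warning: bool = False

    def __post_init__(self) -> None:
        expect = (
            self.rmsea < 0.06 and self.cfi >= 0.95 and self.tli >= 0.95
        )
        if self.model_ok != expect:
            raise ValueError("model_ok inconsistent with index thresholds")


def compute_fit_indices(fit: PathModelFit, n: int | None = None) -> FitIndices:
    """RMSEA / CFI / TLI from likelihood-ratio discrepancies.

    chi2_model = 2(ll_saturated - ll_model) on df_model; the independence
    baseline leaves every visit unexplained.  Adequacy gates: RMSEA < 0.06
    and CFI, TLI >= 0.95.
    """
    if n is None:
        n = fit.n
    chi2_m = max(2.0 * (fit.loglik_saturated - fit.loglik_model), 0.0)
    chi2_i = max(2.0 * (fit.loglik_saturated - fit.loglik_independence), 0.0)
    df_m, df_i = fit.df_model, fit.df_independence
    warn = False
    if df_m == 0:
        rmsea = 0.0
        warn = True
    else:
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * n)))
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_i - df_i, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else float(1.0 - num / den)
    if df_m == 0 or df_i == 0 or chi2_i / max(df_i, 1) <= 1.0:
        tli = 1.0
    else:
        tli = float(
            ((chi2_i / df_i) - (chi2_m / df_m)) / ((chi2_i / df_i) - 1.0)
        )
    ok = rmsea < 0.06 and cfi >= 0.95 and tli >= 0.95
    return FitIndices(rmsea=rmsea, cfi=cfi, tli=tli, model_ok=ok,
                      df_zero_warning=warn)


def select_covariates(
    fits: dict[str, PathModelFit],
    alpha: float = 0.05,
    min_models: int = 2,
    min_timepoints: int = 2,
    include_indirect: bool = True,
) -> set[str]:
    """Retain covariates significant at >=2 time points in >=2 SNP models.

    A time point counts when the covariate's direct path — or, with
    ``include_indirect`` (default), its lag-mediated indirect path into that
    visit — is significant at ``alpha``.  Counting indirect paths matters
    because the lag absorbs a stable covariate's direct effect at later
    visits.
    """
    if len(fits) < min_models:
        raise ValueError(f"need at least {min_models} SNP models")
    retained: set[str] = set()
    any_fit = next(iter(fits.values()))
    cand = [
        t
        for t in any_fit.coef_table["term"].unique()
        if t not in ("const", "lag", "snp")
    ]
    for c in cand:
        n_models = 0
        for f in fits.values():
            sub = f.coef_table[f.coef_table["term"] == c]
            visits = set(sub.loc[sub["p"] < alpha, "visit"])
            if include_indirect and len(f.indirect_table):
                ind = f.indirect_table[f.indirect_table["term"] == c]
                visits |= set(ind.loc[ind["p"] < alpha, "visit"])
            if len(visits) >= min_timepoints:
                n_models += 1
        if n_models >= min_models:
            retained.add(c)
    return retained
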