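"""Kinship-aware mixed-model genome-wide association on trajectory traits.

Traits are the pairwise class indicators (each comparison class against the
lowest-risk class as referent) and the ordinal class rank treated as a
continuous outcome.  Testing is two-stage: variance components of
y = Xb + g + e with cov(g) = 2*Phi*sigma_g^2 are estimated once under the
null covariates (intercept + principal components), the model is rotated to
the eigenbasis where the null covariance is diagonal, and each SNP is then
tested by ordinary least squares on the rotated data — generalised least
squares under the fixed null covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import _profile_reml, estimate_h2
from .kinship import KinshipMatrix
from .lcgm import ClassAssignment
from .popstruct import PCResult
from .simulate import GenotypeMatrix

GWS_P = 1.3e-7
SUGGESTIVE_P = 1.6e-6


@dataclass
class TraitSet:
    """Pairwise (referent = rank-1 class) and ordinal trajectory traits."""

    table: pd.DataFrame = field(repr=False)  # individual_id + trait columns

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.table.columns if c != "individual_id"]


def build_traits(assign: ClassAssignment) -> TraitSet:
    """Derive the GWA trait set from a ranked class assignment.

    Pairwise trait ``pair{k}``: 1 for rank-k individuals, 0 for rank-1
    (referent) individuals, missing for everyone else, k = 2..K.  Ordinal
    trait: the rank label 1..K as a number.
    """
    if assign.rank is None:
        raise ValueError("assignment must be ranked first (rank_classes)")
    K = assign.K
    if K < 2:
        raise ValueError("need at least 2 classes for association traits")
    out = pd.DataFrame({"individual_id": assign.individual_ids})
    rank = assign.rank
    for k in range(2, K + 1):
        col = np.full(len(rank), np.nan)
        col[rank == 1] = 0.0
        col[rank == k] = 1.0
        out[f"pair{k}"] = col
    out["ordinal"] = rank.astype(float)
    return TraitSet(out)


@dataclass
class AssocResult:
    """Per-SNP association table for one trait."""

    trait: str
    table: pd.DataFrame = field(repr=False)
    h2_null: float = np.nan
    n_used: int = 0

    COLUMNS = [
        "CHR", "POS", "SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "TIER",
    ]


def run_mixed_gwa(
    trait: np.ndarray,
    gen: GenotypeMatrix,
    K: KinshipMatrix,
    pcs: PCResult | None = None,
    maf_min: float = 0.01,
    covariates: np.ndarray | None = None,
    trait_name: str = "trait",
    exact: bool = False,
) -> AssocResult:
    """Two-stage (EMMAX-style) mixed-model scan of every SNP on one trait.

    ``trait`` is aligned to ``gen.sample_ids`` (NaN = not in this analysis).
    Null fixed effects are intercept + top PCs (+ optional extra covariates);
    SNPs with minor allele frequency below ``maf_min`` *in the analysed
    subsample* are excluded, and missing dosages are mean-imputed per SNP.
    ``exact=True`` re-estimates the variance components jointly per SNP
    (slow; for small problems and cross-checking the two-stage shortcut).
    """
    y = np.asarray(trait, dtype=float)
    if y.shape != (gen.n_individuals,):
        raise ValueError("trait not aligned to genotype sample ordering")
    X_extra = []
    if pcs is not None:
        if not np.array_equal(pcs.sample_ids, gen.sample_ids):
            raise ValueError("PC scores not aligned to genotype samples")
        X_extra.append(pcs.scores)
    if covariates is not None:
        X_extra.append(np.asarray(covariates, dtype=float))
    Kal = K.align(gen.sample_ids)

    keep = ~np.isnan(y)
    for xa in X_extra:
        keep &= ~np.isnan(xa).any(axis=1)
    idx = np.where(keep)[0]
    if idx.size < 10:
        raise ValueError("too few non-missing individuals")
    y = y[idx]
    if np.nanstd(y) == 0:
        raise ValueError("trait is constant in the analysed subsample")
    X = np.ones((idx.size, 1))
    if X_extra:
        X = np.column_stack([X] + [xa[idx] for xa in X_extra])

    # stage 1: null variance components on A = 2*Phi
    A = Kal.relationship[np.ix_(idx, idx)]
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    yt, xt = U.T @ y, U.T @ X
    hmax = 1.0 if d.min() > 1e-8 else 1.0 - 1e-8
    from scipy import optimize

    res = optimize.minimize_scalar(
        lambda h: -_profile_reml(h, yt, xt, d)[0],
        bounds=(0.0, hmax), method="bounded",
    )
    cands = [0.0, float(res.x), hmax]
    h2 = max(cands, key=lambda h: _profile_reml(h, yt, xt, d)[0])
    w = h2 * d + (1.0 - h2)
    rot = U / np.sqrt(w)  # columns scaled: rot.T @ v whitens v

    # stage 2: GLS per SNP == OLS on the whitened data
    dos = gen.dosages[idx]
    col_mean = np.nanmean(dos, axis=0)
    eaf = col_mean / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    snp_keep = np.where(maf > maf_min)[0]
    dos = np.where(np.isnan(dos), col_mean, dos)[:, snp_keep]

    if exact:
        Ksub = KinshipMatrix(gen.sample_ids[idx], Kal.phi[np.ix_(idx, idx)])
        extra = X[:, 1:] if X.shape[1] > 1 else None
        rows = []
        for jpos, j in enumerate(snp_keep):
            x = dos[:, jpos]
            cov_j = x[:, None] if extra is None else np.column_stack([x, extra])
            r = estimate_h2(y, cov_j, Ksub)
            V = r.sigma_g2 * A + r.sigma_e2 * np.eye(idx.size)
            Xf = np.column_stack([np.ones(idx.size), cov_j])
            Vi = np.linalg.inv(V)
            xtvx = Xf.T @ Vi @ Xf
            bhat = np.linalg.solve(xtvx, Xf.T @ Vi @ y)
            covb = np.linalg.inv(xtvx)
            b, s = float(bhat[1]), float(np.sqrt(covb[1, 1]))
            pv = 2.0 * stats.norm.sf(abs(b / s)) if s > 0 else 1.0
            rows.append((b, s, pv))
        beta, se, pvals = map(np.asarray, zip(*rows))
        meta = gen.snp_meta.iloc[snp_keep]
        table = pd.DataFrame(
            {
                "CHR": meta["chromosome"].to_numpy(),
                "POS": meta["position"].to_numpy(),
                "SNP": meta["snp_id"].to_numpy(),
                "EA": meta["effect_allele"].to_numpy(),
                "OA": meta["other_allele"].to_numpy(),
                "EAF": eaf[snp_keep],
                "BETA": beta,
                "SE": se,
                "P": np.clip(pvals, np.nextafter(0, 1), 1.0),
            }
        )
        return flag_significance(
            AssocResult(trait=trait_name, table=table, h2_null=h2,
                        n_used=idx.size)
        )

    yw = rot.T @ y
    Xw = rot.T @ X
    Gw = rot.T @ dos
    # residualise on the null covariates
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Gr = Gw - Q @ (Q.T @ Gw)
    gg = (Gr**2).sum(axis=0)
    gg[gg == 0] = np.nan
    beta = (Gr * yr[:, None]).sum(axis=0) / gg
    dfres = idx.size - X.shape[1] - 1
    rss = (yr**2).sum() - beta**2 * gg
    sigma2 = rss / dfres
    se = np.sqrt(sigma2 / gg)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dfres)

    meta = gen.snp_meta.iloc[snp_keep]
    table = pd.DataFrame(
        {
            "CHR": meta["chromosome"].to_numpy(),
            "POS": meta["position"].to_numpy(),
            "SNP": meta["snp_id"].to_numpy(),
            "EA": meta["effect_allele"].to_numpy(),
            "OA": meta["other_allele"].to_numpy(),
            "EAF": eaf[snp_keep],
            "BETA": beta,
            "SE": se,
            "P": np.clip(pvals, np.nextafter(0, 1), 1.0),
        }
    ).dropna(subset=["BETA"])
    result = AssocResult(
        trait=trait_name, table=table, h2_null=h2, n_used=idx.size
    )
    return flag_significance(result)


def exact_mixed_gwa_beta(
    trait: np.ndarray,
    snp: np.ndarray,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
) -> float:
    """Per-SNP joint REML effect estimate (slow exact route, oracle use)."""
    y = np.asarray(trait, dtype=float)
    X = snp[:, None] if covariates is None else np.column_stack(
        [snp, covariates]
    )
    res = estimate_h2(y, X, K)
    A = K.relationship
    n = len(y)
    V = res.sigma_g2 * A + res.sigma_e2 * np.eye(n)
    Xf = np.column_stack([np.ones(n), X])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(Xf.T @ Vi @ Xf, Xf.T @ Vi @ y)
    return float(beta[1])


def flag_significance(
    result: AssocResult,
    gws: float = GWS_P,
    suggestive: float = SUGGESTIVE_P,
) -> AssocResult:
    """Assign significance tiers: gws (p < 1.3E-7), suggestive (< 1.6E-6)."""
    tab = result.table.copy()
    p = tab["P"].to_numpy()
    tier = np.where(p < gws, "gws", np.where(p < suggestive, "suggestive", "none"))
    tab["TIER"] = tier
    result.table = tab[AssocResult.COLUMNS]
    return result


def genomic_lambda(pvals: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ coordinates.

    lambda = median of the chi-square(1) statistics implied by the p-values
    divided by the chi-square(1) median (0.4549...).  Also returns expected
    vs observed -log10(p) for a QQ plot.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    srt = np.sort(p)
    n = srt.size
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
            "observed": -np.log10(srt),
        }
    )
    return lam, qq
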