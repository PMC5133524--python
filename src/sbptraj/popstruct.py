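"""LD pruning and founder-based principal components.

Pruning is greedy within a sliding window: the later SNP of any pair with
squared Pearson correlation above the threshold is dropped.  PCA is computed
on the unrelated founders only (dosages centred at twice the founder allele
frequency and scaled by the binomial SD), then every individual — founder or
not — is projected onto the founder loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .simulate import GenotypeMatrix


def ld_prune(
    gen: GenotypeMatrix,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
    sample_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of SNPs surviving sliding-window r^2 pruning, per chromosome.

    ``sample_idx`` restricts the correlation estimates to a subsample
    (typically founders).  Within each window the later SNP of any retained
    pair with r^2 > ``r2_max`` is removed; the window advances by ``step``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    dos = gen.dosages if sample_idx is None else gen.dosages[sample_idx]
    # mean-impute and standardise once; correlations are then dot products
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    z = dos - dos.mean(axis=0)
    sd = z.std(axis=0)
    constant = sd == 0
    sd[constant] = 1.0
    z = z / sd
    nrow = z.shape[0]
    keep = np.ones(gen.n_snps, dtype=bool)
    chroms = gen.snp_meta["chromosome"].to_numpy()
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            r2 = (z[:, win].T @ z[:, win] / nrow) ** 2
            for a in range(len(win)):
                if not keep[win[a]] or constant[win[a]]:
                    continue
                for b in range(a + 1, len(win)):
                    if keep[win[b]] and not constant[win[b]] and r2[a, b] > r2_max:
                        keep[win[b]] = False
            if start + window >= len(idx):
                break
            start += step
    return np.where(keep)[0]


@dataclass
class PCResult:
    """Founder-PCA loadings, all-individual scores, and eigenvalues."""

    sample_ids: np.ndarray
    scores: np.ndarray = field(repr=False)  # individuals x m
    loadings: np.ndarray = field(repr=False)  # SNPs x m
    eigenvalues: np.ndarray = field(repr=False)
    snp_idx: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if (np.diff(self.eigenvalues) > 1e-9).any():
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"individual_id": self.sample_ids})
        for j in range(self.m):
            out[f"PC{j + 1}"] = self.scores[:, j]
        return out


def founder_pca(
    gen: GenotypeMatrix,
    ped: Pedigree,
    pruned: np.ndarray | None = None,
    m: int = 4,
) -> PCResult:
    """Top-``m`` principal components from unrelated founders.

    Founder dosages at the pruned SNPs are centred at 2p and scaled by
    sqrt(2p(1-p)) with p the founder allele frequency; the founder covariance
    is eigendecomposed and all individuals are projected onto the loadings.
    """
    pos = {v: i for i, v in enumerate(gen.sample_ids)}
    f_idx = np.array([pos[i] for i in ped.founders() if i in pos])
    if len(f_idx) < m:
        raise ValueError(f"need at least m={m} founders, have {len(f_idx)}")
    snp_idx = (
        np.arange(gen.n_snps) if pruned is None else np.asarray(pruned)
    )
    dos = gen.dosages[:, snp_idx].copy()
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    fd = dos[f_idx]
    p = fd.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no SNP polymorphic among founders")
    snp_idx = snp_idx[poly]
    dos, fd, p = dos[:, poly], fd[:, poly], p[poly]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    Zf = (fd - 2.0 * p) / scale
    # eigendecomposition via SVD of the founder matrix
    U, s, Vt = np.linalg.svd(Zf, full_matrices=False)
    m_eff = min(m, len(s))
    if m_eff < m:
        raise ValueError("not enough variation for the requested components")
    eig = (s**2) / (len(f_idx) - 1)
    loadings = Vt[:m].T  # SNPs x m, orthonormal
    Zall = (dos - 2.0 * p) / scale
    scores = Zall @ loadings
    return PCResult(
        sample_ids=gen.sample_ids.copy(),
        scores=scores,
        loadings=loadings,
        eigenvalues=eig[:m],
        snp_idx=snp_idx,
    )
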