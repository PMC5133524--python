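"""Synthetic family genotypes and longitudinal SBP phenotypes.

Genotypes are produced by gene dropping: founder alleles are drawn at a
per-SNP allele frequency and every non-founder receives one allele from each
parent, so Mendelian consistency holds by construction.  Phenotypes follow a
latent-class growth structure: a pedigree-spread polygenic value plus an
independent environmental deviation form a liability that is thresholded into
trajectory classes, and observed SBP is the class-specific quadratic age
curve plus sex effect, polygenic value and visit-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .pedigree import Pedigree

_BASES = np.array(list("ACGT"))

#: internal age standardisation used for polynomial coefficients
AGE_CENTER = 45.0
AGE_SCALE = 10.0


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (individuals x SNPs) with per-SNP metadata.

    ``dosages`` counts copies of the effect allele (0/1/2, NaN = missing);
    ``snp_meta`` has columns ``snp_id, chromosome, position, effect_allele,
    other_allele, eaf`` with ``eaf`` equal to the observed mean dosage / 2.
    """

    sample_ids: np.ndarray
    dosages: np.ndarray = field(repr=False)
    snp_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError("dosage matrix shape does not match ids/meta")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        for chrom, grp in self.snp_meta.groupby("chromosome"):
            pos = grp["position"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.snp_meta["eaf"] = self.observed_eaf()

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    def observed_eaf(self) -> np.ndarray:
        """Effect-allele frequency: mean dosage / 2 over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        eaf = self.observed_eaf()
        return np.minimum(eaf, 1.0 - eaf)

    def subset_snps(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        meta = self.snp_meta.iloc[np.asarray(mask_or_idx)].reset_index(drop=True)
        return GenotypeMatrix(
            self.sample_ids, self.dosages[:, np.asarray(mask_or_idx)], meta
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.sample_ids[idx], self.dosages[idx], self.snp_meta.copy()
        )


@dataclass
class LongitudinalPhenotypes:
    """Long-format visit records.

    Columns: ``family_id, individual_id, visit, age, sbp, med_use, sex,
    smoking``.  Ages are strictly increasing within individual, at most 4
    visits each, SBP positive.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = [
        "family_id",
        "individual_id",
        "visit",
        "age",
        "sbp",
        "med_use",
        "sex",
        "smoking",
    ]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        tab = self.table[self.COLUMNS].copy()
        tab = tab.sort_values(["individual_id", "age"], kind="mergesort")
        if (tab["sbp"] <= 0).any():
            raise ValueError("sbp must be positive")
        counts = tab.groupby("individual_id", sort=False).size()
        if (counts > 4).any():
            raise ValueError("more than 4 visits for an individual")
        diffs = tab.groupby("individual_id", sort=False)["age"].diff().dropna()
        if (diffs <= 0).any():
            raise ValueError("ages not strictly increasing within individual")
        self.table = tab.reset_index(drop=True)

    @property
    def individuals(self) -> np.ndarray:
        return self.table["individual_id"].unique()

    def visit_counts(self) -> pd.Series:
        return self.table.groupby("individual_id", sort=False).size()


@dataclass
class TruthRecord:
    """Simulation ground truth for recovery tests."""

    per_individual: pd.DataFrame  # individual_id, true_class, polygenic
    class_coefs: np.ndarray  # K x 3 on the standardised-age scale
    class_props: np.ndarray
    sex_effect: float
    residual_sd: float
    liability_h2: float

    def __post_init__(self) -> None:
        k = len(self.class_coefs)
        labels = self.per_individual["true_class"]
        if not labels.isin(range(1, k + 1)).all():
            raise ValueError("true_class labels must lie in 1..K_true")
        if not 0.0 <= self.liability_h2 <= 1.0:
            raise ValueError("liability_h2 must be in [0, 1]")


_SCENARIO_FIELDS = {
    "k_true",
    "class_props",
    "class_coefs",
    "sex_effect",
    "smoking_effect",
    "smoking_prev",
    "residual_sd",
    "polygenic_var",
    "liability_env_var",
    "n_visits",
    "baseline_age_range",
    "gap_range",
    "max_span",
    "missing_rate",
    "med_center",
    "med_scale",
}


@dataclass
class ScenarioConfig:
    """Generative settings for :func:`simulate_phenotypes`.

    ``class_coefs`` are per-class (intercept, linear, quadratic) coefficients
    over standardised age ``(age - 45) / 10``; ``polygenic_var`` and
    ``liability_env_var`` are the genetic and environmental variances of the
    class liability (their ratio sets the liability heritability), and the
    polygenic value also enters SBP directly in mm Hg.  Medication use is
    logistic in the latent (noise-free) SBP with location ``med_center`` and
    scale ``med_scale``; visits are deleted completely at random at
    ``missing_rate``.
    """

    k_true: int
    class_props: tuple[float, ...]
    class_coefs: tuple[tuple[float, float, float], ...]
    sex_effect: float = 6.0
    smoking_effect: float = 0.0
    smoking_prev: float = 0.2
    residual_sd: float = 10.0
    polygenic_var: float = 9.0
    liability_env_var: float = 9.0
    n_visits: int = 4
    baseline_age_range: tuple[float, float] = (25.0, 60.0)
    gap_range: tuple[float, float] = (4.0, 6.5)
    max_span: float = 17.0
    missing_rate: float = 0.12
    med_center: float = 161.0
    med_scale: float = 9.0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ScenarioError("k_true must be >= 1")
        props = np.asarray(self.class_props, dtype=float)
        if len(props) != self.k_true or (props <= 0).any():
            raise ScenarioError("class_props must be k_true positive fractions")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ScenarioError("class proportions must sum to 1")
        if len(self.class_coefs) != self.k_true:
            raise ScenarioError("need one coefficient triple per class")
        if self.residual_sd < 0 or self.polygenic_var < 0:
            raise ScenarioError("variances must be nonnegative")
        if self.liability_env_var < 0:
            raise ScenarioError("liability_env_var must be nonnegative")
        if self.k_true > 1 and self.polygenic_var + self.liability_env_var <= 0:
            raise ScenarioError("class liability needs positive total variance")
        if not 0 <= self.missing_rate < 1:
            raise ScenarioError("missing_rate must be in [0, 1)")
        if not 2 <= self.n_visits <= 4:
            raise ScenarioError("n_visits must be between 2 and 4")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        unknown = set(d) - _SCENARIO_FIELDS
        if unknown:
            raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("class_coefs",):
            if key in d:
                d[key] = tuple(tuple(float(x) for x in row) for row in d[key])
        for key in ("class_props", "baseline_age_range", "gap_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)

    @classmethod
    def from_flat_file(cls, path) -> "ScenarioConfig":
        """Flat ``key = value`` scenario file.

        Lists are comma-separated (``class_props = 0.5, 0.5``); the per-class
        coefficient triples are semicolon-separated
        (``class_coefs = 113,5,0.8; 124,7,1.2``).  Unknown keys are rejected.
        """
        from .io import read_flat_config

        raw = read_flat_config(path)
        d: dict = {}
        for k, v in raw.items():
            if k == "class_coefs":
                d[k] = [
                    [float(x) for x in row.split(",")]
                    for row in v.split(";")
                ]
            elif k in ("class_props", "baseline_age_range", "gap_range"):
                d[k] = [float(x) for x in v.split(",")]
            elif k in ("k_true", "n_visits"):
                d[k] = int(v)
            else:
                d[k] = float(v)
        return cls.from_dict(d)

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)

    @property
    def liability_h2(self) -> float:
        tot = self.polygenic_var + self.liability_env_var
        return 0.0 if tot == 0 else self.polygenic_var / tot


def reference_scenario() -> ScenarioConfig:
    """Default study-like scenario: 5 trajectory classes over ages 25-77.

    Curves are well separated clinically plausible SBP trajectories (lowest
    class normotensive and stable, highest class hypertensive and steeply
    rising); class proportions (0.40, 0.22, 0.18, 0.13, 0.07); residual SD
    10 mm Hg; liability heritability 0.5.
    """
    return ScenarioConfig(
        k_true=5,
        class_props=(0.40, 0.22, 0.18, 0.13, 0.07),
        class_coefs=(
            (113.0, 5.0, 0.8),
            (124.0, 7.0, 1.2),
            (136.0, 9.0, 1.5),
            (149.0, 11.0, 2.0),
            (165.0, 13.0, 2.5),
        ),
    )


def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    maf_range: tuple[float, float],
    seed: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Gene-drop ``n_snps`` unlinked biallelic SNPs through a pedigree.

    Per SNP, an effect-allele frequency is drawn uniformly in ``maf_range``
    (folded to MAF, i.e. the effect allele may be major or minor with equal
    probability); founders get Binomial(2, freq) dosages and each non-founder
    inherits one allele from each parent (a heterozygous parent transmits the
    effect allele with probability 1/2).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if ped.n == 0:
        raise ValueError("empty pedigree")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    # effect allele is minor or major with equal probability
    flip = rng.random(n_snps) < 0.5
    freq = np.where(flip, 1.0 - maf, maf)

    dos = np.empty((ped.n, n_snps))
    founder = ped.is_founder()
    fa_idx, mo_idx = ped.parent_indices()
    for i in ped.topological_order():
        if founder[i]:
            dos[i] = rng.binomial(2, freq)
        else:
            pat = rng.random(n_snps) < dos[fa_idx[i]] / 2.0
            mat = rng.random(n_snps) < dos[mo_idx[i]] / 2.0
            dos[i] = pat.astype(float) + mat.astype(float)
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan

    alle = np.empty((n_snps, 2), dtype=object)
    for j in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        alle[j] = _BASES[a], _BASES[b]
    chroms = np.sort(rng.integers(1, 23, size=n_snps))
    pos = np.empty(n_snps, dtype=np.int64)
    for c in np.unique(chroms):
        m = chroms == c
        raw = np.sort(rng.integers(1, 250_000_000, size=m.sum()))
        pos[m] = raw + np.arange(m.sum())  # break ties, keep strict order
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
            "chromosome": chroms,
            "position": pos,
            "effect_allele": alle[:, 0],
            "other_allele": alle[:, 1],
            "eaf": freq,
        }
    )
    return GenotypeMatrix(ped.individual_ids.copy(), dos, meta)


def mendelian_error_count(ped: Pedigree, gen: GenotypeMatrix) -> int:
    """Number of (child, SNP) dosage combinations impossible under Mendel.

    A parent with dosage 0 transmits 0 effect alleles, dosage 2 transmits 1,
    dosage 1 either; a child dosage outside the attainable [min, max] range
    of transmitted counts is an error.  Missing dosages are skipped.
    """
    fa_idx, mo_idx = ped.parent_indices()
    child = np.where((fa_idx >= 0) & (mo_idx >= 0))[0]
    if child.size == 0:
        return 0
    d_c = gen.dosages[child]
    d_f = gen.dosages[fa_idx[child]]
    d_m = gen.dosages[mo_idx[child]]
    lo = (d_f == 2).astype(float) + (d_m == 2).astype(float)
    hi = (d_f >= 1).astype(float) + (d_m >= 1).astype(float)
    ok = (d_c >= lo) & (d_c <= hi)
    ok |= np.isnan(d_c) | np.isnan(d_f) | np.isnan(d_m)
    return int((~ok).sum())


def snp_qc(
    gen: GenotypeMatrix,
    ped: Pedigree | None = None,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop monomorphic SNPs and SNPs failing founder Hardy-Weinberg.

    The HWE chi-square test (1 df) is run on founder genotype counts when a
    pedigree is supplied, otherwise on all individuals.  Returns the filtered
    matrix and a per-SNP report with columns ``snp_id, reason``.
    """
    eaf = gen.observed_eaf()
    mono = (eaf <= 0.0) | (eaf >= 1.0)
    hwe_fail = np.zeros(gen.n_snps, dtype=bool)
    sub = gen.dosages
    if ped is not None:
        sub = gen.dosages[ped.is_founder()]
    for j in range(gen.n_snps):
        if mono[j]:
            continue
        d = sub[:, j]
        d = d[~np.isnan(d)]
        n = d.size
        if n == 0:
            continue
        p = d.mean() / 2.0
        if p <= 0 or p >= 1:
            continue
        obs = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()])
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        hwe_fail[j] = stats.chi2.sf(chi2, df=1) < hwe_alpha
    reasons = []
    for j in range(gen.n_snps):
        if mono[j]:
            reasons.append((gen.snp_meta["snp_id"].iloc[j], "monomorphic"))
        elif hwe_fail[j]:
            reasons.append((gen.snp_meta["snp_id"].iloc[j], "hwe"))
    keep = ~(mono | hwe_fail)
    report = pd.DataFrame(reasons, columns=["snp_id", "reason"])
    return gen.subset_snps(np.where(keep)[0]), report


def _drop_polygenic(ped: Pedigree, var_g: float, rng: np.random.Generator) -> np.ndarray:
    """Spread additive polygenic values through the pedigree.

    Founders draw N(0, var_g); each child gets the parental midpoint plus
    Mendelian segregation noise N(0, var_g / 2), so cov(g) = 2*kinship*var_g
    for non-inbred pedigrees.
    """
    g = np.zeros(ped.n)
    if var_g == 0:
        return g
    founder = ped.is_founder()
    fa_idx, mo_idx = ped.parent_indices()
    sd_f = np.sqrt(var_g)
    sd_seg = np.sqrt(var_g / 2.0)
    for i in ped.topological_order():
        if founder[i]:
            g[i] = rng.normal(0.0, sd_f)
        else:
            g[i] = 0.5 * (g[fa_idx[i]] + g[mo_idx[i]]) + rng.normal(0.0, sd_seg)
    return g


def class_mean_sbp(
    coefs: np.ndarray | tuple, age: np.ndarray | float
) -> np.ndarray:
    """Evaluate a class polynomial at raw age (coefs on standardised age)."""
    c = (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE
    b = np.asarray(coefs, dtype=float)
    return b[0] + b[1] * c + b[2] * c**2


def simulate_phenotypes(
    ped: Pedigree,
    gen: GenotypeMatrix | None,
    scenario: ScenarioConfig,
    seed: int,
) -> tuple[LongitudinalPhenotypes, TruthRecord]:
    """Draw longitudinal SBP visits with latent-class and polygenic structure.

    The genotype matrix is accepted for interface symmetry (class liability
    is polygenic-background driven, not single-SNP driven) and may be None.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    sc = scenario

    g = _drop_polygenic(ped, sc.polygenic_var, rng)
    if sc.k_true == 1:
        true_class = np.ones(n, dtype=int)
    else:
        liability = g + rng.normal(0.0, np.sqrt(sc.liability_env_var), size=n)
        tot_sd = np.sqrt(sc.polygenic_var + sc.liability_env_var)
        cuts = stats.norm.ppf(np.cumsum(sc.class_props)[:-1], scale=tot_sd)
        true_class = np.searchsorted(cuts, liability) + 1

    male = (ped.table["sex"] == "male").to_numpy()
    smoker = rng.random(n) < sc.smoking_prev

    # visit design: baseline age + uniform gaps rescaled into the max span
    base = rng.uniform(*sc.baseline_age_range, size=n)
    gaps = rng.uniform(*sc.gap_range, size=(n, sc.n_visits - 1))
    tot = gaps.sum(axis=1)
    over = tot > sc.max_span
    gaps[over] *= (sc.max_span / tot[over])[:, None]
    ages = base[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1
    )

    coefs = np.asarray(sc.class_coefs, dtype=float)
    cstd = (ages - AGE_CENTER) / AGE_SCALE
    mean_traj = (
        coefs[true_class - 1, 0][:, None]
        + coefs[true_class - 1, 1][:, None] * cstd
        + coefs[true_class - 1, 2][:, None] * cstd**2
    )
    latent = (
        mean_traj
        + sc.sex_effect * male[:, None]
        + sc.smoking_effect * smoker[:, None]
        + g[:, None]
    )
    med = rng.random((n, sc.n_visits)) < expit((latent - sc.med_center) / sc.med_scale)
    sbp = latent + rng.normal(0.0, sc.residual_sd, size=(n, sc.n_visits))
    keep = rng.random((n, sc.n_visits)) >= sc.missing_rate

    ii, jj = np.where(keep)
    tab = pd.DataFrame(
        {
            "family_id": ped.table["family_id"].to_numpy()[ii],
            "individual_id": ped.individual_ids[ii],
            "visit": jj + 1,
            "age": ages[ii, jj],
            "sbp": sbp[ii, jj],
            "med_use": med[ii, jj],
            "sex": ped.table["sex"].to_numpy()[ii],
            "smoking": smoker[ii],
        }
    )
    truth = TruthRecord(
        per_individual=pd.DataFrame(
            {
                "individual_id": ped.individual_ids,
                "true_class": true_class,
                "polygenic": g,
            }
        ),
        class_coefs=coefs,
        class_props=np.asarray(sc.class_props),
        sex_effect=sc.sex_effect,
        residual_sd=sc.residual_sd,
        liability_h2=sc.liability_h2,
    )
    return LongitudinalPhenotypes(tab), truth
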