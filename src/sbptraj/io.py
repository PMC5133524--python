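"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as PLINK-style PED/MAP text (primary dialect) or VCF v4.2
with GT only; pedigrees as FAM; phenotypes as long-format CSV.  Dosages
count the effect allele, which is the second allele column of the MAP file
and the ALT allele of a VCF.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .pedigree import MISSING_PARENT, Pedigree
from .simulate import GenotypeMatrix, LongitudinalPhenotypes


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# -- FAM ---------------------------------------------------------------------

_SEX_TO_PLINK = {"male": "1", "female": "2"}
_PLINK_TO_SEX = {"1": "male", "2": "female"}


def write_fam(ped: Pedigree, path) -> None:
    tab = ped.table
    out = pd.DataFrame(
        {
            "fid": tab["family_id"],
            "iid": tab["individual_id"],
            "pat": tab["father_id"],
            "mat": tab["mother_id"],
            "sex": tab["sex"].map(_SEX_TO_PLINK),
            "pheno": "-9",
        }
    )
    out.to_csv(path, sep=" ", header=False, index=False)


def read_fam(path) -> Pedigree:
    tab = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    bad = ~tab["sex"].isin(_PLINK_TO_SEX)
    if bad.any():
        raise FormatError(f"line {bad.idxmax() + 1}: bad sex code {tab.loc[bad.idxmax(), 'sex']!r}")
    return Pedigree(
        pd.DataFrame(
            {
                "family_id": tab["fid"],
                "individual_id": tab["iid"],
                "father_id": tab["pat"],
                "mother_id": tab["mat"],
                "sex": tab["sex"].map(_PLINK_TO_SEX),
            }
        )
    )


# -- PED / MAP ---------------------------------------------------------------


def write_ped_map(
    gen: GenotypeMatrix, ped: Pedigree, prefix: str | os.PathLike
) -> tuple[str, str]:
    """Write `<prefix>.ped` and `<prefix>.map`.

    MAP columns: chromosome, snp_id, genetic distance (0), position, plus
    two allele columns (other allele, then the counted effect allele) so the
    dosage orientation survives a round trip; the PED genotype pair for
    dosage d is d copies of the effect allele and 2 - d of the other allele
    ("0 0" when missing).
    """
    prefix = os.fspath(prefix)
    meta = gen.snp_meta
    with open(prefix + ".map", "w") as fh:
        for r in meta.itertuples():
            fh.write(
                f"{r.chromosome}\t{r.snp_id}\t0\t{r.position}"
                f"\t{r.other_allele}\t{r.effect_allele}\n"
            )
    ptab = ped.table.set_index("individual_id")
    ea = meta["effect_allele"].to_numpy()
    oa = meta["other_allele"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, iid in enumerate(gen.sample_ids):
            row = ptab.loc[iid]
            lead = [
                row["family_id"], iid, row["father_id"], row["mother_id"],
                _SEX_TO_PLINK[row["sex"]], "-9",
            ]
            alleles = []
            for j, d in enumerate(gen.dosages[i]):
                if np.isnan(d):
                    alleles += ["0", "0"]
                else:
                    d = int(d)
                    alleles += [ea[j]] * d + [oa[j]] * (2 - d)
            fh.write(" ".join(lead + alleles) + "\n")
    return prefix + ".ped", prefix + ".map"


def read_ped_map(prefix: str | os.PathLike) -> tuple[GenotypeMatrix, Pedigree]:
    """Read `<prefix>.ped` + `<prefix>.map`.

    Dosage counts the effect allele: the MAP's second allele column when
    present (6-column dialect), else the alphabetically second allele code
    observed in the data.
    """
    prefix = os.fspath(prefix)
    mp = pd.read_csv(prefix + ".map", sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] == 4:
        mp.columns = ["chromosome", "snp_id", "cm", "position"]
        mp["a_other"], mp["a_effect"] = None, None
    elif mp.shape[1] == 6:
        mp.columns = ["chromosome", "snp_id", "cm", "position", "a_other", "a_effect"]
    else:
        raise FormatError(f"{prefix}.map: expected 4 or 6 columns, got {mp.shape[1]}")
    mp["chromosome"] = mp["chromosome"].astype(int)
    mp["position"] = mp["position"].astype(int)
    n_snps = len(mp)
    lead_rows, geno_rows = [], []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"line {lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            lead_rows.append(parts[:6])
            geno_rows.append(parts[6:])
    lead = pd.DataFrame(
        lead_rows, columns=["fid", "iid", "pat", "mat", "sex", "pheno"]
    )
    alle = np.asarray(geno_rows, dtype=object).reshape(len(lead), n_snps, 2)
    dosages = np.empty((len(lead), n_snps))
    eff = np.empty(n_snps, dtype=object)
    oth = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        col = alle[:, j, :]
        codes = sorted(set(col.ravel()) - {"0"})
        if len(codes) > 2:
            raise FormatError(
                f"SNP {mp['snp_id'].iloc[j]!r}: more than 2 allele codes {codes}"
            )
        if mp["a_effect"].iloc[j] is not None:
            oth[j], eff[j] = mp["a_other"].iloc[j], mp["a_effect"].iloc[j]
            bad = set(codes) - {oth[j], eff[j]}
            if bad:
                raise FormatError(
                    f"SNP {mp['snp_id'].iloc[j]!r}: allele codes {sorted(bad)} "
                    f"not in MAP alleles ({oth[j]}, {eff[j]})"
                )
        else:
            if not codes:
                raise FormatError(
                    f"SNP {mp['snp_id'].iloc[j]!r}: all genotypes missing"
                )
            if len(codes) == 1:
                codes = codes * 2
            oth[j], eff[j] = codes[0], codes[1]
        missing = (col == "0").any(axis=1)
        dosages[:, j] = (col == eff[j]).sum(axis=1).astype(float)
        dosages[missing, j] = np.nan
    ped = Pedigree(
        pd.DataFrame(
            {
                "family_id": lead["fid"],
                "individual_id": lead["iid"],
                "father_id": lead["pat"],
                "mother_id": lead["mat"],
                "sex": lead["sex"].map(_PLINK_TO_SEX),
            }
        )
    )
    meta = pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "chromosome": mp["chromosome"],
            "position": mp["position"],
            "effect_allele": eff,
            "other_allele": oth,
            "eaf": np.nanmean(dosages, axis=0) / 2.0,
        }
    )
    return GenotypeMatrix(ped.individual_ids.copy(), dosages, meta), ped


# -- VCF ---------------------------------------------------------------------


def write_vcf(gen: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2, GT only; ALT is the effect (counted) allele."""
    meta = gen.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(meta["chromosome"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gen.sample_ids))
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, r in enumerate(meta.itertuples()):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in gen.dosages[:, j]
            ]
            fh.write(
                f"{r.chromosome}\t{r.position}\t{r.snp_id}\t{r.other_allele}\t"
                f"{r.effect_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF via cyvcf2; dosage counts ALT."""
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, meta_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"{var.ID or var.POS}: not biallelic")
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unk,3 hom-alt
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        rows.append(d)
        meta_rows.append(
            (var.ID, int(var.CHROM), var.POS, var.ALT[0], var.REF)
        )
    meta = pd.DataFrame(
        meta_rows,
        columns=["snp_id", "chromosome", "position", "effect_allele", "other_allele"],
    )
    dosages = np.asarray(rows).T
    meta["eaf"] = np.nanmean(dosages, axis=0) / 2.0
    return GenotypeMatrix(samples, dosages, meta)


def read_genotypes(path, fmt: str = "ped_map") -> GenotypeMatrix:
    """Dispatch genotype reading: ``ped_map`` (prefix) or ``vcf`` (file)."""
    if fmt == "ped_map":
        gen, _ = read_ped_map(path)
        return gen
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# -- phenotypes --------------------------------------------------------------


def write_phenotypes(ph: LongitudinalPhenotypes, path) -> None:
    ph.table.to_csv(path, index=False)


def read_phenotypes(path) -> LongitudinalPhenotypes:
    if not os.path.exists(path):
        raise FileNotFoundError(f"phenotype file not found: {path}")
    tab = pd.read_csv(path)
    for col in ("med_use", "smoking"):
        tab[col] = tab[col].astype(bool)
    return LongitudinalPhenotypes(tab)


# -- flat key-value config ---------------------------------------------------


def read_flat_config(path) -> dict[str, str]:
    """`key = value` lines; '#' comments; keys validated by the consumer."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            out[key] = val
    return out


def write_flat_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")
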