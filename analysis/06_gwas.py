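#!/usr/bin/env python
"""Kinship-aware mixed-model GWA on the trajectory traits.

Scans every SNP with MAF > 1% for each pairwise class trait (rank-1 class
as referent) and the ordinal trait, using EMMAX-style two-stage testing with
the top 4 founder PCs as fixed effects.  Flags genome-wide significant
(p < 1.3E-7) and suggestive (p < 1.6E-6) hits and reports the pooled genomic
inflation factor.  Writes one TSV per trait plus QQ data under results/gwas/.
"""

import os

import numpy as np
import pandas as pd

import sbptraj as st
from sbptraj import io as sio
from sbptraj.kinship import KinshipMatrix
from sbptraj.popstruct import PCResult

HERE = os.path.dirname(__file__)
COHORT = os.path.join(HERE, "..", "results", "cohort")
TRAJ = os.path.join(HERE, "..", "results", "trajectories")
HER = os.path.join(HERE, "..", "results", "heritability")
OUT = os.path.join(HERE, "..", "results", "gwas")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    gen, ped = sio.read_ped_map(os.path.join(COHORT, "genotypes"))
    kin = KinshipMatrix.from_tsv(os.path.join(HER, "kinship.tsv"))
    pc_tab = pd.read_csv(os.path.join(HER, "pcs.csv"))
    assign = pd.read_csv(os.path.join(TRAJ, "assignments.csv"))

    pc_tab = pc_tab.set_index("individual_id").reindex(gen.sample_ids)
    pcs = PCResult(
        sample_ids=gen.sample_ids,
        scores=pc_tab.to_numpy(),
        loadings=np.zeros((1, pc_tab.shape[1])),
        eigenvalues=np.zeros(pc_tab.shape[1]),
        snp_idx=np.arange(0),
    )

    K = int(assign["rank"].max())
    rank = assign.set_index("individual_id")["rank"].reindex(gen.sample_ids)
    traits = {}
    for k in range(2, K + 1):
        y = np.full(len(gen.sample_ids), np.nan)
        y[(rank == 1).to_numpy()] = 0.0
        y[(rank == k).to_numpy()] = 1.0
        traits[f"pair{k}"] = y
    traits["ordinal"] = rank.to_numpy().astype(float)

    all_p = []
    for name, y in traits.items():
        res = st.run_mixed_gwa(y, gen, kin, pcs, maf_min=0.01, trait_name=name)
        res.table.to_csv(os.path.join(OUT, f"gwa_{name}.tsv"), sep="\t",
                         index=False)
        tiers = res.table["TIER"].value_counts().to_dict()
        print(f"{name}: {len(res.table)} SNPs (n = {res.n_used}, "
              f"null h2 = {res.h2_null:.2f}), tiers: {tiers}")
        all_p.append(res.table["P"].to_numpy())

    lam, qq = st.genomic_lambda(np.concatenate(all_p))
    qq.to_csv(os.path.join(OUT, "qq.csv"), index=False)
    print(f"pooled genomic inflation lambda = {lam:.3f} "
          f"({sum(map(len, all_p))} tests)")


if __name__ == "__main__":
    main()
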