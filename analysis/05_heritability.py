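#!/usr/bin/env python
"""Pedigree kinship and heritability of the trajectory-class traits.

Computes recursive kinship for the cohort pedigree, then REML heritability
(with the top 4 founder PCs as fixed effects) of each pairwise class trait
(rank-1 class as referent) and of the ordinal 1..K trait.  Also reruns the
variance-component recovery experiment at the extremes of the
trajectory-class heritability range (true h2 = 0.94 and 0.12).  Writes
results/heritability/.
"""

import os

import numpy as np
import pandas as pd

import sbptraj as st
from sbptraj import io as sio
from sbptraj.experiments import H2_PRESETS, replicate_h2_recovery
from sbptraj.kinship import kinship_matrix
from sbptraj.popstruct import founder_pca, ld_prune

HERE = os.path.dirname(__file__)
COHORT = os.path.join(HERE, "..", "results", "cohort")
TRAJ = os.path.join(HERE, "..", "results", "trajectories")
OUT = os.path.join(HERE, "..", "results", "heritability")
RECOVERY_REPLICATES = 25  # the full 100-replicate run lives in scripts/acceptance.py


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    ped = sio.read_fam(os.path.join(COHORT, "pedigree.fam"))
    gen, _ = sio.read_ped_map(os.path.join(COHORT, "genotypes"))
    assign = pd.read_csv(os.path.join(TRAJ, "assignments.csv"))

    kin = kinship_matrix(ped)
    kin.to_tsv(os.path.join(OUT, "kinship.tsv"))
    pruned = ld_prune(gen, 0.2, sample_idx=np.where(ped.is_founder())[0])
    pcs = founder_pca(gen, ped, pruned, m=4)
    pcs.to_frame().to_csv(os.path.join(OUT, "pcs.csv"), index=False)

    K = int(assign["rank"].max())
    ids = assign["individual_id"].to_numpy()
    kin_s = kin.align(ids)
    pc_pos = {v: i for i, v in enumerate(pcs.sample_ids)}
    pc_mat = pcs.scores[[pc_pos[i] for i in ids]]
    rank = assign["rank"].to_numpy()

    rows = []
    for k in range(2, K + 1):
        y = np.full(len(ids), np.nan)
        y[rank == 1] = 0.0
        y[rank == k] = 1.0
        r = st.estimate_h2(y, pc_mat, kin_s)
        rows.append((f"pair{k}", r.h2, r.se, r.p_value))
    r = st.estimate_h2(rank.astype(float), pc_mat, kin_s)
    rows.append(("ordinal", r.h2, r.se, r.p_value))
    tab = pd.DataFrame(rows, columns=["trait", "h2", "se", "p"])
    tab.to_csv(os.path.join(OUT, "heritability.tsv"), sep="\t", index=False)
    print(tab.round(3).to_string(index=False))

    rec_rows = []
    for preset, h2_true in H2_PRESETS.items():
        ests = replicate_h2_recovery(h2_true, RECOVERY_REPLICATES, seed=1)
        rec_rows.append((preset, h2_true, ests.mean(), ests.std()))
        print(f"recovery {preset}: true {h2_true} -> mean estimate "
              f"{ests.mean():.3f} (SD {ests.std():.3f}, "
              f"{RECOVERY_REPLICATES} replicates)")
    pd.DataFrame(
        rec_rows, columns=["preset", "h2_true", "h2_mean", "h2_sd"]
    ).to_csv(os.path.join(OUT, "h2_recovery.csv"), index=False)


if __name__ == "__main__":
    main()
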