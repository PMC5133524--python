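"""Pedigree kinship coefficients (recursive tabular method).

Phi[i, i] = 0.5 * (1 + Phi[father, mother]); Phi[i, j] = 0.5 * (Phi[f, j] +
Phi[m, j]) for a non-founder i with parents f, m and any j that is not a
descendant of i; founders have self-kinship 0.5 and pairwise kinship 0.
The additive relationship matrix is A = 2 * Phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficient matrix aligned to ``ids``."""

    ids: np.ndarray
    phi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match ids")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("phi must be symmetric")
        if (np.diag(self.phi) < 0.5 - 1e-12).any():
            raise ValueError("self-kinship must be >= 0.5")

    @property
    def relationship(self) -> np.ndarray:
        """Additive relationship matrix A = 2 * Phi."""
        return 2.0 * self.phi

    def align(self, ids) -> "KinshipMatrix":
        """Reorder / subset to the given individual ids."""
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return KinshipMatrix(np.asarray(ids, dtype=object), self.phi[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        """Lower triangle (incl. diagonal) as id1, id2, kinship."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1):
                rows.append((self.ids[i], self.ids[j], self.phi[i, j]))
        pd.DataFrame(rows, columns=["id1", "id2", "kinship"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        tab = pd.read_csv(path, sep="\t")
        ids = pd.unique(pd.concat([tab["id1"], tab["id2"]]).astype(str))
        pos = {v: i for i, v in enumerate(ids)}
        n = len(ids)
        phi = np.zeros((n, n))
        for r in tab.itertuples():
            i, j = pos[str(r.id1)], pos[str(r.id2)]
            phi[i, j] = phi[j, i] = r.kinship
        return cls(np.asarray(ids, dtype=object), phi)


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute the pedigree kinship matrix by the recursive tabular method."""
    n = ped.n
    phi = np.zeros((n, n))
    fa, mo = ped.parent_indices()
    order = ped.topological_order()
    for k, i in enumerate(order):
        f, m = fa[i], mo[i]
        prev = order[:k]
        if f < 0 and m < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            vals = 0.5 * (phi[f, prev] + phi[m, prev])
            phi[i, prev] = vals
            phi[prev, i] = vals
    return KinshipMatrix(ped.individual_ids.copy(), phi)


def gene_drop_kinship(
    ped: Pedigree, n_drops: int, seed: int
) -> KinshipMatrix:
    """Monte-Carlo kinship via repeated gene dropping of unique founder alleles.

    Each drop assigns every founder two globally unique allele labels and
    transmits one random allele per parent down the pedigree; the realized
    kinship estimate for (i, j) is the probability that a random allele from
    i matches a random allele from j, averaged over drops.  Independent
    oracle for :func:`kinship_matrix`.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    fa, mo = ped.parent_indices()
    order = ped.topological_order()
    founder = ped.is_founder()
    acc = np.zeros((n, n))
    a1 = np.empty((n_drops, n), dtype=np.int64)
    a2 = np.empty((n_drops, n), dtype=np.int64)
    # vectorise over drops: label founders 2i / 2i+1, drop all replicates at once
    for i in order:
        if founder[i]:
            a1[:, i] = 2 * i
            a2[:, i] = 2 * i + 1
        else:
            pick_f = rng.random(n_drops) < 0.5
            pick_m = rng.random(n_drops) < 0.5
            a1[:, i] = np.where(pick_f, a1[:, fa[i]], a2[:, fa[i]])
            a2[:, i] = np.where(pick_m, a1[:, mo[i]], a2[:, mo[i]])
    for i in range(n):
        for j in range(i, n):
            match = (
                (a1[:, i] == a1[:, j]).astype(float)
                + (a1[:, i] == a2[:, j])
                + (a2[:, i] == a1[:, j])
                + (a2[:, i] == a2[:, j])
            ) / 4.0
            acc[i, j] = acc[j, i] = match.mean()
    return KinshipMatrix(ped.individual_ids.copy(), acc)
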