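"""Pedigree container and simulator.

A pedigree is a table of (family_id, individual_id, father_id, mother_id, sex)
records, FAM-style.  Founders are exactly the individuals with both parents
missing; every named parent must exist in the same family and the parent graph
must be acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, ...)."""


@dataclass
class Pedigree:
    """Family structure table.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``family_id, individual_id, father_id, mother_id, sex``;
        ``father_id``/``mother_id`` are ``"0"`` for founders, ``sex`` is
        ``"male"`` or ``"female"``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
        missing = set(required) - set(self.table.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        tab = self.table[required].astype(
            {c: str for c in required[:4]} | {"sex": str}
        )
        if tab["individual_id"].duplicated().any():
            dup = tab.loc[tab["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise PedigreeError(f"duplicate individual_id {dup!r}")
        bad_sex = set(tab["sex"]) - {"male", "female"}
        if bad_sex:
            raise PedigreeError(f"invalid sex codes: {sorted(bad_sex)}")
        fam_of = dict(zip(tab["individual_id"], tab["family_id"]))
        for pcol in ("father_id", "mother_id"):
            named = tab.loc[tab[pcol] != MISSING_PARENT]
            for iid, pid, fam in zip(
                named["individual_id"], named[pcol], named["family_id"]
            ):
                if pid not in fam_of:
                    raise PedigreeError(f"{pcol} {pid!r} of {iid!r} not in pedigree")
                if fam_of[pid] != fam:
                    raise PedigreeError(
                        f"{pcol} {pid!r} of {iid!r} is in a different family"
                    )
        self.table = tab.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn-style peel: repeatedly remove individuals whose parents are
        # all already removed; leftovers imply a cycle.
        parents = {
            row.individual_id: {
                p for p in (row.father_id, row.mother_id) if p != MISSING_PARENT
            }
            for row in self.table.itertuples()
        }
        done: set[str] = set()
        frontier = [i for i, ps in parents.items() if not ps]
        while frontier:
            done.update(frontier)
            frontier = [
                i
                for i, ps in parents.items()
                if i not in done and ps <= done
            ]
        if len(done) != len(parents):
            raise PedigreeError("pedigree contains a cycle")

    @property
    def individual_ids(self) -> np.ndarray:
        return self.table["individual_id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def is_founder(self) -> np.ndarray:
        """Boolean mask: both parents missing."""
        return (
            (self.table["father_id"] == MISSING_PARENT)
            & (self.table["mother_id"] == MISSING_PARENT)
        ).to_numpy()

    def founders(self) -> np.ndarray:
        return self.individual_ids[self.is_founder()]

    def topological_order(self) -> np.ndarray:
        """Row indices ordered so parents always precede children."""
        idx_of = {iid: i for i, iid in enumerate(self.individual_ids)}
        fathers = self.table["father_id"].to_numpy()
        mothers = self.table["mother_id"].to_numpy()
        order: list[int] = []
        placed = np.zeros(self.n, dtype=bool)
        while len(order) < self.n:
            progressed = False
            for i in range(self.n):
                if placed[i]:
                    continue
                ok = True
                for p in (fathers[i], mothers[i]):
                    if p != MISSING_PARENT and not placed[idx_of[p]]:
                        ok = False
                        break
                if ok:
                    order.append(i)
                    placed[i] = True
                    progressed = True
            if not progressed:  # pragma: no cover - guarded by __post_init__
                raise PedigreeError("pedigree contains a cycle")
        return np.asarray(order)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(father_idx, mother_idx) row indices, -1 where missing."""
        idx_of = {iid: i for i, iid in enumerate(self.individual_ids)}
        fa = np.array(
            [idx_of.get(p, -1) for p in self.table["father_id"]], dtype=np.int64
        )
        mo = np.array(
            [idx_of.get(p, -1) for p in self.table["mother_id"]], dtype=np.int64
        )
        return fa, mo


def simulate_pedigree(
    n_families: int,
    n_generations: int,
    mean_offspring: float,
    seed: int,
    mate_prob: float = 0.8,
) -> Pedigree:
    """Simulate extended families by forward growth.

    Each family starts from one founder couple.  In every non-terminal
    generation each couple has ``1 + Poisson(mean_offspring - 1)`` children
    (so lineages never die out); each child mates with a newly created,
    unrelated married-in founder with probability ``mate_prob`` and the
    resulting couples produce the next generation.

    Parameters
    ----------
    n_families, n_generations : int
        Number of independent families (>=1) and generations (>=2).
    mean_offspring : float
        Mean number of children per couple (>=1).
    seed : int
        Seed for the generator; output is deterministic given the seed.
    mate_prob : float
        Probability that a non-terminal-generation child reproduces.
    """
    if n_families < 1 or n_generations < 2:
        raise ValueError("need n_families >= 1 and n_generations >= 2")
    if mean_offspring < 1:
        raise ValueError("mean_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, str, str]] = []
    for f in range(1, n_families + 1):
        fam = f"F{f:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}_I{counter:04d}"

        dad, mom = new_id(), new_id()
        rows.append((fam, dad, MISSING_PARENT, MISSING_PARENT, "male"))
        rows.append((fam, mom, MISSING_PARENT, MISSING_PARENT, "female"))
        couples = [(dad, mom)]
        for gen in range(2, n_generations + 1):
            next_couples: list[tuple[str, str]] = []
            for fa, mo in couples:
                n_kids = 1 + rng.poisson(mean_offspring - 1)
                for _ in range(n_kids):
                    sex = "male" if rng.random() < 0.5 else "female"
                    kid = new_id()
                    rows.append((fam, kid, fa, mo, sex))
                    if gen < n_generations and rng.random() < mate_prob:
                        spouse = new_id()
                        spouse_sex = "female" if sex == "male" else "male"
                        rows.append(
                            (fam, spouse, MISSING_PARENT, MISSING_PARENT, spouse_sex)
                        )
                        pair = (kid, spouse) if sex == "male" else (spouse, kid)
                        next_couples.append(pair)
            couples = next_couples
    table = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    )
    return Pedigree(table)
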