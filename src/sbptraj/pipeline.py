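"""End-to-end pipeline: simulate (or load) -> preprocess -> screen -> LCGM ->
kinship / heritability / PCA -> mixed-model GWA, with provenance.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` so each stage is individually
reproducible; every output file gets a manifest line (name, rows, sha256)
in the run log and re-running a config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as sio
from .gwas import build_traits, flag_significance, genomic_lambda, run_mixed_gwa
from .heritability import estimate_h2
from .kinship import kinship_matrix
from .lcgm import (
    assign_classes,
    prune_polynomial_orders,
    rank_classes,
    select_num_classes,
)
from .pathmodel import (
    SNPSkipped,
    compute_fit_indices,
    fit_lagged_path_model,
    select_covariates,
    to_wide,
)
from .pedigree import simulate_pedigree
from .popstruct import founder_pca, ld_prune
from .preprocess import (
    adjust_medication,
    cumulative_hypertensive_years,
    filter_individuals,
)
from .simulate import (
    ScenarioConfig,
    reference_scenario,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger("sbptraj")

_CONFIG_FIELDS = {
    "out_dir", "scenario", "seed", "n_families", "n_generations",
    "mean_offspring", "n_snps", "maf_lo", "maf_hi",
    "pedigree_path", "genotype_prefix", "phenotype_path",
    "med_offset", "min_visits", "z_max", "sbp_threshold",
    "screen_n_snps", "screen_alpha",
    "k_min", "k_max", "order", "traj_covariates", "traj_alpha",
    "r2_max", "prune_window", "prune_step", "n_pcs",
    "maf_min", "gws_p", "suggestive_p",
}


@dataclass
class PipelineConfig:
    """Every stage parameter, with study-derived defaults."""

    out_dir: str = "run"
    scenario: str = "reference"  # or "real" to load the three input paths
    seed: int = 1
    # simulation
    n_families: int = 20
    n_generations: int = 4
    mean_offspring: float = 3.3
    n_snps: int = 2000
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    # real-input mode
    pedigree_path: str | None = None
    genotype_prefix: str | None = None
    phenotype_path: str | None = None
    # preprocess
    med_offset: float = 15.0
    min_visits: int = 2
    z_max: float = 3.0
    sbp_threshold: float = 140.0
    # covariate screen
    screen_n_snps: int = 4
    screen_alpha: float = 0.05
    # trajectories
    k_min: int = 1
    k_max: int = 6
    order: int = 2
    traj_covariates: str = "sex"
    traj_alpha: float = 0.05
    # family genetics
    r2_max: float = 0.2
    prune_window: int = 50
    prune_step: int = 5
    n_pcs: int = 4
    # association
    maf_min: float = 0.01
    gws_p: float = 1.3e-7
    suggestive_p: float = 1.6e-6

    @classmethod
    def from_flat_file(cls, path) -> "PipelineConfig":
        raw = sio.read_flat_config(path)
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in raw.items():
            default = getattr(cls, k, None)
            if isinstance(default, bool):
                kwargs[k] = v.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[k] = int(v)
            elif isinstance(default, float):
                kwargs[k] = float(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, out_dir: str) -> None:
        self.out_dir = out_dir
        os.makedirs(out_dir, exist_ok=True)
        self.manifest: list[dict] = []
        self.log_path = os.path.join(out_dir, "run.log")
        self._log = open(self.log_path, "w")

    def note(self, msg: str) -> None:
        logger.info(msg)
        self._log.write(msg + "\n")
        self._log.flush()

    def register(self, path: str, rows: int | None = None) -> None:
        entry = {
            "name": os.path.basename(path),
            "rows": rows,
            "sha256": _sha256(path),
        }
        self.manifest.append(entry)
        self.note(f"artifact {entry['name']} rows={rows} sha256={entry['sha256']}")

    def close(self) -> None:
        self._log.close()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage 31-bit seeds from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(cfg: PipelineConfig) -> str:
    """Execute the full analysis chain; returns the run directory."""
    run = _Run(cfg.out_dir)
    seeds = _stage_seeds(cfg.seed)
    with open(os.path.join(cfg.out_dir, "config.json"), "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)
    stage = "setup"
    try:
        # ---- inputs ------------------------------------------------------
        t0 = time.time()
        stage = "inputs"
        if cfg.scenario == "real":
            for p, what in (
                (cfg.phenotype_path, "phenotype"),
                (cfg.pedigree_path, "pedigree"),
                (cfg.genotype_prefix, "genotype"),
            ):
                if p is None:
                    raise FileNotFoundError(f"{what} path not configured")
            ph = sio.read_phenotypes(cfg.phenotype_path)
            ped = sio.read_fam(cfg.pedigree_path)
            gen = sio.read_genotypes(cfg.genotype_prefix, "ped_map")
        else:
            scen = reference_scenario() if cfg.scenario == "reference" else None
            if scen is None:
                raise ValueError(f"unknown scenario {cfg.scenario!r}")
            ped = simulate_pedigree(
                cfg.n_families, cfg.n_generations, cfg.mean_offspring, seeds[0]
            )
            gen = simulate_genotypes(
                ped, cfg.n_snps, (cfg.maf_lo, cfg.maf_hi), seeds[1]
            )
            ph, truth = simulate_phenotypes(ped, gen, scen, seeds[2])
            sio.write_fam(ped, os.path.join(cfg.out_dir, "pedigree.fam"))
            run.register(os.path.join(cfg.out_dir, "pedigree.fam"), ped.n)
            truth_path = os.path.join(cfg.out_dir, "truth.csv")
            truth.per_individual.to_csv(truth_path, index=False)
            run.register(truth_path, len(truth.per_individual))
        sio.write_phenotypes(ph, os.path.join(cfg.out_dir, "phenotypes.csv"))
        run.register(os.path.join(cfg.out_dir, "phenotypes.csv"), len(ph.table))
        run.note(f"stage inputs done in {time.time() - t0:.1f}s seed={seeds[0]}")

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        ph_adj = adjust_medication(ph, cfg.med_offset)
        ph_f, report = filter_individuals(ph_adj, cfg.min_visits, cfg.z_max)
        # hypertensive years use the raw (pre-offset) SBP plus medication flag
        from .simulate import LongitudinalPhenotypes as _LP

        raw_kept = ph.table[ph.table["individual_id"].isin(ph_f.individuals)]
        hy = cumulative_hypertensive_years(_LP(raw_kept.copy()), cfg.sbp_threshold)
        rep_path = os.path.join(cfg.out_dir, "filter_report.csv")
        report.to_csv(rep_path)
        run.register(rep_path, len(report.exclusions))
        run.note(
            f"stage preprocess done in {time.time() - t0:.1f}s: "
            f"{report.n_input} -> {report.n_retained} individuals"
        )

        # ---- covariate screen -------------------------------------------
        stage = "covariate_screen"
        t0 = time.time()
        wide = to_wide(ph_f)
        rng = np.random.default_rng(seeds[3])
        common = np.where(gen.maf() >= 0.2)[0]
        pick = rng.choice(
            common, size=min(cfg.screen_n_snps, len(common)), replace=False
        )
        pos = {v: i for i, v in enumerate(gen.sample_ids)}
        row_idx = np.array([pos[i] for i in wide.index])
        fits = {}
        for j in pick:
            snp_id = gen.snp_meta["snp_id"].iloc[j]
            try:
                fits[snp_id] = fit_lagged_path_model(
                    wide, gen.dosages[row_idx, j]
                )
            except SNPSkipped as e:
                run.note(f"screen: {snp_id} skipped ({e})")
        retained = (
            select_covariates(fits, cfg.screen_alpha) if len(fits) >= 2 else set()
        )
        idx_rows = []
        for snp_id, f in fits.items():
            fi = compute_fit_indices(f)
            idx_rows.append(
                (snp_id, fi.rmsea, fi.cfi, fi.tli, fi.model_ok)
            )
        pd.DataFrame(
            idx_rows, columns=["snp_id", "rmsea", "cfi", "tli", "model_ok"]
        ).to_csv(os.path.join(cfg.out_dir, "screen_fit_indices.csv"), index=False)
        run.register(os.path.join(cfg.out_dir, "screen_fit_indices.csv"), len(idx_rows))
        with open(os.path.join(cfg.out_dir, "retained_covariates.txt"), "w") as fh:
            fh.write("\n".join(sorted(retained)) + "\n")
        run.register(os.path.join(cfg.out_dir, "retained_covariates.txt"))
        run.note(
            f"stage covariate_screen done in {time.time() - t0:.1f}s: "
            f"retained {sorted(retained)}"
        )

        # ---- trajectories ------------------------------------------------
        stage = "trajectories"
        t0 = time.time()
        traj_covs = tuple(
            c for c in cfg.traj_covariates.split(",") if c
        ) if cfg.traj_covariates else ()
        # the screen reports 'male'; the trajectory covariate is 'sex'
        model = select_num_classes(
            ph_f, range(cfg.k_min, cfg.k_max + 1), cfg.order,
            covariates=traj_covs, seed=seeds[4],
        )
        model = prune_polynomial_orders(model, ph_f, cfg.traj_alpha, seeds[4])
        assign = assign_classes(model, ph_f)
        last_sbp = (
            ph_f.table.sort_values(["individual_id", "age"])
            .groupby("individual_id")["sbp"].last()
        )
        ranked, rank_map = rank_classes(assign, hy, last_sbp)
        with open(os.path.join(cfg.out_dir, "trajectory_model.json"), "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        run.register(os.path.join(cfg.out_dir, "trajectory_model.json"))
        assign_path = os.path.join(cfg.out_dir, "class_assignments.csv")
        ranked.to_frame().to_csv(assign_path, index=False)
        run.register(assign_path, len(ranked.individual_ids))
        run.note(
            f"stage trajectories done in {time.time() - t0:.1f}s: K={model.K} "
            f"BIC={model.bic:.1f} rank_map={list(rank_map)}"
        )

        # ---- family genetics ---------------------------------------------
        stage = "family_genetics"
        t0 = time.time()
        kin = kinship_matrix(ped)
        kin.to_tsv(os.path.join(cfg.out_dir, "kinship.tsv"))
        run.register(os.path.join(cfg.out_dir, "kinship.tsv"))
        founder_mask = ped.is_founder()
        pruned = ld_prune(
            gen, cfg.r2_max, cfg.prune_window, cfg.prune_step,
            sample_idx=np.where(founder_mask)[0],
        )
        pcs = founder_pca(gen, ped, pruned, m=cfg.n_pcs)
        pcs.to_frame().to_csv(os.path.join(cfg.out_dir, "pcs.csv"), index=False)
        run.register(os.path.join(cfg.out_dir, "pcs.csv"), len(pcs.sample_ids))

        traits = build_traits(ranked) if model.K >= 2 else None
        h2_rows = []
        if traits is not None:
            kin_s = kin.align(traits.table["individual_id"].to_numpy())
            pc_pos = {v: i for i, v in enumerate(pcs.sample_ids)}
            pc_rows = np.array(
                [pc_pos[i] for i in traits.table["individual_id"]]
            )
            pc_mat = pcs.scores[pc_rows]
            for name in traits.trait_names:
                y = traits.table[name].to_numpy()
                try:
                    hr = estimate_h2(y, pc_mat, kin_s)
                    h2_rows.append(
                        (name, hr.h2, hr.se, hr.p_value, hr.sigma_g2, hr.sigma_e2)
                    )
                except ValueError as e:
                    run.note(f"h2 {name}: failed ({e})")
        h2_tab = pd.DataFrame(
            h2_rows, columns=["trait", "h2", "se", "p", "sigma_g2", "sigma_e2"]
        )
        h2_tab.to_csv(os.path.join(cfg.out_dir, "heritability.tsv"), sep="\t",
                      index=False)
        run.register(os.path.join(cfg.out_dir, "heritability.tsv"), len(h2_tab))
        run.note(f"stage family_genetics done in {time.time() - t0:.1f}s")

        # ---- association -------------------------------------------------
        stage = "association"
        t0 = time.time()
        if traits is None:
            run.note("ranking produced K<2 classes: pairwise GWA skipped")
            with open(os.path.join(cfg.out_dir, "gwa_skipped.json"), "w") as fh:
                json.dump({"reason": "K<2, pairwise GWA skipped"}, fh)
        else:
            sample_order = gen.sample_ids
            tt = traits.table.set_index("individual_id")
            all_p = []
            for name in traits.trait_names:
                y = tt[name].reindex(sample_order).to_numpy()
                res = run_mixed_gwa(
                    y, gen, kin, pcs, cfg.maf_min, trait_name=name
                )
                res = flag_significance(res, cfg.gws_p, cfg.suggestive_p)
                path = os.path.join(cfg.out_dir, f"gwa_{name}.tsv")
                res.table.to_csv(path, sep="\t", index=False)
                run.register(path, len(res.table))
                all_p.append(res.table["P"].to_numpy())
            lam, qq = genomic_lambda(np.concatenate(all_p))
            qq.to_csv(os.path.join(cfg.out_dir, "qq.csv"), index=False)
            run.register(os.path.join(cfg.out_dir, "qq.csv"), len(qq))
            run.note(f"genomic lambda (pooled) = {lam:.3f}")
        run.note(f"stage association done in {time.time() - t0:.1f}s")

        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(run.manifest, fh, indent=2)
        run.note("pipeline complete")
        return cfg.out_dir
    except Exception as e:
        run.note(f"FAILED at stage {stage}: {e!r}")
        raise RuntimeError(f"pipeline failed at stage {stage}: {e}") from e
    finally:
        run.close()
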