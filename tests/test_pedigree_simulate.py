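"""Pedigree, gene-dropping, and phenotype generator behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sbptraj as st
from sbptraj.pedigree import Pedigree, PedigreeError
from sbptraj.simulate import (
    AGE_CENTER,
    AGE_SCALE,
    ScenarioConfig,
    ScenarioError,
    class_mean_sbp,
    mendelian_error_count,
    snp_qc,
)


class TestPedigree:
    def test_family_count_is_forced(self):
        ped = st.simulate_pedigree(20, 3, 3.0, seed=1)
        assert ped.table["family_id"].nunique() == 20

    def test_seeded_runs_are_byte_identical(self):
        a = st.simulate_pedigree(5, 3, 3.0, seed=1).table
        b = st.simulate_pedigree(5, 3, 3.0, seed=1).table
        pd.testing.assert_frame_equal(a, b)

    def test_first_generation_are_founders(self):
        ped = st.simulate_pedigree(1, 2, 2.0, seed=7)
        founders = set(ped.founders())
        # generation-1 members are the two family founders plus married-ins;
        # every non-founder must have two in-pedigree parents of opposite sex
        tab = ped.table.set_index("individual_id")
        for row in ped.table.itertuples():
            if row.individual_id in founders:
                assert row.father_id == "0" and row.mother_id == "0"
            else:
                assert tab.loc[row.father_id, "sex"] == "male"
                assert tab.loc[row.mother_id, "sex"] == "female"

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            st.simulate_pedigree(0, 3, 3.0, seed=1)
        with pytest.raises(ValueError):
            st.simulate_pedigree(3, 1, 3.0, seed=1)

    def test_cycle_detected(self):
        tab = pd.DataFrame(
            {
                "family_id": ["F", "F"],
                "individual_id": ["a", "b"],
                "father_id": ["b", "a"],
                "mother_id": ["0", "0"],
                "sex": ["male", "male"],
            }
        )
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(tab)

    def test_dangling_parent_rejected(self):
        tab = pd.DataFrame(
            {
                "family_id": ["F"],
                "individual_id": ["a"],
                "father_id": ["ghost"],
                "mother_id": ["0"],
                "sex": ["male"],
            }
        )
        with pytest.raises(PedigreeError, match="ghost"):
            Pedigree(tab)


class TestGenotypes:
    def test_gene_dropping_is_mendelian_clean(self, small_ped):
        gen = st.simulate_genotypes(small_ped, 300, (0.05, 0.5), seed=3)
        assert mendelian_error_count(small_ped, gen) == 0

    def test_founder_genotypes_hardy_weinberg(self):
        # >=200 founders at fixed frequency 0.3: genotype counts must be
        # consistent with Binomial(2, 0.3) (chi-square, alpha = 0.001)
        ped = st.simulate_pedigree(100, 2, 2.0, seed=9)
        founders = ped.is_founder()
        assert founders.sum() >= 200
        gen = st.simulate_genotypes(ped, 5000, (0.3, 0.3), seed=4)
        fd = gen.dosages[founders]
        n = fd.shape[0] * fd.shape[1]
        counts = np.array([(fd == k).sum() for k in (0, 1, 2)])
        # effect allele may be flipped to the major side per SNP: fold
        folded = np.array([counts[0] + counts[2], counts[1]])
        exp = n * np.array([0.7**2 + 0.3**2, 2 * 0.3 * 0.7])
        chi2 = ((folded - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=1) > 0.001

    def test_monomorphic_maf_rejected(self, small_ped):
        with pytest.raises(ValueError):
            st.simulate_genotypes(small_ped, 10, (0.0, 0.0), seed=1)

    def test_eaf_matches_mean_dosage(self, small_ped):
        gen = st.simulate_genotypes(small_ped, 50, (0.1, 0.5), seed=5)
        np.testing.assert_allclose(
            gen.snp_meta["eaf"], np.nanmean(gen.dosages, axis=0) / 2.0
        )

    def test_qc_drops_monomorphic(self, small_ped):
        gen = st.simulate_genotypes(small_ped, 100, (0.05, 0.5), seed=6)
        gen.dosages[:, 0] = 2.0  # force monomorphic
        gen.snp_meta.loc[0, "eaf"] = 1.0
        clean, report = snp_qc(gen, small_ped)
        assert "snp1" not in set(clean.snp_meta["snp_id"])
        assert ("snp1", "monomorphic") in list(
            report.itertuples(index=False, name=None)
        )
        assert (clean.maf() > 0).all()


class TestPhenotypes:
    def test_degenerate_noise_gives_exact_curves(self, small_ped):
        sc = ScenarioConfig(
            k_true=2,
            class_props=(0.5, 0.5),
            class_coefs=((120.0, 5.0, 1.0), (150.0, 8.0, 2.0)),
            residual_sd=0.0,
            polygenic_var=0.0,
            liability_env_var=1.0,
            missing_rate=0.0,
        )
        ph, truth = st.simulate_phenotypes(small_ped, None, sc, seed=2)
        cls = truth.per_individual.set_index("individual_id")["true_class"]
        for row in ph.table.itertuples():
            k = cls[row.individual_id] - 1
            expect = class_mean_sbp(sc.class_coefs[k], row.age)
            expect += sc.sex_effect * (row.sex == "male")
            assert row.sbp == pytest.approx(float(expect), abs=1e-9)

    def test_reference_visit_design(self, mimic_cohort):
        ph = mimic_cohort["ph_raw"]
        counts = ph.visit_counts()
        assert counts.max() <= 4
        spans = ph.table.groupby("individual_id")["age"].agg(np.ptp)
        assert spans.max() <= 17.0 + 1e-9

    def test_liability_variance_ratio(self, small_ped):
        # moment-matching over replicates: share of liability variance that
        # is polygenic approximates v / (v + w)
        v, w = 16.0, 4.0
        sc = ScenarioConfig(
            k_true=2, class_props=(0.5, 0.5),
            class_coefs=((120.0, 0.0, 0.0), (150.0, 0.0, 0.0)),
            polygenic_var=v, liability_env_var=w,
        )
        gs = []
        for r in range(60):
            _, truth = st.simulate_phenotypes(small_ped, None, sc, seed=1000 + r)
            gs.append(truth.per_individual["polygenic"].to_numpy())
        var_g = np.var(np.concatenate(gs))
        assert var_g / (var_g + w) == pytest.approx(v / (v + w), abs=0.05)
        assert sc.liability_h2 == pytest.approx(v / (v + w))

    def test_marginal_mean_matches_mixture(self, mimic_cohort):
        ph, truth = mimic_cohort["ph_raw"], mimic_cohort["truth"]
        sc = st.reference_scenario()
        ages = ph.table["age"].to_numpy()
        mix = np.zeros_like(ages)
        for k in range(sc.k_true):
            mix += sc.class_props[k] * class_mean_sbp(sc.class_coefs[k], ages)
        male_frac = (ph.table["sex"] == "male").mean()
        expect = mix.mean() + sc.sex_effect * male_frac
        assert ph.table["sbp"].mean() == pytest.approx(expect, abs=2.0)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ScenarioError, match="sum to 1"):
            ScenarioConfig(
                k_true=2, class_props=(0.5, 0.4),
                class_coefs=((120, 0, 0), (150, 0, 0)),
            )

    def test_unknown_scenario_keys_rejected(self):
        with pytest.raises(ScenarioError, match="unknown"):
            ScenarioConfig.from_dict({"k_true": 1, "bogus": 3})

    def test_scenario_flat_file_round_trip(self, tmp_path):
        path = tmp_path / "scenario.cfg"
        path.write_text(
            "k_true = 2\n"
            "class_props = 0.6, 0.4\n"
            "class_coefs = 115,5,1; 150,9,2\n"
            "residual_sd = 8\n"
        )
        sc = ScenarioConfig.from_flat_file(path)
        assert sc.k_true == 2
        assert sc.class_coefs == ((115.0, 5.0, 1.0), (150.0, 9.0, 2.0))
        assert sc.residual_sd == 8.0
        path.write_text("k_true = 2\nwhatever = 1\n")
        with pytest.raises(ScenarioError, match="unknown"):
            ScenarioConfig.from_flat_file(path)

    def test_generators_bit_reproducible(self, small_ped):
        sc = st.reference_scenario()
        a, _ = st.simulate_phenotypes(small_ped, None, sc, seed=5)
        b, _ = st.simulate_phenotypes(small_ped, None, sc, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        ga = st.simulate_genotypes(small_ped, 20, (0.1, 0.5), seed=5)
        gb = st.simulate_genotypes(small_ped, 20, (0.1, 0.5), seed=5)
        np.testing.assert_array_equal(ga.dosages, gb.dosages)
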