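"""Censored-normal growth mixture: likelihood, EM, selection, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import sbptraj as st
from sbptraj.lcgm import (
    InfeasibleConfigError,
    MIN_GROUP_SIZE,
    censored_normal_loglik,
)
from sbptraj.simulate import AGE_CENTER, AGE_SCALE, ScenarioConfig
from conftest import make_phenotypes


class TestCensoredNormalLoglik:
    def test_standard_normal_at_mode(self):
        ll = censored_normal_loglik(0.0, 0.0, 1.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_lower_bound_mass_at_median(self):
        ll = censored_normal_loglik(0.0, 0.0, 1.0, y_min=0.0)
        assert ll == pytest.approx(np.log(0.5))

    def test_total_mass_integrates_to_one(self):
        # interior density + point masses at the bounds, against quadrature
        y_min, y_max, mu, sigma = 80.0, 250.0, 130.0, 20.0
        interior, _ = integrate.quad(
            lambda y: np.exp(censored_normal_loglik(y, mu, sigma, y_min, y_max)),
            y_min + 1e-9, y_max - 1e-9, limit=200,
        )
        p_lo = np.exp(censored_normal_loglik(y_min, mu, sigma, y_min, y_max))
        p_hi = np.exp(censored_normal_loglik(y_max, mu, sigma, y_min, y_max))
        assert interior + p_lo + p_hi == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            censored_normal_loglik(np.nan, 0.0, 1.0)
        with pytest.raises(ValueError):
            censored_normal_loglik(0.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            censored_normal_loglik(0.0, 0.0, 1.0, y_min=5.0, y_max=1.0)


def _flat_two_class_cohort(n=400, means=(110.0, 170.0), sigma=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    labels = {}
    for i in range(n):
        k = int(rng.random() < 0.5)
        labels[f"i{i:04d}"] = k + 1
        base_age = rng.uniform(35, 55)
        for v in range(1, 4):
            age = base_age + 5 * (v - 1)
            rows.append(
                (f"i{i:04d}", v, age, means[k] + rng.normal(0, sigma), False)
            )
    return make_phenotypes(rows), labels


class TestFitLCGM:
    def test_k1_equals_polynomial_least_squares(self, mimic_cohort):
        ph = mimic_cohort["ph"]
        m = st.fit_lcgm(ph, K=1, seed=1)
        c = (ph.table["age"].to_numpy() - AGE_CENTER) / AGE_SCALE
        X = np.column_stack([np.ones_like(c), c, c**2])
        ref, *_ = np.linalg.lstsq(X, ph.table["sbp"].to_numpy(), rcond=None)
        np.testing.assert_allclose(m.coefs[0], ref, atol=1e-6)

    def test_em_loglik_monotone(self, mimic_cohort):
        m = st.fit_lcgm(mimic_cohort["ph"], K=3, seed=2, n_starts=2)
        diffs = np.diff(m.ll_trace)
        assert (diffs >= -1e-9).all()

    def test_separated_classes_recovered(self):
        ph, labels = _flat_two_class_cohort()
        m = st.fit_lcgm(ph, K=2, seed=3, n_starts=3)
        a = st.assign_classes(m, ph)
        truth = np.array([labels[i] for i in a.individual_ids])
        agree = max((a.hard == truth).mean(), (a.hard == 3 - truth).mean())
        assert agree >= 0.95

    def test_infeasible_k_rejected(self):
        ph, _ = _flat_two_class_cohort(n=60)
        with pytest.raises(InfeasibleConfigError):
            st.fit_lcgm(ph, K=3, seed=1)  # 60 <= 25 * 3

    def test_label_permutation_leaves_fit_invariant(self):
        ph, _ = _flat_two_class_cohort(n=150, seed=9)
        m = st.fit_lcgm(ph, K=2, seed=4, n_starts=2)
        perm = m.to_dict()
        perm["coefs"] = perm["coefs"][::-1]
        perm["pi"] = perm["pi"][::-1]
        m2 = st.TrajectoryModel.from_dict(perm)
        a1 = st.assign_classes(m, ph)
        a2 = st.assign_classes(m2, ph)
        # permuted labels, identical partition and posterior mass
        assert (a2.hard == 3 - a1.hard).all()
        np.testing.assert_allclose(a2.posterior, a1.posterior[:, ::-1], atol=1e-12)

    def test_finite_bounds_em_monotone(self):
        ph, _ = _flat_two_class_cohort(n=120, seed=5)
        m = st.fit_lcgm(
            ph, K=2, bounds=(80.0, 250.0), seed=5, n_starts=1, max_iter=40
        )
        assert (np.diff(m.ll_trace) >= -1e-7).all()


class TestSelectNumClasses:
    def test_single_class_generator_selects_k1(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(200):
            base_age = rng.uniform(35, 55)
            for v in range(1, 4):
                rows.append(
                    (f"i{i:03d}", v, base_age + 5 * (v - 1),
                     130.0 + rng.normal(0, 8.0), False)
                )
        ph = make_phenotypes(rows)
        m = st.select_num_classes(ph, range(1, 4), seed=7, n_starts=3)
        assert m.K == 1

    def test_small_group_solutions_excluded(self):
        # 190 in one flat class, 10 in another far away: K=2 fits cleanly but
        # violates the N > 25 rule, so selection must fall back to K=1
        rng = np.random.default_rng(8)
        rows = []
        for i in range(200):
            mean = 180.0 if i < 10 else 120.0
            base_age = rng.uniform(35, 55)
            for v in range(1, 4):
                rows.append(
                    (f"i{i:03d}", v, base_age + 5 * (v - 1),
                     mean + rng.normal(0, 5.0), False)
                )
        ph = make_phenotypes(rows)
        m = st.select_num_classes(ph, range(1, 3), seed=9, n_starts=3)
        assert m.K == 1

    def test_all_infeasible_raises_with_diagnostics(self):
        ph, _ = _flat_two_class_cohort(n=30)
        with pytest.raises(InfeasibleConfigError, match="2"):
            st.select_num_classes(ph, range(2, 4), seed=1)


class TestPruning:
    def test_linear_class_loses_quadratic_term(self):
        # single class generated purely linear in age
        rng = np.random.default_rng(10)
        rows = []
        for i in range(300):
            base_age = rng.uniform(30, 60)
            for v in range(1, 4):
                age = base_age + 5 * (v - 1)
                c = (age - AGE_CENTER) / AGE_SCALE
                rows.append(
                    (f"i{i:03d}", v, age, 130.0 + 6.0 * c + rng.normal(0, 6.0),
                     False)
                )
        ph = make_phenotypes(rows)
        m = st.fit_lcgm(ph, K=1, order=2, seed=11)
        pruned = st.prune_polynomial_orders(m, ph)
        assert pruned.class_terms[0] == (0, 1)
        assert pruned.n_params < m.n_params

    def test_significant_model_is_fixed_point(self):
        ph, _ = _flat_two_class_cohort(n=300, seed=12)
        m = st.fit_lcgm(ph, K=1, order=0, seed=13)
        pruned = st.prune_polynomial_orders(m, ph)
        assert pruned.class_terms == m.class_terms
        assert pruned.n_params == m.n_params

    def test_pruned_model_has_smaller_penalty(self, mimic_cohort):
        ph = mimic_cohort["ph"]
        m = st.fit_lcgm(ph, K=2, seed=14, n_starts=3)
        pruned = st.prune_polynomial_orders(m, ph)
        assert pruned.n_params <= m.n_params
        assert pruned.K == m.K


class TestAssignAndRank:
    def test_posterior_rows_sum_to_one(self, mimic_cohort):
        m = st.fit_lcgm(mimic_cohort["ph"], K=2, seed=15, n_starts=2)
        a = st.assign_classes(m, mimic_cohort["ph"])
        np.testing.assert_allclose(a.posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_overwhelming_likelihood_wins(self):
        ph, labels = _flat_two_class_cohort(n=100, seed=16)
        m = st.fit_lcgm(ph, K=2, seed=17, n_starts=2)
        a = st.assign_classes(m, ph)
        # every individual sits ~12 residual SDs from the wrong class mean
        assert (a.posterior.max(axis=1) > 0.999).all()

    def test_equal_likelihood_ties_to_lowest_index(self):
        ph, _ = _flat_two_class_cohort(n=60, seed=18)
        m = st.fit_lcgm(ph, K=2, seed=19, n_starts=1, max_iter=3)
        dup = m.to_dict()
        dup["coefs"][1] = dup["coefs"][0]
        dup["pi"] = [0.5, 0.5]
        m2 = st.TrajectoryModel.from_dict(dup)
        a = st.assign_classes(m2, ph)
        np.testing.assert_allclose(a.posterior, 0.5, atol=1e-12)
        assert (a.hard == 1).all()

    def _toy_assignment(self, class_of):
        ids = np.array(list(class_of), dtype=object)
        K = max(class_of.values())
        post = np.full((len(ids), K), 1e-6)
        for i, iid in enumerate(ids):
            post[i, class_of[iid] - 1] = 1.0
        post /= post.sum(axis=1, keepdims=True)
        return st.ClassAssignment(ids, post, post.argmax(axis=1) + 1)

    def test_sorted_means_give_identity_ranking(self):
        class_of = {f"i{i}": (i % 5) + 1 for i in range(25)}
        a = self._toy_assignment(class_of)
        years = pd.Series(
            {iid: float(k - 1) * 3.0 for iid, k in class_of.items()}
        )
        ranked, rank_map = st.rank_classes(a, years)
        assert list(rank_map) == [1, 2, 3, 4, 5]
        assert sorted(set(ranked.rank)) == [1, 2, 3, 4, 5]

    def test_reversed_means_swap_ranks(self):
        class_of = {"a": 1, "b": 1, "c": 2, "d": 2}
        a = self._toy_assignment(class_of)
        years = pd.Series({"a": 12.0, "b": 12.0, "c": 0.0, "d": 0.0})
        ranked, rank_map = st.rank_classes(a, years)
        assert list(rank_map) == [2, 1]
        assert list(ranked.rank) == [2, 2, 1, 1]
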