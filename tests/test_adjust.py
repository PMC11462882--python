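"""Design matrix, ridge propensity model, pseudo-value outcome regression,
and the three standardization estimators."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rmstprofile import adjust
from rmstprofile.adjust import (
    DesignMatrix,
    PropensityFit,
    build_design_matrix,
    center_estimates,
    dr_estimates,
    fit_outcome_model,
    fit_propensity_fixed,
    gcomp_estimates,
    iptw_estimates,
    unadjusted_estimates,
)


def make_patients(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.normal(68, 14, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "index_year": rng.choice([2012, 2013, 2014, 2015], n),
        "cf_01": rng.integers(0, 2, n),
        "cf_02": rng.integers(0, 2, n),
    })


class TestDesignMatrix:
    def test_identical_patients_identical_rows(self):
        pats = make_patients(4)
        pats.loc[1] = pats.loc[0]
        X = build_design_matrix(pats).frame
        assert np.allclose(X.iloc[0], X.iloc[1])

    def test_interaction_is_product_of_sex_and_spline(self):
        pats = make_patients(50)
        X = build_design_matrix(pats).frame
        for k in range(1, 5):
            prod = X[f"age_ns{k}"] * X["sex_F"]
            assert np.allclose(X[f"age_ns{k}:sex_F"], prod)

    def test_spline_spans_natural_cubic_spline_oracle(self):
        """The age basis must span the classical truncated-power natural
        cubic spline space on the same quantile knots."""
        pats = make_patients(300, seed=3)
        age = pats["age"].to_numpy(float)
        X = build_design_matrix(pats, age_sex_interaction=False).frame
        mine = X[[c for c in X if c.startswith("age_ns")]].to_numpy()
        mine = np.column_stack([np.ones(len(age)), mine])

        # quantile knots (computed over unique values) of the df+1-knot
        # natural-spline space that intercept + 4 basis columns span
        knots = np.percentile(np.unique(age), np.linspace(0, 100, 5))

        def d(x, k, kK):
            return (np.clip(x - k, 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3) / (kK - k)

        cols = [np.ones_like(age), age]
        for k in knots[:-2]:
            cols.append(d(age, k, knots[-1]) - d(age, knots[-2], knots[-1]))
        oracle = np.column_stack(cols)
        # same span: projections of arbitrary targets coincide
        rng = np.random.default_rng(1)
        y = np.sin(age / 10) + rng.normal(0, 1, len(age))
        fit_mine = mine @ np.linalg.lstsq(mine, y, rcond=None)[0]
        fit_oracle = oracle @ np.linalg.lstsq(oracle, y, rcond=None)[0]
        assert np.allclose(fit_mine, fit_oracle, atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        pats = make_patients(30)
        pats["cf_01"] = 1
        with pytest.warns(UserWarning, match="constant"):
            X = build_design_matrix(pats)
        assert "cf_01" not in X.columns

    def test_full_rank_with_entity_dummies(self):
        pats = make_patients(200, seed=5)
        X = build_design_matrix(pats)
        labels = np.random.default_rng(0).integers(0, 3, len(pats))
        D = (labels[:, None] == np.arange(3)).astype(float)
        M = np.hstack([D, X.without_intercept()])
        assert np.linalg.matrix_rank(M) == M.shape[1]


class TestPropensity:
    def test_huge_lambda_gives_marginal_frequencies(self, small_frame):
        _, frame = small_frame
        X = build_design_matrix(frame)
        labels = frame["entity"].to_numpy()
        fit = fit_propensity_fixed(X, labels, lambda_=1e9)
        marginals = np.bincount(labels) / len(labels)
        assert np.allclose(fit.probs.to_numpy(), marginals[None, :], atol=1e-3)

    def test_rows_sum_to_one_and_positive(self, small_frame):
        _, frame = small_frame
        X = build_design_matrix(frame)
        fit = fit_propensity_fixed(X, frame["entity"].to_numpy(), lambda_=1.0)
        p = fit.probs.to_numpy()
        assert np.allclose(p.sum(axis=1), 1.0) and (p > 0).all()

    def test_small_entity_reduces_folds_with_warning(self):
        rng = np.random.default_rng(0)
        pats = make_patients(60)
        labels = np.array([0] * 55 + [1] * 5)
        X = build_design_matrix(pats)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            adjust.fit_propensity_ridge(X, labels, n_folds=10, seed=1,
                                        lambda_grid=np.array([1.0, 10.0]))

    def test_positivity_floor_enforced(self):
        probs = pd.DataFrame({0: [1e-9, 0.5], 1: [1.0 - 1e-9, 0.5]})
        fit = PropensityFit(probs, 1.0, None, None, np.array([0, 1]))
        with pytest.raises(ValueError, match="positivity"):
            fit.check_positivity(np.array([0, 1]))


class TestOutcomeModel:
    def test_exact_interpolation_of_linear_truth(self):
        rng = np.random.default_rng(2)
        pats = make_patients(400, seed=2)
        X = build_design_matrix(pats)
        labels = rng.integers(0, 3, 400)
        beta = rng.normal(0, 1, X.without_intercept().shape[1])
        alpha = np.array([5.0, -3.0, 11.0])
        y = alpha[labels] + X.without_intercept() @ beta
        pseudo = pd.DataFrame({"pseudo_rmtl_noncompliance": y,
                               "pseudo_rmtl_competing": y * 0.5})
        fit = fit_outcome_model(pseudo, X, labels)
        assert np.allclose(fit.alpha["pseudo_rmtl_noncompliance"], alpha, atol=1e-8)
        assert np.allclose(fit.beta["pseudo_rmtl_noncompliance"], beta, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        pats = make_patients(300, seed=4)
        X = build_design_matrix(pats)
        labels = rng.integers(0, 3, 300)
        y = rng.normal(100, 20, 300)
        pseudo = pd.DataFrame({"pseudo_rmtl_noncompliance": y,
                               "pseudo_rmtl_competing": rng.normal(20, 5, 300)})
        fit = fit_outcome_model(pseudo, X, labels)
        pred = fit.predict("pseudo_rmtl_noncompliance", X)[np.arange(300), labels]
        resid = y - pred
        M = np.hstack([(labels[:, None] == np.arange(3)).astype(float),
                       X.without_intercept()])
        assert np.max(np.abs(M.T @ resid)) < 1e-6

    def test_matches_independent_qr_solver(self):
        rng = np.random.default_rng(4)
        pats = make_patients(250, seed=6)
        X = build_design_matrix(pats)
        labels = rng.integers(0, 2, 250)
        y = rng.normal(0, 1, 250)
        pseudo = pd.DataFrame({"pseudo_rmtl_noncompliance": y,
                               "pseudo_rmtl_competing": y})
        fit = fit_outcome_model(pseudo, X, labels)
        M = np.hstack([(labels[:, None] == np.arange(2)).astype(float),
                       X.without_intercept()])
        Q, R = np.linalg.qr(M)
        coef = np.linalg.solve(R, Q.T @ y)
        got = np.concatenate([fit.alpha["pseudo_rmtl_noncompliance"],
                              fit.beta["pseudo_rmtl_noncompliance"]])
        assert np.allclose(got, coef, atol=1e-8)

    def test_not_estimable_raises(self):
        pats = make_patients(10)
        X = build_design_matrix(pats)
        pseudo = pd.DataFrame({"pseudo_rmtl_noncompliance": np.ones(10),
                               "pseudo_rmtl_competing": np.ones(10)})
        with pytest.raises(ValueError, match="estimable"):
            fit_outcome_model(pseudo, X, np.arange(10) % 5)


class TestStandardizedEstimators:
    def make_pseudo(self, n, rng):
        p1 = rng.normal(180, 50, n)
        p2 = rng.normal(40, 15, n)
        return pd.DataFrame({
            "pseudo_rmtl_noncompliance": p1,
            "pseudo_rmtl_competing": p2,
        })

    def test_constant_weights_reduce_iptw_to_entity_means(self):
        rng = np.random.default_rng(5)
        n = 90
        labels = rng.integers(0, 3, n)
        pseudo = self.make_pseudo(n, rng)
        marg = np.bincount(labels, minlength=3) / n
        probs = pd.DataFrame(np.tile(marg, (n, 1)), columns=np.arange(3))
        fit = PropensityFit(probs, 0.0, None, None, np.arange(3))
        est = iptw_estimates(pseudo, fit, labels, 365).set_index("entity")
        for z in range(3):
            expect = pseudo.loc[labels == z, "pseudo_rmtl_noncompliance"].mean()
            assert est.loc[z, "rmtl_noncompliance"] == pytest.approx(expect, abs=1e-10)

    def test_single_entity_iptw_is_unweighted_mean(self):
        rng = np.random.default_rng(6)
        n = 40
        pseudo = self.make_pseudo(n, rng)
        probs = pd.DataFrame({0: np.full(n, 1.0)})
        fit = PropensityFit(probs, 0.0, None, None, np.array([0]))
        est = iptw_estimates(pseudo, fit, np.zeros(n, dtype=int), 365)
        assert est["rmtl_noncompliance"].iloc[0] == pytest.approx(
            pseudo["pseudo_rmtl_noncompliance"].mean(), abs=1e-10)

    def test_gcomp_without_confounder_effects_is_entity_mean(self):
        rng = np.random.default_rng(7)
        n = 200
        labels = rng.integers(0, 2, n)
        pseudo = self.make_pseudo(n, rng)
        # design with intercept only: model = entity means
        X = DesignMatrix(pd.DataFrame({"intercept": np.ones(n)}))
        fit = fit_outcome_model(pseudo, X, labels)
        est = gcomp_estimates(fit, X, 365).set_index("entity")
        for z in range(2):
            assert est.loc[z, "rmtl_noncompliance"] == pytest.approx(
                pseudo.loc[labels == z, "pseudo_rmtl_noncompliance"].mean(), abs=1e-9)

    def test_decomposition_holds_for_all_estimators(self, small_frame):
        from rmstprofile.pseudo import pseudo_matrix

        _, frame = small_frame
        labels = frame["entity"].to_numpy()
        pm = pseudo_matrix(frame, 365)
        X = build_design_matrix(frame)
        prop = fit_propensity_fixed(X, labels, lambda_=1.0)
        fit = fit_outcome_model(pm, X, labels)
        for est in (unadjusted_estimates(frame, 365),
                    iptw_estimates(pm, prop, labels, 365),
                    gcomp_estimates(fit, X, 365),
                    dr_estimates(pm, prop, fit, X, labels, 365)):
            total = est["rmst"] + est["rmtl_noncompliance"] + est["rmtl_competing"]
            assert np.allclose(total, 365.0, atol=1e-9)

    def test_centering(self):
        est = pd.DataFrame({"entity": [0, 1], "rmtl_noncompliance": [10.0, 4.0],
                            "rmtl_competing": [1.0, 1.0], "rmst": [354.0, 360.0]})
        out = center_estimates(est)
        assert np.allclose(out["centered_rmtl_noncompliance"], [3.0, -3.0])
        assert out["centered_rmtl_noncompliance"].sum() == pytest.approx(0, abs=1e-12)
        same = center_estimates(pd.DataFrame({"entity": [0, 1],
                                              "rmtl_noncompliance": [5.0, 5.0],
                                              "rmtl_competing": [1.0, 1.0],
                                              "rmst": [359.0, 359.0]}))
        assert np.allclose(same["centered_rmtl_noncompliance"], 0.0)

    def test_null_generator_centered_estimates_near_zero(self):
        """No entity effects but confounding present: all estimators'
        centered values hover around zero."""
        from rmstprofile.episodes import EpisodeParams, build_cohort_episodes
        from rmstprofile.pseudo import pseudo_matrix
        from rmstprofile.simulate import SimConfig, generate_population

        cfg = SimConfig(n_patients=6000, n_entities=3, seed=31)
        b = generate_population(cfg)
        eps = build_cohort_episodes(b, EpisodeParams())
        frame = eps.merge(b.patients.drop(columns=["discharge_day"]), on="patient_id")
        labels = frame["entity"].to_numpy()
        pm = pseudo_matrix(frame, 365)
        X = build_design_matrix(frame)
        probs = b.latent[[f"propensity_{z}" for z in range(3)]].to_numpy()
        prop = PropensityFit(pd.DataFrame(probs, columns=np.arange(3),
                                          index=frame.index), 0.0, None, None, np.arange(3))
        fit = fit_outcome_model(pm, X, labels)
        for est in (iptw_estimates(pm, prop, labels, 365),
                    gcomp_estimates(fit, X, 365),
                    dr_estimates(pm, prop, fit, X, labels, 365)):
            centered = center_estimates(est)["centered_rmtl_noncompliance"]
            assert np.max(np.abs(centered)) < 12.0  # ~2000/entity: s.e. ~3 days
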