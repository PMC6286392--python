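"""Univariate F-filter and the cross-validated L1/L2 penalised fit."""

import numpy as np
import pandas as pd
import pytest

from panmir.datatypes import ValidationError
from panmir.preprocess import standardize
from panmir.regression import (
    associate_signature,
    fit_elastic_net,
    univariate_filter,
)
from panmir.simulate import simulate_study

from conftest import tiny_sim_config


def _standard_design(rng, n, p):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])


class TestUnivariateFilter:
    def test_identical_covariate_retained(self, rng):
        X = _standard_design(rng, 50, 5)
        y = X["x0"].to_numpy()
        kept = univariate_filter(y, X, 0.2)
        assert "x0" in kept

    def test_constant_covariate_dropped(self, rng):
        X = _standard_design(rng, 30, 3)
        X["const"] = 1.0
        y = rng.standard_normal(30)
        assert "const" not in univariate_filter(standardize(y), X, 0.999)

    def test_null_retention_matches_threshold(self, rng):
        # p uniform under the null: retained fraction ~ Binomial(10000, 0.2)
        X = _standard_design(rng, 200, 10_000)
        y = standardize(rng.standard_normal(200))
        frac = len(univariate_filter(y, X, 0.2)) / 10_000
        assert frac == pytest.approx(0.20, abs=0.02)


class TestElasticNet:
    def test_lasso_dead_zone_all_zero(self, rng):
        X = _standard_design(rng, 60, 8)
        y = standardize(rng.standard_normal(60))
        lam_max = float(np.max(np.abs((X - X.mean()).to_numpy().T @ (y - y.mean()))))
        res = fit_elastic_net(y, X, lambda1=lam_max * 1.0001, lambda2=0.0)
        assert all(b == 0 for b in res.coefficients.values())

    def test_unpenalised_matches_normal_equations(self, rng):
        X = _standard_design(rng, 50, 10)
        beta = rng.standard_normal(10)
        y = standardize(X.to_numpy() @ beta + 0.3 * rng.standard_normal(50))
        res = fit_elastic_net(y, X, lambda1=0.0, lambda2=0.0)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        ref = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        fitted = np.array([res.coefficients[c] for c in X.columns])
        assert np.allclose(fitted, ref, rtol=1e-6, atol=1e-8)

    def test_exact_predictor_dominates(self, rng):
        X = _standard_design(rng, 80, 5)
        y = X["x1"].to_numpy().copy()
        res = fit_elastic_net(y, X, lambda1=1e-4, lambda2=0.0)
        assert res.coefficients["x1"] == pytest.approx(1.0, abs=0.01)
        others = [abs(v) for k, v in res.coefficients.items() if k != "x1"]
        assert max(others) < 0.02

    def test_l1_path_shrinks_l1_norm(self, rng):
        X = _standard_design(rng, 60, 6)
        y = standardize(X.to_numpy() @ rng.standard_normal(6) + rng.standard_normal(60))
        norms = []
        for lam1 in [0.5, 2.0, 8.0, 32.0]:
            res = fit_elastic_net(y, X, lambda1=lam1, lambda2=0.1)
            norms.append(sum(abs(v) for v in res.coefficients.values()))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_cv_selects_reasonable_model(self, rng):
        X = _standard_design(rng, 100, 20)
        signal = X.to_numpy()[:, :3] @ np.array([0.8, -0.8, 0.8])
        y = standardize(signal + rng.standard_normal(100))
        res = fit_elastic_net(y, X, seed=4)
        top = sorted(res.coefficients, key=lambda k: -abs(res.coefficients[k]))[:3]
        assert set(top) == {"x0", "x1", "x2"}
        assert res.lambda2 in (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)

    def test_no_covariates_gives_intercept_only(self):
        y = np.array([0.5, -0.5, 0.2, -0.2] * 5)
        res = fit_elastic_net(y, pd.DataFrame(index=range(20)))
        assert res.coefficients == {}

    def test_fold_assignment_needs_enough_samples(self, rng):
        X = _standard_design(rng, 6, 2)
        with pytest.raises(ValidationError):
            fit_elastic_net(standardize(rng.standard_normal(6)), X, n_folds=10)


@pytest.fixture(scope="module")
def assoc():
    study = simulate_study(tiny_sim_config(seed=9))
    coef = associate_signature(study.cohorts, study.signatures, seed=5)
    return study, coef["SIG1"]


class TestAssociateSignature:

    def test_planted_drivers_fully_assessed_with_correct_sign(self, assoc):
        study, mat = assoc
        truth = study.truth.drivers.drop_duplicates(subset=["mirna"])
        for _, row in truth.iterrows():
            vals = mat.loc[row["mirna"]]
            assert vals.notna().all()
            nonzero = vals[vals != 0]
            assert (np.sign(nonzero) == row["sign"]).mean() > 0.5

    def test_low_expressed_mirnas_are_na(self, assoc):
        study, mat = assoc
        cfg = study.config
        low = cfg.mirna_ids[-int(0.1 * cfg.n_mirnas):]
        present = [m for m in low if m in mat.index]
        assert all(mat.loc[m].isna().all() for m in present) if present else True
        # detection-failing miRNAs either dropped entirely or all-NA rows removed
        assert not set(low) <= set(mat.index)

    def test_matrix_has_no_all_na_rows(self, assoc):
        _, mat = assoc
        assert mat.notna().any(axis=1).all()
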