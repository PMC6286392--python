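"""Integrative TSG-expression models and cross-type predictor aggregation."""

import numpy as np
import pandas as pd
import pytest

from panmir.datatypes import ValidationError
from panmir.regression import PenalizedModelResult
from panmir.tsg import aggregate_tsg_predictors, build_tsg_design, fit_tsg_model

from conftest import tiny_sim_config
from panmir.simulate import simulate_study


@pytest.fixture(scope="module")
def mode_study():
    # planted copy-number effect dominant over the regulator arms, so the
    # dosage coefficient should top every per-type model
    return simulate_study(
        tiny_sim_config(
            seed=21, cnv_effect=1.2, meth_mirna_slope=0.8, meth_beta_slope=1.0
        )
    )


@pytest.fixture(scope="module")
def mode_gene(mode_study):
    return mode_study.truth.tsg_modes["gene"].iloc[0]


class TestBuildDesign:
    def test_columns_standardized(self, mode_study, mode_gene):
        design = build_tsg_design(mode_gene, mode_study.cohorts[0])
        X = design.covariates.to_numpy()
        assert np.abs(X.mean(axis=0)).max() < 1e-8
        assert np.abs(X.std(axis=0, ddof=1) - 1).max() < 1e-8
        assert np.abs(design.response.mean()) < 1e-8

    def test_column_bookkeeping(self, mode_study, mode_gene):
        cohort = mode_study.cohorts[0]
        design = build_tsg_design(mode_gene, cohort)
        roles = design.covariates.columns
        n_mut = sum(r.startswith("mutation_type:") for r in roles)
        n_probe = sum(r.startswith("methylation:") for r in roles)
        n_mirna = sum(r.startswith("mirna:") for r in roles)
        n_cnv = sum(r == "cnv" for r in roles)
        assert len(roles) == n_cnv + n_mut + n_probe + n_mirna
        assert n_probe == sum(
            1 for p, g in cohort.probe_to_gene.items() if g == mode_gene
        )
        # dropped columns carry reasons
        assert all(len(item) == 2 for item in design.dropped_columns)

    def test_unmutated_gene_has_no_mutation_columns(self, mode_study):
        cohort = mode_study.cohorts[0]
        recs = cohort.mutations.records
        mutated = set(recs["gene"])
        target = next(g for g in cohort.mrna.feature_ids[:50] if g not in mutated)
        design = build_tsg_design(target, cohort)
        assert not any(c.startswith("mutation_type:") for c in design.covariates.columns)
        assert any("no mutations" in reason for _, reason in design.dropped_columns)

    def test_absent_gene_rejected(self, mode_study):
        with pytest.raises(ValidationError, match="absent"):
            build_tsg_design("NOT_A_GENE", mode_study.cohorts[0])


@pytest.fixture(scope="module")
def fits(mode_study, mode_gene):
    out = []
    for cohort in mode_study.cohorts:
        design = build_tsg_design(mode_gene, cohort)
        out.append(fit_tsg_model(design, seed=3))
    return out


class TestFitAndAggregate:

    def test_cnv_coefficient_positive_and_dominant(self, fits):
        for fit in fits:
            assert fit.coefficients["cnv"] > 0
            top = max(fit.coefficients, key=lambda k: abs(fit.coefficients[k]))
            assert top == "cnv"

    def test_cognate_mirnas_negative(self, mode_study, mode_gene, fits):
        cognates = mode_study.config.cognate_mirnas[mode_gene]
        for fit in fits:
            vals = [fit.coefficients.get(f"mirna:{m}", 0.0) for m in cognates]
            assert min(vals) < 0

    def test_aggregation_calls_cnv_positive(self, fits, mode_study, mode_gene):
        rp = aggregate_tsg_predictors(fits, n_perm=10_000, seed=2)
        t = rp.table
        assert t.loc["cnv", "pfp_up"] < 0.05
        cognates = [f"mirna:{m}" for m in mode_study.config.cognate_mirnas[mode_gene]]
        assert min(t.loc[c, "pfp_down"] for c in cognates if c in t.index) < 0.05

    def test_predictor_in_single_type_excluded(self):
        a = PenalizedModelResult("g", "T01", {"cnv": 0.5, "mirna:m1": -0.1})
        b = PenalizedModelResult("g", "T02", {"cnv": 0.4, "mirna:m2": -0.2})
        rp = aggregate_tsg_predictors([a, b], min_lists=2, n_perm=500, seed=0)
        assert "mirna:m1" not in rp.table.index
        assert "cnv" in rp.table.index

    def test_single_type_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_tsg_predictors([PenalizedModelResult("g", "T01", {"cnv": 1.0})])
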