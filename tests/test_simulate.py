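"""The synthetic cohort generator and its truth record."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmir.datatypes import ValidationError
from panmir.preprocess import log2_plus1
from panmir.simulate import (
    default_config,
    generate_cohorts,
    read_truth,
    simulate_study,
    truth_report,
)

from conftest import tiny_sim_config


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = simulate_study(tiny_sim_config(seed=7))
        b = simulate_study(tiny_sim_config(seed=7))
        for ca, cb in zip(a.cohorts, b.cohorts):
            assert ca.mrna.data.equals(cb.mrna.data)
            assert ca.mirna.data.equals(cb.mirna.data)
            assert ca.methylation.data.equals(cb.methylation.data)
            assert ca.mutations.records.equals(cb.mutations.records)
        assert a.target_map.pairs.equals(b.target_map.pairs)

    def test_different_seeds_differ(self):
        a = simulate_study(tiny_sim_config(seed=1))
        b = simulate_study(tiny_sim_config(seed=2))
        assert not a.cohorts[0].mrna.data.equals(b.cohorts[0].mrna.data)


class TestStructure:
    def test_default_conditions_dimensions(self):
        cohorts, truth = generate_cohorts(default_config(seed=3))
        assert len(cohorts) == 6
        for c in cohorts:
            assert c.n_samples == 150
            assert c.mirna.n_features == 300
            assert c.mrna.n_features == 800
        assert len(truth.drivers.drop_duplicates(subset=["signature", "mirna"])) == 20
        assert len(truth.pairs) == 40

    def test_candidate_pair_counts(self):
        study = simulate_study(default_config(seed=3))
        src = study.target_map.pairs["source_count"]
        assert (src >= 2).sum() == 2000  # 40 planted + 1960 decoys
        assert (src == 1).sum() == 100
        assert len(study.tsg_genes) == 140

    def test_methylation_in_unit_interval(self, tiny_study):
        for c in tiny_study.cohorts:
            beta = c.methylation.values
            assert beta.min() >= 0 and beta.max() <= 1

    def test_inconsistent_config_rejected(self):
        cfg = tiny_sim_config()
        cfg.repressive_pairs = [("miR-0001", "G0001", +0.5, 1.0)]
        with pytest.raises(ValidationError, match="slope"):
            simulate_study(cfg)
        cfg = tiny_sim_config()
        cfg.tsg_modes = {"NOPE": "exclusive"}
        with pytest.raises(ValidationError):
            simulate_study(cfg)


class TestPlantedEffects:
    def test_noise_free_pair_recovers_exact_slope(self):
        cfg = tiny_sim_config(
            seed=5, mutation_rate=0.0, cnv_effect=0.0, n_cancer_types=1
        )
        cfg.repressive_pairs = [(cfg.mirna_ids[0], cfg.tsg_genes[0], -0.5, 0.0)]
        study = simulate_study(cfg)
        c = study.cohorts[0]
        x = log2_plus1(c.mirna).data.loc[cfg.mirna_ids[0]].to_numpy()
        y = log2_plus1(c.mrna).data.loc[cfg.tsg_genes[0]].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-0.5, abs=1e-8)

    @pytest.mark.parametrize("mode,sign", [("exclusive", -1), ("cooccurring", +1)])
    def test_regulator_arm_correlation_sign(self, tiny_study, mode, sign):
        modes = tiny_study.truth.tsg_modes.set_index("gene")
        gene = modes.index[modes["mode"] == mode][0]
        c = tiny_study.cohorts[0]
        mirnas = modes.loc[gene, "cognate_mirnas"].split(",")
        probes = modes.loc[gene, "cognate_probes"].split(",")
        m = log2_plus1(c.mirna).data.loc[mirnas].mean(axis=0)
        b = c.methylation.data.loc[probes].mean(axis=0)
        rho = stats.spearmanr(m, b).statistic
        assert np.sign(rho) == sign


class TestTruthReport:
    def test_round_trip(self, tiny_study, tmp_path):
        truth_report(tiny_study.truth, tmp_path)
        back = read_truth(tmp_path)
        pd.testing.assert_frame_equal(back.drivers, tiny_study.truth.drivers)
        pd.testing.assert_frame_equal(back.pairs, tiny_study.truth.pairs, check_dtype=False)
        pd.testing.assert_frame_equal(back.tsg_modes, tiny_study.truth.tsg_modes)
        pd.testing.assert_frame_equal(
            back.phenotypes, tiny_study.truth.phenotypes, check_exact=False
        )

    def test_mode_table_row_count(self, tiny_study):
        assert len(tiny_study.truth.tsg_modes) == len(tiny_study.config.tsg_modes)
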