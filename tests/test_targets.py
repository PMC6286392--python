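"""Partial Spearman screening, enrichment and the bootstrap TSG null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmir.datatypes import TargetMap, ValidationError
from panmir.targets import (
    PairCorrelationMatrix,
    TsgScreenContext,
    bootstrap_tsg_null,
    build_pair_matrix,
    count_repressed_tsg,
    fisher_enrichment,
    myc_cooccurrence_check,
    partial_spearman,
    recurrent_negative_pairs,
)


def _residual_oracle(x, y, z):
    """Partial Spearman via residual-on-ranks regression."""
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))

    def _resid(a, b):
        b1 = np.column_stack([np.ones_like(b), b])
        coef, *_ = np.linalg.lstsq(b1, a, rcond=None)
        return a - b1 @ coef

    ex, ey = _resid(rx, rz), _resid(ry, rz)
    return float(np.corrcoef(ex, ey)[0, 1])


class TestPartialSpearman:
    def test_constant_z_equals_plain_spearman(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        rho, p = partial_spearman(x, y, np.zeros(40))
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_identical_vectors_give_unit_rho(self, rng):
        x = rng.standard_normal(30)
        z = (rng.random(30) < 0.3).astype(int)
        rho, p = partial_spearman(x, x, z)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_matches_residualization_oracle(self, rng):
        for _ in range(5):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            z = (rng.random(30) < 0.4).astype(int)
            rho, _ = partial_spearman(x, y, z)
            assert rho == pytest.approx(_residual_oracle(x, y, z), abs=1e-10)

    def test_symmetric_and_monotone_invariant(self, rng):
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        z = (rng.random(25) < 0.5).astype(int)
        r1, _ = partial_spearman(x, y, z)
        r2, _ = partial_spearman(y, x, z)
        r3, _ = partial_spearman(np.exp(x), y**3, z)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            partial_spearman([1, 2, 3], [1, 2, 3], [0, 1, 0])


@pytest.fixture(scope="module")
def screened(tiny_study):
    return tiny_study, build_pair_matrix(tiny_study.target_map, tiny_study.cohorts)


class TestBuildPairMatrix:

    def test_planted_pairs_recorded_negative(self, screened):
        """Planted repressions are recorded with negative rho in nearly every
        type (an occasional cell can miss alpha at this cohort size)."""
        study, pm = screened
        total = recorded = 0
        for mi, g, *_ in study.config.repressive_pairs:
            row = pm.rho.loc[(mi, g)]
            assert row.notna().sum() >= len(row) - 1
            assert (row.dropna() < 0).all()
            total += len(row)
            recorded += row.notna().sum()
        assert recorded / total >= 0.9

    def test_recorded_cells_within_bounds(self, screened):
        _, pm = screened
        vals = pm.rho.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert (np.abs(finite) <= 1).all()

    def test_low_expressed_genes_not_evaluable(self, screened):
        study, pm = screened
        cfg = study.config
        n_low = int(cfg.frac_low_expressed * cfg.n_genes)
        n_sig = sum(len(s.genes) for s in cfg.signatures)
        lo = min(max(n_sig, cfg.n_genes - 140 - n_low), cfg.n_genes - n_low)
        low = set(cfg.gene_ids[lo : lo + n_low])
        genes_in_matrix = set(pm.rho.index.get_level_values("gene"))
        assert not (low & genes_in_matrix)


class TestRecurrentNegativePairs:
    def _matrix(self, rho):
        idx = pd.MultiIndex.from_tuples(rho.index, names=["mirna", "gene"])
        return PairCorrelationMatrix(pd.DataFrame(rho.to_numpy(), index=idx,
                                                  columns=rho.columns))

    def test_pair_below_min_types_excluded(self, rng):
        rows = {(f"m{i}", f"g{i}"): rng.uniform(-0.6, -0.1, 6) for i in range(10)}
        rho = pd.DataFrame(rows).T
        rho.iloc[0, :2] = np.nan  # only 4 recorded cells
        hits = recurrent_negative_pairs(self._matrix(rho), min_types=5, fdr=1.1)
        assert ("m0", "g0") not in hits
        assert len(hits) == 9

    def test_most_negative_pair_has_smallest_rp(self, rng):
        rows = {(f"m{i}", f"g{i}"): rng.uniform(-0.3, 0.5, 6) for i in range(20)}
        rows[("mx", "gx")] = np.full(6, -0.9)
        _, rp = recurrent_negative_pairs(
            self._matrix(pd.DataFrame(rows).T), min_types=5, return_rp=True
        )
        assert rp.table["rp_down"].idxmin() == ("mx", "gx")


class TestFisherEnrichment:
    def test_empty_hits_p_one(self):
        res = fisher_enrichment(set(), {"a", "b"}, {"a", "b", "c"})
        assert res.p == 1.0

    def test_matches_hypergeometric_enumeration(self):
        universe = {f"g{i}" for i in range(20)}
        annotation = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(5)}  # all annotated
        res = fisher_enrichment(hits, annotation, universe)
        # brute force: P(table at least as extreme) over hypergeom(20, 10, 5)
        dist = stats.hypergeom(20, 10, 5)
        p_obs = dist.pmf(5)
        ref = sum(dist.pmf(k) for k in range(6) if dist.pmf(k) <= p_obs * (1 + 1e-9))
        assert res.p == pytest.approx(ref, rel=1e-9)

    def test_odds_ratio_one_gives_p_one(self):
        universe = {f"g{i}" for i in range(12)}
        annotation = {f"g{i}" for i in range(6)}  # half the universe
        hits = {"g0", "g1", "g2", "g6", "g7", "g8"}  # half annotated
        res = fisher_enrichment(hits, annotation, universe)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment({"zz"}, {"a"}, {"a", "b"})


@pytest.fixture(scope="module")
def stub_context():
    """A field where exactly 10 of 40 miRNAs carry one strongly repressed
    TSG target each; a chosen list's count follows a hypergeometric."""
    rng = np.random.default_rng(7)
    rows = {}
    for i in range(40):
        if i < 10:
            rows[(f"m{i}", f"tsg{i}")] = np.full(6, -0.9) + rng.uniform(0, 0.01, 6)
        for j in range(3):  # decoy field pairs
            rows[(f"m{i}", f"dec{i}_{j}")] = rng.uniform(-0.25, 0.35, 6)
    rho = pd.DataFrame(rows).T
    idx = pd.MultiIndex.from_tuples(rho.index, names=["mirna", "gene"])
    pm = PairCorrelationMatrix(pd.DataFrame(rho.to_numpy(), index=idx,
                                            columns=rho.columns))
    tsg = {f"tsg{i}" for i in range(10)}
    return TsgScreenContext(pm, tsg, min_types=5, fdr=0.05, n_perm=1000)


class TestBootstrapTsgNull:

    def test_count_statistic_matches_construction(self, stub_context):
        assert count_repressed_tsg(stub_context, [f"m{i}" for i in range(10)]) == 10
        assert count_repressed_tsg(stub_context, ["m20", "m25"]) == 0

    def test_null_matches_analytic_hypergeometric(self, stub_context):
        pool = [f"m{i}" for i in range(40)]
        res = bootstrap_tsg_null(
            pool, 8, stub_context, B=400, seed=3, observed=4.0
        )
        # null count ~ Hypergeom(40, 10, 8); percentile of 4 = CDF(4)
        ref = stats.hypergeom(40, 10, 8).cdf(4)
        assert res.ecdf_percentile == pytest.approx(ref, abs=0.08)

    def test_observed_above_all_null(self, stub_context):
        pool = [f"m{i}" for i in range(40)]
        res = bootstrap_tsg_null(pool, 2, stub_context, B=120, seed=5, observed=11)
        assert res.ecdf_percentile == 1.0
        assert res.p_upper == 0.0
        assert res.p_upper_smoothed <= 1 / 121 + 1e-12

    def test_list_longer_than_pool_rejected(self, stub_context):
        with pytest.raises(ValidationError):
            bootstrap_tsg_null(["m1"], 2, stub_context, B=100, seed=1, observed=0)


class TestMycCooccurrence:
    def test_perfect_cooccurrence_significant(self):
        mut = np.zeros(40, dtype=int)
        mut[:10] = 1
        table = myc_cooccurrence_check({("TSG1", "T01"): mut}, {"T01": mut.copy()})
        assert table["p_adj"].iloc[0] < 0.05

    def test_independent_vectors_not_called(self, rng):
        tsg_mut, amp = {}, {}
        for t in range(12):
            amp[f"T{t}"] = (rng.random(60) < 0.2).astype(int)
            for g in range(8):
                tsg_mut[(f"G{g}", f"T{t}")] = (rng.random(60) < 0.1).astype(int)
        table = myc_cooccurrence_check(tsg_mut, amp)
        assert len(table) == 96
        assert (table["p_adj"] >= 0.05).all()

    def test_all_zero_amplification_p_one(self):
        mut = np.array([1, 0, 1, 0])
        table = myc_cooccurrence_check({("G", "T"): mut}, {"T": np.zeros(4, dtype=int)})
        assert table["p"].iloc[0] == 1.0
        assert bool(table["degenerate"].iloc[0])
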