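"""Standard recovery and calibration experiments on the synthetic study.

These functions bundle the study conditions (generator defaults) with the
pipeline stages so that calibration and recovery can be measured
reproducibly: driver-miRNA recovery across cancer types, null calibration of
the univariate filter and the rank product, repressive-pair recovery with
TSG enrichment and its bootstrap null, and exclusivity discrimination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .exclusivity import (
    RegulatorPartition,
    bootstrap_exclusivity,
    compute_pi,
    partition_from_truth,
)
from .preprocess import detection_filter, log2_plus1, standardize, standardize_matrix
from .rankprod import rank_product, significant_items
from .regression import associate_signature, univariate_filter
from .signatures import score_signature
from .simulate import SimConfig, default_config, simulate_study
from .targets import (
    TsgScreenContext,
    bootstrap_tsg_null,
    build_pair_matrix,
    count_repressed_tsg,
    eligible_mirna_pool,
    fisher_enrichment,
    recurrent_negative_pairs,
)


def single_signature_config(seed: int, driver_effect: float = 0.4) -> SimConfig:
    """Study conditions reduced to one signature (10 drivers, 6 types)."""
    cfg = default_config(seed=seed, driver_effect=driver_effect)
    cfg.signatures = cfg.signatures[:1]
    drivers = set(cfg.signatures[0].driver_mirnas)
    cfg.repressive_pairs = [p for p in cfg.repressive_pairs if p[0] in drivers]
    cfg.tsg_modes = {}
    cfg.cognate_mirnas = {}
    cfg.validate()
    return cfg


def driver_recovery_trial(seed: int, n_perm: int = 10_000) -> dict:
    """Recover the planted signature drivers in the correct orientation.

    Returns the number of the 10 planted drivers recovered with the right
    sign at pfp < 0.05 and the number of false-positive calls.
    """
    cfg = single_signature_config(seed)
    study = simulate_study(cfg)
    coef = associate_signature(
        study.cohorts, study.signatures, seed=child_seed(seed, "assoc")
    )
    name = study.signatures[0].name
    rp = rank_product(coef[name], n_perm=n_perm, seed=child_seed(seed, "rp"))
    pos, neg = significant_items(rp, 0.05)
    truth = study.truth.drivers.drop_duplicates(subset=["mirna"])
    tp_pos = set(truth.loc[truth["sign"] > 0, "mirna"])
    tp_neg = set(truth.loc[truth["sign"] < 0, "mirna"])
    recovered = len(tp_pos & set(pos)) + len(tp_neg & set(neg))
    false_pos = len(set(pos) - tp_pos) + len(set(neg) - tp_neg)
    return {"recovered": recovered, "n_planted": len(truth), "false_positives": false_pos}


def null_study(seed: int):
    """The study conditions under the global null (driver effect 0)."""
    return simulate_study(default_config(seed=seed, driver_effect=0.0))


def univariate_null_stats(study) -> tuple[float, pd.DataFrame, int]:
    """Retention fraction of the p < 0.2 filter (pooled over signatures and
    cancer types, with the number of tests), and the per-type univariate
    correlation matrix (miRNA x cancer type) for the first signature."""
    sig = study.signatures[0]
    retained = 0
    total = 0
    slope_cols = {}
    for cohort in study.cohorts:
        aligned = cohort.aligned(require=["mrna", "mirna"])
        mrna = detection_filter(log2_plus1(aligned.mrna), 0.8)
        mirna = detection_filter(aligned.mirna, 0.8)
        mirna = log2_plus1(mirna)
        Xf, _ = standardize_matrix(mirna.data, axis=1)
        X = Xf.T
        for s in study.signatures:
            y = standardize(score_signature(mrna, s).scores)
            kept = univariate_filter(y, X, 0.2)
            retained += len(kept)
            total += X.shape[1]
            if s.name == sig.name:
                slope_cols[cohort.cancer_type] = pd.Series(
                    (X.to_numpy() * y[:, None]).sum(axis=0) / (len(y) - 1),
                    index=X.columns,
                )
    slopes = pd.DataFrame(slope_cols)
    return retained / total, slopes, total


def null_false_positive_trial(
    seed: int, n_items: int = 300, n_lists: int = 6, n_perm: int = 2000
) -> int:
    """False-positive calls of significant_items on a global-null matrix."""
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(
        rng.standard_normal((n_items, n_lists)),
        index=[f"item{i}" for i in range(n_items)],
    )
    rp = rank_product(mat, n_perm=n_perm, seed=child_seed(seed, "rp"))
    pos, neg = significant_items(rp, 0.05)
    return len(pos) + len(neg)


def pair_screen_trial(seed: int, B: int = 1000, screen_n_perm: int = 2000) -> dict:
    """Repressive-pair recovery, TSG enrichment and the bootstrap null.

    The observed miRNA list is the planted driver set (the signature-
    associated miRNAs by construction); recovery is measured on the full
    candidate field.
    """
    study = simulate_study(default_config(seed=seed))
    pm = build_pair_matrix(study.target_map, study.cohorts)
    planted = set(
        map(tuple, study.truth.pairs[["mirna", "gene"]].itertuples(index=False, name=None))
    )
    hits = recurrent_negative_pairs(
        pm, min_types=5, n_perm=screen_n_perm, seed=child_seed(seed, "screen")
    )
    repressed_genes = {g for _, g in hits}
    universe = {g for _, g in pm.pair_ids}
    enr = fisher_enrichment(repressed_genes, study.tsg_genes, universe)

    drivers = sorted(set(study.truth.drivers["mirna"]))
    pool = eligible_mirna_pool(study.cohorts) & set(study.target_map.pairs["mirna"])
    ctx = TsgScreenContext(pm, study.tsg_genes, 5, 0.05, screen_n_perm)
    observed = count_repressed_tsg(ctx, drivers, seed=child_seed(seed, "obs"))
    boot = bootstrap_tsg_null(
        pool, len(drivers), ctx, B=B, seed=child_seed(seed, "boot"), observed=observed
    )
    return {
        "pairs_recovered": len(set(hits) & planted),
        "n_planted": len(planted),
        "n_hits": len(hits),
        "fisher_p": enr.p,
        "observed_tsg": observed,
        "bootstrap_percentile": boot.ecdf_percentile,
        "bootstrap_p_upper": boot.p_upper,
    }


def exclusivity_trial(seed: int, B: int = 1000) -> dict:
    """Exclusivity percentiles for one exclusive, one cooccurring and one
    randomly drawn regulator set in a single synthetic cohort."""
    cfg = default_config(seed=seed, n_cancer_types=1)
    study = simulate_study(cfg)
    cohort = study.cohorts[0]
    modes = study.truth.tsg_modes.set_index("gene")
    out: dict = {}
    for mode in ("exclusive", "cooccurring"):
        gene = modes.index[modes["mode"] == mode][0]
        part = partition_from_truth(cohort, gene, modes.loc[gene])
        res = bootstrap_exclusivity(
            cohort, gene, part, B=B, seed=child_seed(seed, "excl", gene)
        )
        pcts = {lab: pct for lab, _, pct in res.differences}
        out[mode] = {
            "D1": pcts["D1_AA_minus_AB"],
            "D2": pcts["D2_BB_minus_AB"],
            "pi": (res.pi_AA, res.pi_BB, res.pi_AB),
        }
    # null calibration: a random regulator set of the same shape
    rng = np.random.default_rng(child_seed(seed, "null-part"))
    aligned = cohort.aligned(require=["mirna", "methylation", "mrna"])
    mirna = log2_plus1(detection_filter(aligned.mirna, 0.8))
    mirnas = list(rng.choice(mirna.feature_ids, size=5, replace=False))
    probes = list(rng.choice(aligned.methylation.feature_ids, size=5, replace=False))
    part = RegulatorPartition(
        "random", cohort.cancer_type,
        mirna.data.loc[mirnas].T, aligned.methylation.data.loc[probes].T,
    )
    res = bootstrap_exclusivity(
        cohort, "random", part, B=B, seed=child_seed(seed, "excl-null")
    )
    out["random"] = {lab: pct for lab, _, pct in res.differences}
    return out


def pi_null_level(seed: int, n: int = 200, n_cols: int = 60) -> float:
    """Mean Pi of independent-noise regulator sets (nominal level ~0.025)."""
    rng = np.random.default_rng(seed)
    a = pd.DataFrame(rng.standard_normal((n, n_cols)))
    b = pd.DataFrame(rng.standard_normal((n, n_cols)))
    b.columns = [f"b{i}" for i in range(n_cols)]
    part = RegulatorPartition("null", "none", a, b)
    return float(np.mean(compute_pi(part)))
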