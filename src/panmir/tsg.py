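"""Integrative penalised models of tumour-suppressor-gene expression.

For one TSG in one cohort the response is its standardized log2(x+1)
expression over the samples where all five omics layers are present; the
covariates are the gene's copy-number dosage, one 0/1 indicator per mutation
classification observed for the gene, the beta values of every methylation
probe mapped to the gene, and the whole detection-filtered miRNA layer. All
columns are standardized; zero-variance columns are dropped and recorded.
Fitting reuses the cross-validated elastic net, and per-predictor
coefficients are aggregated across cancer types with the rank product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .datatypes import OmicsCohort, ValidationError
from .preprocess import detection_filter, log2_plus1, standardize
from .regression import L2_GRID, PenalizedModelResult, fit_elastic_net
from .rankprod import RankProductResult, rank_product

log = logging.getLogger(__name__)


@dataclass
class TsgDesign:
    """Standardized response and covariates for one (gene, cancer type)."""

    gene: str
    cancer_type: str
    response: np.ndarray
    covariates: pd.DataFrame  # samples x columns, standardized; role-labelled names
    dropped_columns: list = field(default_factory=list)  # (column, reason)
    flagged_columns: list = field(default_factory=list)  # near-constant survivors


def build_tsg_design(
    gene: str,
    cohort: OmicsCohort,
    probe_to_gene: dict | None = None,
    detection: float = 0.8,
) -> TsgDesign:
    """Assemble the standardized design matrix for one TSG in one cohort."""
    aligned = cohort.aligned(require=["mrna", "mirna", "cnv", "methylation"])
    if aligned.mutations is None:
        raise ValidationError(f"{cohort.cancer_type}: mutation layer required")
    samples = aligned.mrna.sample_ids
    n = len(samples)
    probe_to_gene = probe_to_gene if probe_to_gene is not None else aligned.probe_to_gene

    mrna = aligned.mrna
    if mrna.scale == "raw":
        mrna = log2_plus1(mrna)
    if gene not in mrna.data.index:
        raise ValidationError(f"gene {gene!r} absent from expression matrix")
    y = standardize(mrna.data.loc[gene].to_numpy())

    cols: dict[str, np.ndarray] = {}
    dropped: list = []
    flagged: list = []

    if gene in aligned.cnv.data.index:
        cols["cnv"] = aligned.cnv.data.loc[gene].to_numpy(dtype=float)
    else:
        dropped.append(("cnv", "gene absent from copy-number layer"))

    recs = aligned.mutations.for_gene(gene)
    recs = recs[recs["sample"].isin(set(samples))]
    observed_types = sorted(set(recs["classification"]))
    if not observed_types:
        dropped.append(("mutation_type:*", "no mutations observed for gene"))
    for vc in observed_types:
        carriers = set(recs.loc[recs["classification"] == vc, "sample"])
        cols[f"mutation_type:{vc}"] = np.array(
            [1.0 if s in carriers else 0.0 for s in samples]
        )
        if len(carriers) == 1:
            flagged.append(f"mutation_type:{vc}")

    probes = sorted(p for p, g in probe_to_gene.items() if g == gene)
    for p in probes:
        if p in aligned.methylation.data.index:
            cols[f"methylation:{p}"] = aligned.methylation.data.loc[p].to_numpy(dtype=float)
    mirna = detection_filter(aligned.mirna, detection)
    if mirna.scale == "raw":
        mirna = log2_plus1(mirna)
    for mi in mirna.data.index:
        cols[f"mirna:{mi}"] = mirna.data.loc[mi].to_numpy(dtype=float)

    std_cols = {}
    for name, v in cols.items():
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            dropped.append((name, "zero variance"))
            continue
        std_cols[name] = (v - v.mean()) / sd
    X = pd.DataFrame(std_cols, index=samples)
    if dropped:
        log.info("tsg design %s/%s: dropped %d columns", gene, cohort.cancer_type, len(dropped))
    return TsgDesign(gene, cohort.cancer_type, y, X, dropped, flagged)


def fit_tsg_model(
    design: TsgDesign,
    l2_grid=L2_GRID,
    n_folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> PenalizedModelResult:
    """Elastic-net fit of the TSG design (same contract as the miRNA model)."""
    return fit_elastic_net(
        design.response,
        design.covariates,
        l2_grid=l2_grid,
        n_folds=n_folds,
        seed=seed,
        signature_name=design.gene,
        cancer_type=design.cancer_type,
        **kwargs,
    )


def aggregate_tsg_predictors(
    results: list[PenalizedModelResult],
    min_lists: int = 2,
    n_perm: int = 10_000,
    seed: int = 0,
) -> RankProductResult:
    """Rank-product aggregation of predictor coefficients across cancer types.

    Predictors are aligned by role label (``cnv``, ``mutation_type:<label>``,
    ``methylation:<probe>``, ``mirna:<id>``); a predictor present in fewer
    than ``min_lists`` cancer types is excluded by the rank product itself.
    """
    if len(results) < 2:
        raise ValidationError("aggregate_tsg_predictors needs >= 2 fitted cancer types")
    types = [r.cancer_type for r in results]
    if len(set(types)) != len(types):
        raise ValidationError("duplicate cancer types among results")
    labels: list[str] = []
    for r in results:
        for k in r.coefficients:
            if k not in labels:
                labels.append(k)
    mat = pd.DataFrame(np.nan, index=labels, columns=types)
    for r in results:
        for k, b in r.coefficients.items():
            mat.loc[k, r.cancer_type] = b
    return rank_product(mat, min_lists=min_lists, n_perm=n_perm, seed=seed)


def run_tsg_analysis(
    gene: str,
    cohorts: list[OmicsCohort],
    probe_to_gene: dict | None = None,
    detection: float = 0.8,
    min_lists: int = 2,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[list[PenalizedModelResult], RankProductResult]:
    """Fit the TSG model in every cohort and aggregate the predictors."""
    fits = []
    for cohort in cohorts:
        design = build_tsg_design(gene, cohort, probe_to_gene, detection)
        fits.append(
            fit_tsg_model(design, seed=child_seed(seed, "tsg", gene, cohort.cancer_type))
        )
    rp = aggregate_tsg_predictors(fits, min_lists, n_perm, seed=child_seed(seed, "tsg-agg", gene))
    return fits, rp
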