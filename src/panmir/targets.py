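"""miRNA-target anticorrelation screening and TSG enrichment.

Predicted miRNA-target pairs are scored per cancer type by the Spearman
correlation of miRNA vs target mRNA expression, partial to the target's
binary non-silent mutation status. A cell is recorded only when the
two-sided p-value (asymptotic t approximation) is below alpha, otherwise it
is NA. Pairs assessed in at least ``min_types`` cancer types are aggregated
with the rank product in the most-negative-first orientation; the repressed
target genes are then tested for tumour-suppressor enrichment with Fisher's
exact test and against a bootstrap null that redraws random miRNA lists of
the same length and reruns the whole screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed
from .datatypes import (
    DEFAULT_NONSILENT,
    OmicsCohort,
    TargetMap,
    ValidationError,
)
from .preprocess import detection_filter, log2_plus1, mutation_binary_vector
from .rankprod import fractional_rank, rank_product_from_ranks

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------

def _rank_std(v: np.ndarray) -> np.ndarray | None:
    """Fractional ranks standardized to mean 0, unit (n-1) sd; None if constant."""
    r = stats.rankdata(v, method="average")
    sd = r.std(ddof=1)
    if sd == 0:
        return None
    return (r - r.mean()) / sd


def _t_p(rho: float, df: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y given binary z.

    Fractional-rank transforms feed the Pearson recursion
    rho_xy.z = (rho_xy - rho_xz rho_yz) / sqrt((1 - rho_xz^2)(1 - rho_yz^2)),
    with a two-sided p from t = rho sqrt((n-3)/(1-rho^2)) on n-3 df. A
    constant z falls back to the plain Spearman correlation on n-2 df;
    |rho_xz| = 1 or |rho_yz| = 1 leaves the partial correlation undefined
    (NaN is returned).
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    n = len(x)
    if not (len(y) == n == len(z)):
        raise ValidationError("partial_spearman: vectors are not aligned")
    if n < 5:
        raise ValidationError("partial_spearman needs n >= 5")
    rx, ry = _rank_std(x), _rank_std(y)
    if rx is None or ry is None:
        return np.nan, np.nan
    rz = _rank_std(z)
    r_xy = float(rx @ ry) / (n - 1)
    if rz is None:
        log.debug("partial_spearman: constant covariate, plain Spearman fallback")
        return r_xy, _t_p(r_xy, n - 2)
    r_xz = float(rx @ rz) / (n - 1)
    r_yz = float(ry @ rz) / (n - 1)
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        return np.nan, np.nan
    rho = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    return rho, _t_p(rho, n - 3)


# ---------------------------------------------------------------------------
# pair correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelationMatrix:
    """(miRNA, gene) x cancer-type partial Spearman rhos, NA when not significant."""

    rho: pd.DataFrame  # MultiIndex (mirna, gene) x cancer types
    n_samples: dict = field(default_factory=dict)  # cancer type -> n
    alpha: float = 0.05

    def restrict_mirnas(self, mirnas) -> "PairCorrelationMatrix":
        keep = self.rho.index.get_level_values("mirna").isin(set(mirnas))
        return PairCorrelationMatrix(self.rho[keep], dict(self.n_samples), self.alpha)

    @property
    def pair_ids(self) -> list[tuple]:
        return list(self.rho.index)


def build_pair_matrix(
    target_map: TargetMap,
    cohorts: list[OmicsCohort],
    alpha: float = 0.05,
    detection: float = 0.8,
    nonsilent_set=DEFAULT_NONSILENT,
) -> PairCorrelationMatrix:
    """Mutation-partialled Spearman screen of every candidate pair per cohort.

    A cell is evaluable only when both the miRNA and the target gene pass the
    detection filter in that cohort; it is recorded iff p < alpha. Pairs
    never evaluable anywhere are dropped with a logged count.
    """
    pairs = list(target_map.pairs[["mirna", "gene"]].itertuples(index=False, name=None))
    index = pd.MultiIndex.from_tuples(pairs, names=["mirna", "gene"])
    types = [c.cancer_type for c in cohorts]
    rho = pd.DataFrame(np.nan, index=index, columns=types)
    n_samples = {}

    for cohort in cohorts:
        aligned = cohort.aligned(require=["mrna", "mirna"])
        samples = aligned.mrna.sample_ids
        n = len(samples)
        n_samples[cohort.cancer_type] = n
        mrna = aligned.mrna
        if mrna.scale == "raw":
            mrna = log2_plus1(mrna)
        mrna = detection_filter(mrna, detection)
        mirna = aligned.mirna
        mirna = detection_filter(mirna, detection)
        if mirna.scale == "raw":
            mirna = log2_plus1(mirna)

        gvals = mrna.data
        mvals = mirna.data
        # rank-standardize every row once
        def _rows(df):
            out = {}
            for fid, row in zip(df.index, df.to_numpy()):
                out[fid] = _rank_std(row)
            return out

        zg = _rows(gvals)
        zm = _rows(mvals)

        by_gene: dict[str, list[str]] = {}
        for mi, g in pairs:
            if g in zg and mi in zm:
                by_gene.setdefault(g, []).append(mi)

        pos = {pair: i for i, pair in enumerate(pairs)}
        col = np.full(len(pairs), np.nan)
        for g in sorted(by_gene):
            ry = zg[g]
            if ry is None:
                continue
            if aligned.mutations is not None:
                zvec = mutation_binary_vector(aligned.mutations, g, samples, nonsilent_set)
            else:
                zvec = np.zeros(n, dtype=int)
            rz = _rank_std(zvec)
            r_yz = float(ry @ rz) / (n - 1) if rz is not None else 0.0
            for mi in by_gene[g]:
                rx = zm[mi]
                if rx is None:
                    continue
                r_xy = float(rx @ ry) / (n - 1)
                if rz is None:
                    r, p = r_xy, _t_p(r_xy, n - 2)
                else:
                    r_xz = float(rx @ rz) / (n - 1)
                    denom = (1 - r_xz**2) * (1 - r_yz**2)
                    if denom <= 0:
                        continue
                    r = float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom), -1, 1))
                    p = _t_p(r, n - 3)
                if p < alpha:
                    col[pos[(mi, g)]] = r
        rho[cohort.cancer_type] = col

    never = rho.isna().all(axis=1)
    # keep never-evaluable pairs out of the matrix but report the count
    if never.any():
        log.info("build_pair_matrix: %d pairs never significant/evaluable", int(never.sum()))
    return PairCorrelationMatrix(rho[~never], n_samples, alpha)


def _pair_ranks(m: PairCorrelationMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-type most-negative-first fractional ranks over every recorded cell."""
    ranks = pd.DataFrame(np.nan, index=m.rho.index, columns=m.rho.columns)
    sizes = np.zeros(m.rho.shape[1], dtype=int)
    for k, col in enumerate(m.rho.columns):
        vals = m.rho[col].to_numpy()
        mask = np.isfinite(vals)
        sizes[k] = int(mask.sum())
        if sizes[k]:
            ranks[col] = fractional_rank(vals)
    return ranks, sizes


def recurrent_negative_pairs(
    m: PairCorrelationMatrix,
    min_types: int = 5,
    fdr: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    mirnas=None,
    return_rp: bool = False,
):
    """Pairs consistently most-negative across cancer types.

    Per-type fractional ranks run over every recorded cell of the full
    candidate matrix — a pair's consistency is always judged against all
    other candidate pairs. When ``mirnas`` is given, aggregation (and the
    pfp correction) is restricted to the pairs of those miRNAs while the
    ranks keep the full-field scale. Pairs with fewer than ``min_types``
    recorded cells are excluded; pairs with rank-product pfp < ``fdr`` in
    the most-negative orientation are returned.
    """
    if len(m.rho) == 0:
        return ([], None) if return_rp else []
    ranks, sizes = _pair_ranks(m)
    usable = sizes >= 2
    ranks = ranks.loc[:, usable]
    sizes = sizes[usable]
    if mirnas is not None:
        keep = ranks.index.get_level_values("mirna").isin(set(mirnas))
        ranks = ranks[keep]
    counts = ranks.notna().sum(axis=1)
    if ranks.shape[1] == 0 or (counts >= min_types).sum() == 0:
        return ([], None) if return_rp else []
    rp = rank_product_from_ranks(ranks, sizes, min_lists=min_types, n_perm=n_perm, seed=seed)
    hits = list(rp.table.index[rp.table["pfp_down"] < fdr])
    return (hits, rp) if return_rp else hits


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    contingency: np.ndarray  # [[hit&ann, hit&~ann], [~hit&ann, ~hit&~ann]]
    odds_ratio: float
    p: float
    sided: str
    universe_size: int
    gene_hits: list


def fisher_enrichment(
    hit_genes: set, annotation: set, universe: set, sided: str = "two"
) -> EnrichmentResult:
    """Fisher exact test of annotation membership among hit genes."""
    universe = set(universe)
    if not universe:
        raise ValidationError("fisher_enrichment: empty universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValidationError("hit_genes must be a subset of the universe")
    ann = set(annotation) & universe
    a = len(hits & ann)
    b = len(hits - ann)
    c = len(ann - hits)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    alternative = {"two": "two-sided", "greater": "greater"}[sided]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return EnrichmentResult(table, float(odds), float(p), sided, len(universe), sorted(hits & ann))


# ---------------------------------------------------------------------------
# bootstrap TSG null
# ---------------------------------------------------------------------------

@dataclass
class TsgScreenContext:
    """Precomputed inputs for the repressed-TSG count statistic."""

    pair_matrix: PairCorrelationMatrix  # over every eligible miRNA's candidate pairs
    tsg_genes: set
    min_types: int = 5
    fdr: float = 0.05
    n_perm: int = 2000


def count_repressed_tsg(context: TsgScreenContext, mirnas, seed: int = 0) -> int:
    """Number of distinct TSGs among the repressed targets of a miRNA list."""
    hits = recurrent_negative_pairs(
        context.pair_matrix,
        context.min_types,
        context.fdr,
        context.n_perm,
        seed=seed,
        mirnas=mirnas,
    )
    genes = {g for _, g in hits}
    return len(genes & set(context.tsg_genes))


@dataclass
class BootstrapNullResult:
    B: int
    null_values: np.ndarray
    observed: float
    ecdf_percentile: float
    p_upper: float
    p_upper_smoothed: float
    seed: int


def bootstrap_tsg_null(
    eligible_mirnas,
    list_length: int,
    context: TsgScreenContext,
    B: int = 1000,
    seed: int = 0,
    observed: float | None = None,
    observed_mirnas=None,
) -> BootstrapNullResult:
    """Bootstrap null for the repressed-TSG count of a miRNA list.

    Each resample draws ``list_length`` miRNAs uniformly without replacement
    from the eligible pool and reruns the screen; the observed statistic's
    plain ecdf percentile (#{null <= observed} / B) and its upper-tail
    p-values are reported.
    """
    pool = sorted(set(eligible_mirnas))
    if list_length > len(pool):
        raise ValidationError("list_length exceeds the eligible miRNA pool")
    if B < 100:
        import warnings

        warnings.warn("B < 100 gives an unstable ecdf percentile", stacklevel=2)
    if observed is None:
        if observed_mirnas is None:
            raise ValidationError("provide observed or observed_mirnas")
        observed = count_repressed_tsg(context, observed_mirnas, seed=child_seed(seed, "obs"))
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        draw = rng.choice(pool, size=list_length, replace=False)
        null[b] = count_repressed_tsg(context, draw, seed=child_seed(seed, "boot", str(b)))
    pct = float(np.mean(null <= observed))
    return BootstrapNullResult(
        B=B,
        null_values=null,
        observed=float(observed),
        ecdf_percentile=pct,
        p_upper=1.0 - pct,
        p_upper_smoothed=float((np.sum(null >= observed) + 1) / (B + 1)),
        seed=seed,
    )


def eligible_mirna_pool(cohorts: list[OmicsCohort], detection: float = 0.8) -> set:
    """miRNAs passing the detection filter in at least one cohort."""
    pool: set = set()
    for c in cohorts:
        m = detection_filter(c.aligned(require=["mirna", "mrna"]).mirna, detection)
        pool |= set(m.feature_ids)
    return pool


# ---------------------------------------------------------------------------
# MYC amplification co-occurrence check
# ---------------------------------------------------------------------------

def myc_cooccurrence_check(
    tsg_mutations: dict, myc_amplification: dict
) -> pd.DataFrame:
    """One-sided Fisher tests of TSG mutation vs MYC amplification co-occurrence.

    ``tsg_mutations`` maps (gene, cancer_type) to a 0/1 vector;
    ``myc_amplification`` maps cancer_type to an aligned 0/1 vector. Returns
    a table with per-pair one-sided (greater) p and Benjamini-Hochberg
    adjusted p. All-zero vectors yield p = 1 and are flagged.
    """
    rows = []
    for (gene, ctype), mut in sorted(tsg_mutations.items()):
        amp = np.asarray(myc_amplification[ctype], dtype=int)
        mut = np.asarray(mut, dtype=int)
        if len(amp) != len(mut):
            raise ValidationError(f"({gene}, {ctype}): vectors are not aligned")
        degenerate = mut.sum() == 0 or amp.sum() == 0
        if degenerate:
            p = 1.0
        else:
            a = int(np.sum((mut == 1) & (amp == 1)))
            b = int(np.sum((mut == 1) & (amp == 0)))
            c = int(np.sum((mut == 0) & (amp == 1)))
            d = int(np.sum((mut == 0) & (amp == 0)))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"gene": gene, "cancer_type": ctype, "p": float(p), "degenerate": degenerate})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
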