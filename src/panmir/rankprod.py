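"""Rank-product meta-analysis across cancer-type lists.

Items (miRNAs, miRNA-target pairs, model predictors) are fractionally ranked
within each list, ranks are normalized by the per-list non-NA count, and the
geometric mean of an item's normalized ranks over the lists where it was
assessed is its rank product (RP). Small RP in the descending orientation
means consistently large values ("up"); small RP in the ascending
orientation means consistently small/negative values ("down").

Significance is a permutation test: under the null an item's rank in each
list is uniform on 1..n_k, independently across lists. Per-item p-values use
the (b+1)/(B+1) add-one estimator; an exact enumeration mode is available
when the Cartesian product of list sizes is small. The estimated false
positive proportion (pfp) follows the Breitling convention
pfp_i = p_i * n_items / rank(p_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ValidationError

log = logging.getLogger(__name__)

#: Largest Cartesian product of list sizes for which 'auto' uses enumeration.
MAX_EXACT_COMBINATIONS = 1_000_000


def fractional_rank(values, direction: str = "ascending") -> np.ndarray:
    """Rank a vector 1..n with ties averaged; NA inputs get NA ranks.

    ``descending`` ranks the largest value first. For untied data
    ``rank_desc = n + 1 - rank_asc``; the identity also holds with averaged
    ties.
    """
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    if not mask.any():
        raise ValidationError("fractional_rank: all values are NA")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    out = np.full(arr.shape, np.nan)
    vals = arr[mask]
    out[mask] = rankdata(vals if direction == "ascending" else -vals, method="average")
    return out


@dataclass
class RankProductResult:
    """Per-item RP, permutation p and estimated FDR (pfp) in both orientations.

    ``table`` is indexed by item id with columns
    ``rp_up, p_up, pfp_up, rp_down, p_down, pfp_down, n_lists``.
    The "up" orientation flags consistently large values, "down" consistently
    small/negative ones.
    """

    table: pd.DataFrame
    list_sizes: np.ndarray
    n_excluded: int = 0

    @property
    def item_ids(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _null_log_rp_exact(sizes: np.ndarray) -> np.ndarray:
    """All attainable mean-log-normalized-rank values over the rank lattice."""
    logs = [np.log(np.arange(1, n + 1) / n) for n in sizes]
    total = reduce(lambda a, b: np.add.outer(a, b).ravel(), logs)
    return total / len(sizes)


def _null_log_rp_perm(sizes: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    draws = np.zeros(n_perm)
    for n in sizes:
        draws += np.log(rng.integers(1, n + 1, size=n_perm) / n)
    return draws / len(sizes)


def rank_product(
    values: pd.DataFrame,
    min_lists: int = 2,
    n_perm: int = 10_000,
    seed: int | None = 0,
    method: str = "auto",
) -> RankProductResult:
    """Aggregate an items x lists value matrix (NaN = not assessed).

    Ranks are computed within each list over *every* non-NA cell, so excluded
    items (fewer than ``min_lists`` assessments) still shape the rank scale
    their competitors are measured on; only items with >= ``min_lists``
    non-NA entries are reported. p-values in the two orientations are
    computed against the same per-pattern null.
    """
    if values.shape[1] < 1:
        raise ValidationError("rank_product needs at least one list")
    arr = values.to_numpy(dtype=float)
    n_lists = arr.shape[1]
    n_nonna = np.isfinite(arr).sum(axis=0)
    if (n_nonna < 2).any():
        bad = list(values.columns[n_nonna < 2])
        raise ValidationError(f"lists with fewer than 2 non-NA items: {bad}")

    ranks_down = np.full(arr.shape, np.nan)  # ascending: most negative first
    for k in range(n_lists):
        col = arr[:, k]
        mask = np.isfinite(col)
        ranks_down[mask, k] = rankdata(col[mask], method="average")
    return rank_product_from_ranks(
        pd.DataFrame(ranks_down, index=values.index, columns=values.columns),
        n_nonna,
        min_lists=min_lists,
        n_perm=n_perm,
        seed=seed,
        method=method,
    )


def rank_product_from_ranks(
    ranks: pd.DataFrame,
    list_sizes,
    min_lists: int = 2,
    n_perm: int = 10_000,
    seed: int | None = 0,
    method: str = "auto",
) -> RankProductResult:
    """Rank product from precomputed ascending fractional ranks.

    ``ranks`` holds each item's most-negative-first rank within its list;
    ``list_sizes`` gives the number of ranked items per list, which may
    exceed the rows provided — this is how a subset of items (e.g. the
    target pairs of one miRNA list) is aggregated while staying ranked
    against the full candidate field. The descending rank is derived as
    n_k + 1 - rank, and the permutation null draws ranks uniformly from
    1..n_k.
    """
    arr = ranks.to_numpy(dtype=float)
    n_nonna = np.asarray(list_sizes, dtype=int)
    if len(n_nonna) != arr.shape[1]:
        raise ValidationError("list_sizes length does not match the rank matrix")
    ranks_down = arr
    ranks_up = n_nonna[None, :] + 1 - arr

    with np.errstate(divide="ignore", invalid="ignore"):
        log_norm_up = np.log(ranks_up / n_nonna)
        log_norm_down = np.log(ranks_down / n_nonna)
    counts = np.isfinite(arr).sum(axis=1)
    eligible = counts >= min_lists
    n_excluded = int((~eligible).sum())
    if n_excluded:
        log.info("rank_product: excluded %d items with < %d lists", n_excluded, min_lists)
    if not eligible.any():
        empty = pd.DataFrame(
            columns=["rp_up", "p_up", "pfp_up", "rp_down", "p_down", "pfp_down", "n_lists"]
        )
        return RankProductResult(empty, n_nonna, n_excluded)

    obs_up = np.nanmean(np.where(np.isfinite(arr), log_norm_up, np.nan), axis=1)
    obs_down = np.nanmean(np.where(np.isfinite(arr), log_norm_down, np.nan), axis=1)

    idx = np.where(eligible)[0]
    p_up = np.empty(len(idx))
    p_down = np.empty(len(idx))

    # Group items by missingness pattern: they share a null distribution.
    patterns: dict[tuple, list[int]] = {}
    for pos, i in enumerate(idx):
        pat = tuple(np.where(np.isfinite(arr[i]))[0])
        patterns.setdefault(pat, []).append(pos)

    rng = np.random.default_rng(seed)
    for pat, positions in sorted(patterns.items()):
        sizes = n_nonna[list(pat)]
        n_comb = float(np.prod(sizes.astype(float)))
        use_exact = method == "exact" or (method == "auto" and n_comb <= MAX_EXACT_COMBINATIONS)
        if use_exact:
            null = np.sort(_null_log_rp_exact(sizes))
            denom = len(null)
            add_one = 0
        else:
            null = np.sort(_null_log_rp_perm(sizes, n_perm, rng))
            denom = n_perm + 1
            add_one = 1
        for pos in positions:
            i = idx[pos]
            b_up = np.searchsorted(null, obs_up[i] + 1e-12, side="right")
            b_down = np.searchsorted(null, obs_down[i] + 1e-12, side="right")
            p_up[pos] = (b_up + add_one) / denom
            p_down[pos] = (b_down + add_one) / denom

    n_rep = len(idx)
    pfp_up = p_up * n_rep / rankdata(p_up, method="max")
    pfp_down = p_down * n_rep / rankdata(p_down, method="max")

    table = pd.DataFrame(
        {
            "rp_up": np.exp(obs_up[idx]),
            "p_up": p_up,
            "pfp_up": pfp_up,
            "rp_down": np.exp(obs_down[idx]),
            "p_down": p_down,
            "pfp_down": pfp_down,
            "n_lists": counts[idx],
        },
        index=ranks.index[idx],
    )
    return RankProductResult(table, n_nonna, n_excluded)


def significant_items(
    rp: RankProductResult, fdr_threshold: float = 0.05
) -> tuple[list, list]:
    """Items called consistently positive / consistently negative at pfp < threshold.

    The lists are disjoint: an item somehow passing in both orientations is
    assigned to the one with the smaller p.
    """
    if len(rp) == 0:
        return [], []
    t = rp.table
    pos = t["pfp_up"] < fdr_threshold
    neg = t["pfp_down"] < fdr_threshold
    both = pos & neg
    if both.any():
        prefer_up = t["p_up"] <= t["p_down"]
        pos = pos & (~both | prefer_up)
        neg = neg & (~both | ~prefer_up)
    return list(t.index[pos]), list(t.index[neg])
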