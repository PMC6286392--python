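"""Global preprocessing every downstream stage assumes.

The conventions here are deliberately strict and boring: log2(x+1) on raw
expression, an inclusive >=80% non-zero detection filter, standardization to
mean 0 / sample (n-1) standard deviation 1, binary non-silent mutation
vectors, and exclusion of cohorts with fewer than nine aligned samples.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_NONSILENT,
    VARIANT_VOCABULARY,
    DegenerateCovariateError,
    ExpressionMatrix,
    MutationTable,
    OmicsCohort,
    ValidationError,
)

log = logging.getLogger(__name__)


def log2_plus1(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1) cell-wise to a raw-scale matrix."""
    if m.scale != "raw":
        raise ValidationError(f"log2_plus1 expects a raw-scale matrix, got {m.scale!r}")
    if m.values.size and m.values.min() < 0:
        raise ValidationError("log2_plus1: negative input cell")
    return ExpressionMatrix(np.log2(m.data + 1.0), "log2p1")


def detection_filter(m: ExpressionMatrix, min_fraction: float = 0.8) -> ExpressionMatrix:
    """Keep features non-zero in at least ``min_fraction`` of samples (inclusive).

    Zero means exactly 0 after parsing; no epsilon is applied. An empty
    result is a warning, not an error.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac_nonzero = (m.data != 0).mean(axis=1)
    keep = frac_nonzero >= min_fraction
    if not keep.any():
        warnings.warn("detection_filter removed every feature", stacklevel=2)
    dropped = int((~keep).sum())
    if dropped:
        log.info("detection_filter: dropped %d/%d features", dropped, m.n_features)
    return ExpressionMatrix(m.data.loc[keep], m.scale)


def standardize(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to unit sample (n-1) standard deviation."""
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("standardize needs a 1-d vector of length >= 2")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateCovariateError("zero-variance vector cannot be standardized")
    return (arr - arr.mean()) / sd


def standardize_matrix(df: pd.DataFrame, axis: int = 1) -> tuple[pd.DataFrame, list]:
    """Standardize each row (axis=1) or column (axis=0) of a DataFrame.

    Zero-variance rows/columns are dropped with a logged warning; their
    labels are returned alongside the standardized frame.
    """
    values = df.to_numpy(dtype=float)
    if axis == 1:
        sd = values.std(axis=1, ddof=1)
        keep = (sd > 0) & np.isfinite(sd)
        out = df.loc[keep]
        vals = out.to_numpy(dtype=float)
        vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        result = pd.DataFrame(vals, index=out.index, columns=out.columns)
        dropped = list(df.index[~keep])
    else:
        sd = values.std(axis=0, ddof=1)
        keep = (sd > 0) & np.isfinite(sd)
        out = df.loc[:, keep]
        vals = out.to_numpy(dtype=float)
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
        result = pd.DataFrame(vals, index=out.index, columns=out.columns)
        dropped = list(df.columns[~keep])
    if dropped:
        log.warning("standardize_matrix: dropped %d zero-variance entries", len(dropped))
    return result, dropped


def mutation_binary_vector(
    t: MutationTable,
    gene: str,
    samples: Sequence[str],
    nonsilent_set: frozenset | set = DEFAULT_NONSILENT,
) -> np.ndarray:
    """0/1 per sample: 1 iff the gene carries any non-silent record in that sample.

    Unknown classification strings are warned about and treated as silent.
    """
    if len(samples) == 0:
        raise ValueError("mutation_binary_vector needs a non-empty sample list")
    recs = t.for_gene(gene)
    unknown = set(recs["classification"]) - VARIANT_VOCABULARY - set(nonsilent_set)
    if unknown:
        warnings.warn(
            f"unknown variant classifications treated as silent: {sorted(unknown)}",
            stacklevel=2,
        )
    hit = set(recs.loc[recs["classification"].isin(nonsilent_set), "sample"])
    return np.array([1 if s in hit else 0 for s in samples], dtype=int)


def exclude_small_cohorts(
    cohorts: Iterable[OmicsCohort], min_n: int = 9
) -> list[OmicsCohort]:
    """Drop cohorts whose aligned sample count is below ``min_n`` (i.e. < 9 by default)."""
    cohorts = list(cohorts)
    kept = []
    for c in cohorts:
        n = c.n_samples
        if n < min_n:
            log.info("excluding cohort %s: %d aligned samples < %d", c.cancer_type, n, min_n)
        else:
            kept.append(c)
    if not kept:
        raise ValidationError("every cohort was excluded (or none were provided)")
    return kept
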