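"""Univariate-filtered L1/L2 penalised regression of signature scores on miRNAs.

The model predicts a standardized signature score from standardized miRNA
log-expression. miRNAs are first screened by a permissive univariate F-test
(p < 0.2); the surviving covariates enter an elastic-net fit whose objective
is the Gaussian log-likelihood minus L1 and L2 penalties,

    maximise  -1/2 * ||y - Xb||^2  -  lambda1 * sum|b_j|  -  lambda2 * sum b_j^2.

For each lambda2 on a fixed grid, lambda1 is profiled over a log-spaced path
from lambda1_max (the smallest value giving the all-zero model) downwards,
scored by 10-fold cross-validated held-out Gaussian log-likelihood; the
(lambda1, lambda2) pair with the greatest CV log-likelihood wins and the
model is refit on the full data. The inner solve at fixed penalties is
delegated to scikit-learn's coordinate descent via the exact reparametrisation
alpha = (lambda1 + 2*lambda2)/n, l1_ratio = lambda1/(lambda1 + 2*lambda2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from ._seeds import child_seed
from .datatypes import OmicsCohort, ValidationError
from .preprocess import detection_filter, log2_plus1, standardize, standardize_matrix
from .signatures import score_signature

log = logging.getLogger(__name__)

L2_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class PenalizedModelResult:
    """A fitted penalised linear model for one (signature, cancer type)."""

    signature_name: str
    cancer_type: str
    coefficients: dict = field(default_factory=dict)
    intercept: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    cv_loglik: float = np.nan
    n_samples: int = 0
    fold_seed: int = 0


def univariate_filter(
    y: np.ndarray, X: pd.DataFrame, p_threshold: float = 0.2
) -> list:
    """Columns of X whose single-covariate regression F-test has p < threshold.

    ``X`` is samples x covariates; zero-variance columns are dropped with a
    warning. The F statistic of the univariate model equals
    r^2 (n-2) / (1 - r^2) on (1, n-2) degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValidationError("univariate_filter needs n >= 4")
    if X.shape[0] != n:
        raise ValidationError("y and X are not row-aligned")
    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("univariate_filter: dropped %d zero-variance covariates", degenerate.sum())
    yc = y - y.mean()
    xc = vals - vals.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (
            np.sqrt((xc**2).sum(axis=0)) * np.sqrt((yc**2).sum())
        )
        r = np.clip(r, -1.0, 1.0)
        fstat = r**2 * (n - 2) / (1 - r**2)
    p = stats.f.sf(fstat, 1, n - 2)
    p[degenerate] = 1.0
    keep = p < p_threshold
    return list(X.columns[keep])


def _lasso_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda1 at which the (centered) solution is all-zero."""
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(xc.T @ yc))) if X.shape[1] else 0.0


def _solve_at(model: ElasticNet, lam1: float, lam2: float, n: int, Xc, yc) -> np.ndarray:
    if lam1 + 2 * lam2 <= 0:
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        return coef
    model.alpha = (lam1 + 2 * lam2) / n
    model.l1_ratio = lam1 / (lam1 + 2 * lam2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xc, yc)
    return model.coef_.copy()


def _heldout_loglik(coef, Xtr, ytr, Xte, yte, xm, ym) -> float:
    resid_tr = (ytr - ym) - (Xtr - xm) @ coef
    sigma2 = max(float(resid_tr @ resid_tr) / len(ytr), 1e-8)
    resid_te = (yte - ym) - (Xte - xm) @ coef
    return float(
        -0.5 * len(yte) * np.log(2 * np.pi * sigma2) - (resid_te @ resid_te) / (2 * sigma2)
    )


def fit_elastic_net(
    y: np.ndarray,
    X: pd.DataFrame,
    l2_grid=L2_GRID,
    n_folds: int = 10,
    seed: int = 0,
    n_l1: int = 40,
    l1_min_ratio: float = 1e-3,
    lambda1: float | None = None,
    lambda2: float | None = None,
    signature_name: str = "",
    cancer_type: str = "",
) -> PenalizedModelResult:
    """Cross-validated L1/L2 penalised fit of standardized y on standardized X.

    Passing ``lambda1``/``lambda2`` skips the search and fits at those exact
    penalties (``lambda1 = lambda2 = 0`` is the ordinary least-squares fit).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    features = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if Xv.shape[0] != n:
        raise ValidationError("y and X are not row-aligned")

    if not features:
        log.warning("fit_elastic_net: no covariates survived filtering; intercept-only model")
        return PenalizedModelResult(
            signature_name, cancer_type, {}, float(y.mean()), 0.0, 0.0, np.nan, n, seed
        )

    def _final(lam1, lam2, cv_ll):
        model = ElasticNet(fit_intercept=False, max_iter=5000, warm_start=True, tol=1e-4)
        xm, ym = Xv.mean(axis=0), y.mean()
        Xc, yc = Xv - xm, y - ym
        if lam1 + 2 * lam2 > 0:
            # warm-start down the path to the chosen lambda1 for stability
            lmax = max(_lasso_max(Xv, y), lam1)
            for l1 in np.geomspace(lmax, max(lam1, 1e-12), 8):
                coef = _solve_at(model, l1, lam2, n, Xc, yc)
        else:
            coef = _solve_at(model, 0.0, 0.0, n, Xc, yc)
        intercept = float(ym - xm @ coef)
        return PenalizedModelResult(
            signature_name,
            cancer_type,
            dict(zip(features, map(float, coef))),
            intercept,
            float(lam1),
            float(lam2),
            cv_ll,
            n,
            seed,
        )

    if lambda1 is not None and lambda2 is not None:
        return _final(lambda1, lambda2, np.nan)

    if n < n_folds:
        raise ValidationError(f"need at least n_folds={n_folds} samples, got {n}")

    lam1_max = _lasso_max(Xv, y)
    if lam1_max == 0:  # y orthogonal to every covariate
        lam1_max = 1.0
    path = np.geomspace(lam1_max, lam1_max * l1_min_ratio, n_l1)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds

    cv_ll = np.zeros((len(l2_grid), n_l1))
    for f in range(n_folds):
        te = fold_of == f
        tr = ~te
        Xtr, ytr, Xte, yte = Xv[tr], y[tr], Xv[te], y[te]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - xm, ytr - ym
        gram = Xc.T @ Xc
        for i2, lam2 in enumerate(l2_grid):
            model = ElasticNet(
                fit_intercept=False,
                max_iter=5000,
                warm_start=True,
                precompute=gram,
                tol=1e-4,
            )
            for i1, lam1 in enumerate(path):
                coef = _solve_at(model, lam1, lam2, len(ytr), Xc, yc)
                cv_ll[i2, i1] += _heldout_loglik(coef, Xtr, ytr, Xte, yte, xm, ym)

    i2, i1 = np.unravel_index(np.argmax(cv_ll), cv_ll.shape)
    return _final(path[i1], l2_grid[i2], float(cv_ll[i2, i1]))


def _mirna_log_matrix(cohort: OmicsCohort, min_fraction: float) -> pd.DataFrame:
    """Detection-filtered log2p1 miRNA matrix (features x samples)."""
    m = cohort.mirna
    m = detection_filter(m, min_fraction)
    if m.scale == "raw":
        m = log2_plus1(m)
    return m.data


def associate_signature(
    cohorts: list[OmicsCohort],
    signatures,
    detection: float = 0.8,
    p_threshold: float = 0.2,
    l2_grid=L2_GRID,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Fit the penalised model per (signature, cancer type).

    Returns one coefficient matrix (miRNA x cancer type) per signature:
    NaN where the miRNA failed the detection or univariate filter in that
    type, the (possibly exactly zero) penalised coefficient otherwise. Rows
    that are NaN everywhere are dropped.
    """
    if not cohorts:
        raise ValidationError("associate_signature needs at least one cohort")
    sig_list = list(signatures)
    all_mirnas: list[str] = []
    per_type: dict[str, dict[str, PenalizedModelResult]] = {s.name: {} for s in sig_list}
    for cohort in cohorts:
        if cohort.mirna is None:
            log.warning("cohort %s lacks a miRNA layer; skipped", cohort.cancer_type)
            continue
        aligned = cohort.aligned(require=["mrna", "mirna"])
        mrna = aligned.mrna
        if mrna.scale == "raw":
            mrna = log2_plus1(mrna)
        mrna = detection_filter(mrna, detection)
        mirna_log = _mirna_log_matrix(aligned, detection)
        for mi in mirna_log.index:
            if mi not in all_mirnas:
                all_mirnas.append(mi)
        Xfull, _ = standardize_matrix(mirna_log, axis=1)
        X = Xfull.T  # samples x miRNAs
        for sig in sig_list:
            score = score_signature(mrna, sig)
            yv = standardize(score.scores)
            retained = univariate_filter(yv, X, p_threshold)
            res = fit_elastic_net(
                yv,
                X.loc[:, retained],
                l2_grid=l2_grid,
                n_folds=n_folds,
                seed=child_seed(seed, "penassoc", sig.name, cohort.cancer_type),
                signature_name=sig.name,
                cancer_type=cohort.cancer_type,
            )
            per_type[sig.name][cohort.cancer_type] = res

    out: dict[str, pd.DataFrame] = {}
    types = [c.cancer_type for c in cohorts]
    for sig in sig_list:
        mat = pd.DataFrame(np.nan, index=all_mirnas, columns=types)
        for t, res in per_type[sig.name].items():
            for mi, b in res.coefficients.items():
                mat.loc[mi, t] = b
        out[sig.name] = mat.dropna(how="all")
    return out
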