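"""Exclusivity of miRNA- vs methylation-mediated repression: the Pi statistics.

For a TSG's negative regulators, split into a miRNA activity set A and a
methylation probe set B, Pi_AA / Pi_BB / Pi_AB are the fractions of
within-A, within-B and cross A-B variable pairs showing significant positive
Spearman co-correlation (two-sided p < alpha by the asymptotic t
approximation AND rho > 0). High within-set but low cross-set Pi indicates
mutually exclusive regulation.

Calibration is by bootstrap: resample |A| random detection-filtered miRNAs
and |B| random probes from the same cohort, recompute the Pi triple, and
place the observed pairwise differences D1 = Pi_AA - Pi_AB,
D2 = Pi_BB - Pi_AB, D3 = Pi_AA - Pi_BB on the ecdf of their null
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsCohort, ValidationError
from .preprocess import detection_filter, log2_plus1

log = logging.getLogger(__name__)

DIFF_LABELS = ("D1_AA_minus_AB", "D2_BB_minus_AB", "D3_AA_minus_BB")


@dataclass
class RegulatorPartition:
    """Sample-aligned regulator activity columns for one gene and cohort."""

    gene: str
    cancer_type: str
    set_A: pd.DataFrame  # samples x miRNA activities
    set_B: pd.DataFrame  # samples x methylation probes

    def __post_init__(self) -> None:
        if self.set_A.shape[1] + self.set_B.shape[1] < 2:
            raise ValidationError("partition needs at least two regulator columns")
        if len(self.set_A) and len(self.set_B) and not self.set_A.index.equals(self.set_B.index):
            raise ValidationError("set_A and set_B are not sample-aligned")


@dataclass
class ExclusivityResult:
    gene: str
    cancer_type: str
    pi_AA: float
    pi_BB: float
    pi_AB: float
    differences: list  # (label, observed, ecdf_percentile)
    B: int
    seed: int
    null_values: dict = field(default_factory=dict)  # label -> np.ndarray

    @property
    def exclusive_call(self) -> bool:
        """Advisory label: max(D1, D2) percentile >= 0.95."""
        pcts = {lab: pct for lab, _, pct in self.differences}
        return max(pcts[DIFF_LABELS[0]], pcts[DIFF_LABELS[1]]) >= 0.95


def _sig_pos_flags(columns: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean matrix: column pairs with significant positive Spearman rho.

    ``columns`` is samples x variables. Constant columns yield undefined
    correlations and count as not significant.
    """
    n, k = columns.shape
    if n < 5:
        raise ValidationError("Pi statistics need n >= 5 samples")
    ranks = np.apply_along_axis(stats.rankdata, 0, columns)
    sd = ranks.std(axis=0, ddof=1)
    ok = sd > 0
    z = np.zeros_like(ranks)
    z[:, ok] = (ranks[:, ok] - ranks[:, ok].mean(axis=0)) / sd[ok]
    rho = (z.T @ z) / (n - 1)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[~np.isfinite(t)] = 0.0  # |rho| == 1 on distinct columns
    flags = (p < alpha) & (rho > 0)
    flags[~ok, :] = False
    flags[:, ~ok] = False
    np.fill_diagonal(flags, False)
    return flags


def _pi_from_flags(flags: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    def within(idx):
        if len(idx) < 2:
            return np.nan
        sub = flags[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())

    pi_aa = within(idx_a)
    pi_bb = within(idx_b)
    if len(idx_a) and len(idx_b):
        pi_ab = float(flags[np.ix_(idx_a, idx_b)].mean())
    else:
        pi_ab = np.nan
    return pi_aa, pi_bb, pi_ab


def compute_pi(partition: RegulatorPartition, alpha: float = 0.05):
    """The (Pi_AA, Pi_BB, Pi_AB) triple; within-set Pi is NaN for set size < 2."""
    a, b = partition.set_A, partition.set_B
    combined = pd.concat([a, b], axis=1).to_numpy(dtype=float)
    flags = _sig_pos_flags(combined, alpha)
    idx_a = np.arange(a.shape[1])
    idx_b = np.arange(a.shape[1], a.shape[1] + b.shape[1])
    return _pi_from_flags(flags, idx_a, idx_b)


def bootstrap_exclusivity(
    cohort: OmicsCohort,
    gene: str,
    observed_partition: RegulatorPartition,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    detection: float = 0.8,
) -> ExclusivityResult:
    """Observed Pi differences placed on a resampled-regulator null.

    The resampling pool is every detection-filtered miRNA and every
    methylation probe of the cohort (observed regulators included, the
    conservative choice); draws are without replacement within each class.
    """
    n_a = observed_partition.set_A.shape[1]
    n_b = observed_partition.set_B.shape[1]
    aligned = cohort.aligned(require=["mirna", "methylation", "mrna"])
    mirna = detection_filter(aligned.mirna, detection)
    if mirna.scale == "raw":
        mirna = log2_plus1(mirna)
    meth = aligned.methylation
    if mirna.n_features < n_a or meth.n_features < n_b:
        raise ValidationError("cohort pools smaller than the observed partition")

    pool = np.vstack([mirna.values, meth.values]).T  # samples x (M + P)
    flags = _sig_pos_flags(pool, alpha)
    n_m = mirna.n_features

    obs = compute_pi(observed_partition, alpha)
    obs_d = {
        DIFF_LABELS[0]: obs[0] - obs[2],
        DIFF_LABELS[1]: obs[1] - obs[2],
        DIFF_LABELS[2]: obs[0] - obs[1],
    }

    rng = np.random.default_rng(seed)
    null = {lab: np.empty(B) for lab in DIFF_LABELS}
    n_redraw = 0
    for b in range(B):
        while True:
            ia = rng.choice(n_m, size=n_a, replace=False)
            ib = n_m + rng.choice(meth.n_features, size=n_b, replace=False)
            pa, pb, pab = _pi_from_flags(flags, ia, ib)
            if not (np.isnan(pa) or np.isnan(pb) or np.isnan(pab)):
                break
            n_redraw += 1
        null[DIFF_LABELS[0]][b] = pa - pab
        null[DIFF_LABELS[1]][b] = pb - pab
        null[DIFF_LABELS[2]][b] = pa - pb
    if n_redraw > 0.1 * B:
        import warnings

        warnings.warn(f"{n_redraw} degenerate resamples redrawn", stacklevel=2)

    diffs = []
    for lab in DIFF_LABELS:
        if np.isnan(obs_d[lab]):
            diffs.append((lab, np.nan, np.nan))
        else:
            diffs.append((lab, float(obs_d[lab]), float(np.mean(null[lab] <= obs_d[lab]))))
    return ExclusivityResult(
        gene=gene,
        cancer_type=cohort.cancer_type,
        pi_AA=obs[0],
        pi_BB=obs[1],
        pi_AB=obs[2],
        differences=diffs,
        B=B,
        seed=seed,
        null_values=null,
    )


def partition_from_truth(cohort: OmicsCohort, gene: str, truth_row) -> RegulatorPartition:
    """Build the observed partition of a simulated TSG from its truth record."""
    mirnas = [m for m in str(truth_row["cognate_mirnas"]).split(",") if m]
    probes = [p for p in str(truth_row["cognate_probes"]).split(",") if p]
    aligned = cohort.aligned(require=["mirna", "methylation", "mrna"])
    mirna = aligned.mirna
    if mirna.scale == "raw":
        mirna = log2_plus1(mirna)
    a = mirna.data.loc[mirnas].T
    b = aligned.methylation.data.loc[probes].T
    return RegulatorPartition(gene, cohort.cancer_type, a, b)
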