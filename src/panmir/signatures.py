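"""Per-sample gene-signature summary scores.

A sample's score for a signature is the median, over the signature genes
present in the (detection-filtered) log2(x+1) expression matrix, of that
sample's expression. Genes absent from the matrix are dropped with a logged
count; the even-count median is the midpoint of the two central values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, GeneSignature, ValidationError

log = logging.getLogger(__name__)


@dataclass
class SignatureScoreVector:
    signature_name: str
    sample_ids: list[str]
    scores: np.ndarray
    n_genes_used: int
    standardized: bool = False

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.sample_ids):
            raise ValidationError("scores/sample_ids length mismatch")
        if self.n_genes_used < 1:
            raise ValidationError("signature score used zero genes")


def score_signature(expr: ExpressionMatrix, sig: GeneSignature) -> SignatureScoreVector:
    """Median log2(x+1) expression of the signature genes, per sample."""
    if expr.scale != "log2p1":
        raise ValidationError(
            f"score_signature expects log2p1 expression, got {expr.scale!r}"
        )
    present = [g for g in expr.feature_ids if g in sig.genes]
    if not present:
        raise ValidationError(f"signature {sig.name!r}: no genes present in matrix")
    n_missing = len(sig.genes) - len(present)
    if n_missing:
        log.info("signature %s: %d/%d genes absent", sig.name, n_missing, len(sig.genes))
    if len(present) < 0.5 * len(sig.genes):
        log.warning(
            "signature %s: only %d/%d genes present", sig.name, len(present), len(sig.genes)
        )
    sub = expr.data.loc[present]
    scores = np.median(sub.to_numpy(), axis=0)
    return SignatureScoreVector(
        signature_name=sig.name,
        sample_ids=expr.sample_ids,
        scores=scores,
        n_genes_used=len(present),
    )
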