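"""Core containers for multi-omic cohort analysis.

Every omics layer is held as a features x samples table with an explicit
scale tag so that downstream stages can assert they receive data on the
scale they expect (raw counts, log2(x+1), standardized, or an already-linear
quantity such as copy-number dosage or methylation beta values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Valid values for :attr:`ExpressionMatrix.scale`.
SCALE_TAGS = ("raw", "log2p1", "standardized", "linear")

#: MAF variant classifications treated as non-silent, non-intronic by default.
DEFAULT_NONSILENT = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

#: Classifications the simulator and parsers recognise (silent / intronic ones
#: included so that masking logic is exercised).
VARIANT_VOCABULARY = frozenset(DEFAULT_NONSILENT | {"Silent", "Intron", "3'UTR", "5'UTR"})


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class DegenerateCovariateError(ValueError):
    """Raised when a zero-variance vector is standardized."""


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a declared scale.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    scale:
        One of :data:`SCALE_TAGS`. ``raw`` additionally requires all values
        to be non-negative.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale == "raw" and values.size and values.min() < 0:
            raise ValidationError("raw-scale matrix contains negative values")

    # Convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)], self.scale)

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(features)], self.scale)


@dataclass
class MutationTable:
    """Per-sample variant calls: unique (gene, sample, classification) records."""

    records: pd.DataFrame  # columns: gene, sample, classification

    COLUMNS = ("gene", "sample", "classification")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation table missing columns {missing}")
        self.records = self.records.loc[:, list(self.COLUMNS)].drop_duplicates()
        self.records = self.records.reset_index(drop=True)

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.records[self.records["gene"] == gene]

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class GeneSignature:
    """A named gene set proxying a cancer hallmark phenotype."""

    name: str
    genes: frozenset
    hallmark: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("signature needs a non-empty name")
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has an empty gene set")


@dataclass
class OmicsCohort:
    """One cancer type's aligned multi-omic tables.

    The analysis sample set is the intersection of the sample ids of the
    layers that are present; :meth:`aligned` restricts every layer to that
    set in a common order. Layers not needed by a stage may be ``None``.
    """

    cancer_type: str
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mutations: MutationTable | None = None
    cnv: ExpressionMatrix | None = None
    methylation: ExpressionMatrix | None = None
    probe_to_gene: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.methylation is not None:
            vals = self.methylation.values
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValidationError(
                    f"{self.cancer_type}: methylation beta values outside [0, 1]"
                )

    def _layers(self, require: Iterable[str] | None = None) -> dict[str, ExpressionMatrix]:
        layers = {"mrna": self.mrna, "mirna": self.mirna}
        if self.cnv is not None:
            layers["cnv"] = self.cnv
        if self.methylation is not None:
            layers["methylation"] = self.methylation
        if require is not None:
            for name in require:
                if getattr(self, name, None) is None:
                    raise ValidationError(
                        f"{self.cancer_type}: required layer {name!r} is absent"
                    )
        return layers

    def analysis_samples(self, require: Iterable[str] | None = None) -> list[str]:
        """Sample ids present in every available (or required) layer.

        Order follows the mRNA layer for determinism.
        """
        layers = self._layers(require)
        common = set(self.mrna.sample_ids)
        for m in layers.values():
            common &= set(m.sample_ids)
        return [s for s in self.mrna.sample_ids if s in common]

    @property
    def n_samples(self) -> int:
        return len(self.analysis_samples())

    def aligned(self, require: Iterable[str] | None = None) -> "OmicsCohort":
        """Return a copy with every present layer restricted to the shared samples."""
        samples = self.analysis_samples(require)
        if not samples:
            raise ValidationError(f"{self.cancer_type}: no shared samples across layers")

        def _sub(m: ExpressionMatrix | None) -> ExpressionMatrix | None:
            return None if m is None else m.subset_samples(samples)

        return OmicsCohort(
            cancer_type=self.cancer_type,
            mrna=_sub(self.mrna),
            mirna=_sub(self.mirna),
            mutations=self.mutations,
            cnv=_sub(self.cnv),
            methylation=_sub(self.methylation),
            probe_to_gene=dict(self.probe_to_gene),
        )


@dataclass
class TargetMap:
    """Predicted miRNA -> target-gene map with per-pair source support counts."""

    pairs: pd.DataFrame  # columns: mirna, gene, source_count

    def __post_init__(self) -> None:
        required = {"mirna", "gene", "source_count"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValidationError(f"target map missing columns {sorted(missing)}")
        if (self.pairs["source_count"] < 1).any():
            raise ValidationError("target map source_count must be >= 1")
        if (self.pairs["mirna"] == self.pairs["gene"]).any():
            raise ValidationError("target map contains self-maps")
        self.pairs = self.pairs.drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)

    def targets_of(self, mirna: str) -> set:
        return set(self.pairs.loc[self.pairs["mirna"] == mirna, "gene"])

    def restrict_mirnas(self, mirnas: Iterable[str]) -> "TargetMap":
        keep = self.pairs["mirna"].isin(set(mirnas))
        return TargetMap(self.pairs[keep].copy())

    def min_sources(self, k: int = 2) -> "TargetMap":
        return TargetMap(self.pairs[self.pairs["source_count"] >= k].copy())

    @property
    def all_genes(self) -> set:
        return set(self.pairs["gene"])

    @property
    def all_mirnas(self) -> set:
        return set(self.pairs["mirna"])
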