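"""Readers and writers for the plain-text exchange formats of the pipeline.

Expression-like layers travel as TSV with feature ids in the first column and
a header row of sample ids; mutations as MAF-like TSV; gene sets as GMT; gene
lists as one symbol per line. Missing cells in numeric tables are an error —
NA handling is explicit and happens downstream, never silently at parse time.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSignature,
    MutationTable,
    TargetMap,
    ValidationError,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when a text input cannot be interpreted."""


def read_expression_tsv(path: str | Path, scale_tag: str = "raw") -> ExpressionMatrix:
    """Read a features x samples TSV into an :class:`ExpressionMatrix`.

    The first column holds feature ids; the header row holds sample ids.
    Malformed numeric cells and missing values are parse errors that name the
    offending row and column; duplicate ids are validation errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: malformed numeric cell at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing cell at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), scale_tag)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_maf(path: str | Path) -> MutationTable:
    """Read a MAF-like TSV (Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification).

    Extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    colmap = {
        "Hugo_Symbol": "gene",
        "Tumor_Sample_Barcode": "sample",
        "Variant_Classification": "classification",
    }
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF missing required columns {missing}")
    return MutationTable(df.rename(columns=colmap)[["gene", "sample", "classification"]])


def write_maf(t: MutationTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = t.records.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample": "Tumor_Sample_Barcode",
            "classification": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    The description field is used as the hallmark label.
    """
    sigs: list[GeneSignature] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, hallmark, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in seen:
            raise ValidationError(f"{path}: duplicate signature name {name!r}")
        seen.add(name)
        sigs.append(GeneSignature(name=name, genes=frozenset(genes), hallmark=hallmark))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.hallmark, *sorted(sig.genes)]) + "\n")


def read_gene_list(path: str | Path) -> set:
    """One gene symbol per line; blank lines ignored."""
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """TSV probe_id <tab> gene (many probes to one gene allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: probe map needs two columns (probe, gene)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        raise ValidationError(f"{path}: duplicate probe ids in probe map")
    return dict(zip(probes, genes))


def write_probe_map(mapping: dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"probe_id": list(mapping.keys()), "gene": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path, min_sources: int = 2) -> TargetMap:
    """TSV mirna <tab> gene <tab> source_count.

    Rows supported by fewer than ``min_sources`` prediction databases are
    dropped at load (pass ``min_sources=1`` to keep everything).
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    tm = TargetMap(df)
    n0 = len(tm.pairs)
    tm = tm.min_sources(min_sources)
    dropped = n0 - len(tm.pairs)
    if dropped:
        log.info("target map: dropped %d pairs with < %d sources", dropped, min_sources)
    return tm


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tm.pairs.to_csv(path, sep="\t", index=False)
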