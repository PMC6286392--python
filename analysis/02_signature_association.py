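#!/usr/bin/env python
"""Associate miRNAs with hallmark signature scores per cancer type.

For every (signature, cancer type): score samples by the median log2(x+1)
expression of the signature genes, standardize scores and detection-filtered
miRNA expression, keep miRNAs passing the univariate F-test at p < 0.2, and
fit the cross-validated L1/L2 penalised model. Writes one miRNA x cancer-type
coefficient matrix per signature under results/coefficients/.
"""

from pathlib import Path

from panmir.pipeline import load_study
from panmir.regression import associate_signature

BASE = Path(__file__).resolve().parent.parent
STUDY = BASE / "scratch" / "study"
ROOT = BASE / "results"


def main(seed: int = 1) -> None:
    study = load_study(STUDY)
    coef = associate_signature(study.cohorts, study.signatures, seed=seed)
    outdir = ROOT / "coefficients"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in sorted(coef):
        mat = coef[name]
        mat.to_csv(outdir / f"{name}.tsv", sep="\t", index_label="mirna",
                   float_format="%.10g")
        n_assessed = int(mat.notna().sum().sum())
        print(f"{name}: {mat.shape[0]} miRNAs x {mat.shape[1]} types, "
              f"{n_assessed} assessed cells -> {outdir / (name + '.tsv')}")


if __name__ == "__main__":
    main()
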