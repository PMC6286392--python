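#!/usr/bin/env python
"""Model TSG expression from copy number, mutation type, methylation and
miRNA, and aggregate predictors across cancer types.

For each regulation-mode TSG: per cohort, the standardized log2 expression
is regressed on the gene's CNV dosage, per-classification mutation
indicators, its methylation probes, and the whole detection-filtered miRNA
layer, with the same cross-validated L1/L2 penalty as the signature models.
Coefficients are aggregated across types with the rank product; the tables
of consistently positive / negative predictors go to results/tsg/.
"""

from pathlib import Path

from panmir.pipeline import load_study
from panmir.rankprod import significant_items
from panmir.simulate import read_truth
from panmir.tsg import run_tsg_analysis

BASE = Path(__file__).resolve().parent.parent
STUDY = BASE / "scratch" / "study"
ROOT = BASE / "results"


def main(seed: int = 1) -> None:
    study = load_study(STUDY)
    truth = read_truth(STUDY / "truth")
    outdir = ROOT / "tsg"
    outdir.mkdir(parents=True, exist_ok=True)
    for _, row in truth.tsg_modes.iterrows():
        gene = row["gene"]
        fits, rp = run_tsg_analysis(gene, study.cohorts, seed=seed)
        rp.table.to_csv(outdir / f"{gene}_predictors.tsv", sep="\t",
                        index_label="predictor", float_format="%.10g")
        pos, neg = significant_items(rp, 0.05)
        print(f"{gene} ({row['mode']}): consistently positive {pos[:4]}; "
              f"negative {neg[:6]}")


if __name__ == "__main__":
    main()
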