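#!/usr/bin/env python
"""Generate the synthetic multi-omic study under the standard conditions.

Six cancer-type cohorts of 150 samples each: 800 genes, 300 mature miRNAs
and 300 methylation probes per cohort, two 50-gene hallmark signatures with
10 driver miRNAs apiece (standardized effect 0.4, half positive / half
negative), 40 repressive miRNA->TSG pairs (slope -0.5) hidden among 2000
candidate target pairs, a 140-gene synthetic TSG list, and four TSGs under
exclusive or cooccurring miRNA/methylation regulation.

Writes per-cohort TSV/MAF tables plus the planted-truth record under
scratch/study/ (large, regenerable; summary tables go to results/).
"""

from pathlib import Path

from panmir.pipeline import write_study
from panmir.simulate import default_config, simulate_study

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "study"  # large regenerable inputs live outside results/


def main(seed: int = 1) -> None:
    study = simulate_study(default_config(seed=seed))
    write_study(study, OUT)
    n = sum(c.n_samples for c in study.cohorts)
    print(f"wrote {len(study.cohorts)} cohorts ({n} samples) to {OUT}")
    print(f"planted: {len(study.truth.drivers.drop_duplicates(subset=['mirna']))} "
          f"driver miRNAs, {len(study.truth.pairs)} repressive pairs, "
          f"{len(study.truth.tsg_modes)} regulation-mode TSGs")


if __name__ == "__main__":
    main()
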