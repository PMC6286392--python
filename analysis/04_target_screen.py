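#!/usr/bin/env python
"""Screen candidate miRNA-target pairs for recurrent repression and test TSG
enrichment.

Every candidate pair is scored per cancer type by the Spearman correlation
of miRNA vs target expression partial to the target's non-silent mutation
status; cells with p >= 0.05 are NA. Pairs recorded in >= 5 types are
aggregated with the most-negative-first rank product against the full
candidate field. The repressed targets of the signature-associated miRNAs
are then tested for TSG enrichment (two-sided Fisher) and the repressed-TSG
count is placed on a 1000-resample bootstrap null of random miRNA lists.
"""

from pathlib import Path

import pandas as pd

from panmir.pipeline import load_study
from panmir.targets import (
    TsgScreenContext,
    bootstrap_tsg_null,
    build_pair_matrix,
    eligible_mirna_pool,
    fisher_enrichment,
    recurrent_negative_pairs,
)

BASE = Path(__file__).resolve().parent.parent
STUDY = BASE / "scratch" / "study"
ROOT = BASE / "results"


def main(seed: int = 1) -> None:
    study = load_study(STUDY)
    edges = pd.read_csv(ROOT / "edges.tsv", sep="\t")
    assoc = sorted(set(edges["mirna"]))
    pm = build_pair_matrix(study.target_map, study.cohorts)
    pm.rho.to_csv(ROOT / "pair_correlations.tsv", sep="\t", float_format="%.10g")

    hits = recurrent_negative_pairs(pm, min_types=5, n_perm=2000, seed=seed,
                                    mirnas=assoc)
    pd.DataFrame(hits, columns=["mirna", "gene"]).to_csv(
        ROOT / "repressed_pairs.tsv", sep="\t", index=False
    )
    genes = {g for _, g in hits}
    universe = {g for _, g in pm.pair_ids}
    enr = fisher_enrichment(genes, study.tsg_genes, universe)
    n_tsg = len(genes & study.tsg_genes)
    print(f"{len(hits)} recurrently repressed pairs for {len(assoc)} "
          f"signature-associated miRNAs; {n_tsg} TSGs among {len(genes)} targets")
    print(f"Fisher enrichment: OR={enr.odds_ratio:.2f}, p={enr.p:.3g} "
          f"(universe {enr.universe_size})")

    pool = eligible_mirna_pool(study.cohorts) & study.target_map.all_mirnas
    ctx = TsgScreenContext(pm, study.tsg_genes, min_types=5, fdr=0.05, n_perm=2000)
    boot = bootstrap_tsg_null(pool, len(assoc), ctx, B=1000, seed=seed,
                              observed=n_tsg)
    print(f"bootstrap null (B=1000): ecdf percentile {boot.ecdf_percentile:.3f}, "
          f"p_upper {boot.p_upper:.3f}")
    pd.DataFrame([{
        "n_pairs": len(hits), "n_target_genes": len(genes), "n_tsg": n_tsg,
        "fisher_odds_ratio": enr.odds_ratio, "fisher_p": enr.p,
        "bootstrap_percentile": boot.ecdf_percentile,
        "bootstrap_p_upper": boot.p_upper,
    }]).to_csv(ROOT / "enrichment.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
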