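"""End-to-end orchestration: simulate -> score -> associate -> aggregate ->
target screen -> enrichment -> TSG models -> exclusivity.

Every stochastic stage receives a child seed derived deterministically from
the master seed and the stage name, so a run is a pure function of
(inputs, config, master_seed) and reruns are byte-identical. A JSON manifest
records the configuration, seeds, input digests and output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from ._seeds import child_seed
from .datatypes import OmicsCohort, ValidationError
from .exclusivity import bootstrap_exclusivity, partition_from_truth
from .preprocess import exclude_small_cohorts
from .rankprod import rank_product, significant_items
from .regression import L2_GRID, associate_signature
from .simulate import (
    SimulatedStudy,
    config_from_json,
    config_to_json,
    default_config,
    read_truth,
    simulate_study,
    truth_report,
)
from .targets import (
    TsgScreenContext,
    bootstrap_tsg_null,
    build_pair_matrix,
    eligible_mirna_pool,
    fisher_enrichment,
    recurrent_negative_pairs,
)
from .tsg import run_tsg_analysis

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and sizes of a pipeline run, JSON-serialisable."""

    detection: float = 0.8
    univariate_p: float = 0.2
    alpha: float = 0.05
    min_types: int = 5
    min_cohort_n: int = 9
    l2_grid: tuple = L2_GRID
    n_folds: int = 10
    fdr: float = 0.05
    rp_n_perm: int = 10_000
    screen_n_perm: int = 2000
    bootstrap_B: int = 1000
    exclusivity_B: int = 1000
    master_seed: int = 0
    outdir: str = "panmir_run"
    simulate: dict | None = None  # SimConfig as JSON; None => load from input_dir
    input_dir: str | None = None
    run_bootstrap: bool = True
    run_tsg: bool = True
    run_exclusivity: bool = True

    def validate(self) -> None:
        if not 0 < self.detection <= 1 or not 0 < self.alpha < 1:
            raise ValidationError("thresholds out of range")
        if not self.l2_grid:
            raise ValidationError("empty l2 grid")
        if self.simulate is None and self.input_dir is None:
            raise ValidationError("config needs either a simulate section or input_dir")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["l2_grid"] = tuple(d.get("l2_grid", L2_GRID))
        return cls(**d)


# ---------------------------------------------------------------------------
# study persistence (the layout `panmir simulate` writes and stages consume)
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for cohort in study.cohorts:
        d = outdir / cohort.cancer_type
        pio.write_expression_tsv(cohort.mrna, d / "mrna.tsv")
        pio.write_expression_tsv(cohort.mirna, d / "mirna.tsv")
        pio.write_maf(cohort.mutations, d / "mutations.maf")
        pio.write_expression_tsv(cohort.cnv, d / "cnv.tsv")
        pio.write_expression_tsv(cohort.methylation, d / "methylation.tsv")
        pio.write_probe_map(cohort.probe_to_gene, d / "probe_map.tsv")
    pio.write_gmt(study.signatures, outdir / "signatures.gmt")
    pio.write_target_map(study.target_map, outdir / "targets.tsv")
    pio.write_gene_list(study.tsg_genes, outdir / "tsg.txt")
    truth_report(study.truth, outdir / "truth")
    (outdir / "sim_config.json").write_text(
        json.dumps(config_to_json(study.config), indent=1, sort_keys=True)
    )


def load_cohort(d: str | Path, cancer_type: str | None = None) -> OmicsCohort:
    d = Path(d)
    if not d.exists():
        raise FileNotFoundError(f"cohort directory not found: {d}")

    def _opt(name, scale):
        p = d / name
        return pio.read_expression_tsv(p, scale) if p.exists() else None

    probe_path = d / "probe_map.tsv"
    return OmicsCohort(
        cancer_type=cancer_type or d.name,
        mrna=pio.read_expression_tsv(d / "mrna.tsv", "raw"),
        mirna=pio.read_expression_tsv(d / "mirna.tsv", "raw"),
        mutations=pio.read_maf(d / "mutations.maf") if (d / "mutations.maf").exists() else None,
        cnv=_opt("cnv.tsv", "linear"),
        methylation=_opt("methylation.tsv", "linear"),
        probe_to_gene=pio.read_probe_map(probe_path) if probe_path.exists() else {},
    )


def load_study(indir: str | Path) -> SimulatedStudy:
    indir = Path(indir)
    cohort_dirs = sorted(p for p in indir.iterdir() if p.is_dir() and (p / "mrna.tsv").exists())
    if not cohort_dirs:
        raise FileNotFoundError(f"no cohort directories under {indir}")
    cohorts = [load_cohort(p) for p in cohort_dirs]
    signatures = pio.read_gmt(indir / "signatures.gmt")
    target_map = pio.read_target_map(indir / "targets.tsv")
    tsg_genes = pio.read_gene_list(indir / "tsg.txt")
    truth_dir = indir / "truth"
    truth = read_truth(truth_dir) if truth_dir.exists() else None
    cfg_path = indir / "sim_config.json"
    cfg = config_from_json(json.loads(cfg_path.read_text())) if cfg_path.exists() else None
    return SimulatedStudy(cohorts, truth, signatures, target_map, tsg_genes, cfg)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_record = {**asdict(cfg), "l2_grid": list(cfg.l2_grid)}
    cfg_record.pop("outdir")  # the manifest's own location; keep runs comparable
    manifest: dict = {
        "config": cfg_record,
        "seeds": {},
        "inputs": {},
        "outputs": [],
        "counts": {},
    }

    def _write(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        manifest["outputs"].append(name)

    # stage: inputs -------------------------------------------------------
    if cfg.simulate is not None:
        sim_cfg = config_from_json(cfg.simulate)
        sim_cfg.seed = child_seed(cfg.master_seed, "simulate")
        manifest["seeds"]["simulate"] = sim_cfg.seed
        study = simulate_study(sim_cfg)
        manifest["inputs"]["sim_config_digest"] = hashlib.sha256(
            json.dumps(config_to_json(sim_cfg), sort_keys=True).encode()
        ).hexdigest()[:16]
    else:
        indir = Path(cfg.input_dir)
        study = load_study(indir)
        manifest["inputs"] = {
            str(p.relative_to(indir)): _digest(p) for p in sorted(indir.rglob("*.tsv"))
        }

    cohorts = exclude_small_cohorts(study.cohorts, cfg.min_cohort_n)
    manifest["counts"]["cohorts"] = len(cohorts)
    manifest["counts"]["cohorts_excluded"] = len(study.cohorts) - len(cohorts)

    # stage: associate + aggregate ---------------------------------------
    assoc_seed = child_seed(cfg.master_seed, "associate")
    manifest["seeds"]["associate"] = assoc_seed
    coef = associate_signature(
        cohorts,
        study.signatures,
        detection=cfg.detection,
        p_threshold=cfg.univariate_p,
        l2_grid=cfg.l2_grid,
        n_folds=cfg.n_folds,
        seed=assoc_seed,
    )
    assoc_pos: dict[str, list] = {}
    assoc_neg: dict[str, list] = {}
    edges = []
    for name in sorted(coef):
        _write(coef[name], f"coefficients/{name}.tsv", index_label="mirna")
        rp_seed = child_seed(cfg.master_seed, "rankprod", name)
        manifest["seeds"][f"rankprod:{name}"] = rp_seed
        rp = rank_product(coef[name], min_lists=2, n_perm=cfg.rp_n_perm, seed=rp_seed)
        _write(rp.table, f"rankprod/{name}.tsv", index_label="mirna")
        pos, neg = significant_items(rp, cfg.fdr)
        assoc_pos[name], assoc_neg[name] = pos, neg
        edges += [(name, mi, "positive") for mi in pos]
        edges += [(name, mi, "negative") for mi in neg]
    edges_df = pd.DataFrame(edges, columns=["signature", "mirna", "direction"])
    _write(edges_df, "edges.tsv", index=False)
    manifest["counts"]["associated_mirnas"] = int(len(edges_df))

    # stage: target screen ------------------------------------------------
    assoc_mirnas = sorted({mi for _, mi, _ in edges})
    pair_matrix = build_pair_matrix(study.target_map, cohorts, cfg.alpha, cfg.detection)
    _write(pair_matrix.rho, "pair_correlations.tsv")
    screen_seed = child_seed(cfg.master_seed, "screen")
    manifest["seeds"]["screen"] = screen_seed
    hits, rp_pairs = recurrent_negative_pairs(
        pair_matrix, cfg.min_types, cfg.fdr, cfg.screen_n_perm, screen_seed,
        mirnas=assoc_mirnas, return_rp=True,
    )
    hits_df = pd.DataFrame(hits, columns=["mirna", "gene"])
    _write(hits_df, "repressed_pairs.tsv", index=False)
    repressed_genes = sorted({g for _, g in hits})
    universe = {g for _, g in pair_matrix.pair_ids}
    enrich = fisher_enrichment(set(repressed_genes), study.tsg_genes, universe, sided="two")
    n_tsg = len(set(repressed_genes) & study.tsg_genes)
    manifest["counts"]["repressed_pairs"] = len(hits)
    manifest["counts"]["repressed_tsg"] = n_tsg
    enrich_row = {
        "n_repressed_genes": len(repressed_genes),
        "n_repressed_tsg": n_tsg,
        "fisher_odds_ratio": enrich.odds_ratio,
        "fisher_p": enrich.p,
        "universe_size": enrich.universe_size,
    }

    if cfg.run_bootstrap and assoc_mirnas:
        boot_seed = child_seed(cfg.master_seed, "bootstrap")
        manifest["seeds"]["bootstrap"] = boot_seed
        pool = eligible_mirna_pool(cohorts, cfg.detection) & set(
            study.target_map.pairs["mirna"]
        )
        context = TsgScreenContext(
            pair_matrix, study.tsg_genes, cfg.min_types, cfg.fdr, cfg.screen_n_perm
        )
        boot = bootstrap_tsg_null(
            pool,
            min(len(assoc_mirnas), len(pool)),
            context,
            B=cfg.bootstrap_B,
            seed=boot_seed,
            observed=n_tsg,
        )
        enrich_row.update(
            bootstrap_percentile=boot.ecdf_percentile,
            bootstrap_p_upper=boot.p_upper,
            bootstrap_B=boot.B,
        )
    _write(pd.DataFrame([enrich_row]), "enrichment.tsv", index=False)

    # stage: TSG regulation + exclusivity ---------------------------------
    focus_genes: list[str] = []
    if study.truth is not None and len(study.truth.tsg_modes):
        focus_genes = list(study.truth.tsg_modes["gene"])
    if cfg.run_tsg and focus_genes:
        tsg_seed = child_seed(cfg.master_seed, "tsg")
        manifest["seeds"]["tsg"] = tsg_seed
        for gene in focus_genes:
            fits, rp = run_tsg_analysis(
                gene, cohorts, detection=cfg.detection,
                n_perm=cfg.rp_n_perm, seed=tsg_seed,
            )
            _write(rp.table, f"tsg/{gene}_predictors.tsv", index_label="predictor")
    if cfg.run_exclusivity and focus_genes and study.truth is not None:
        excl_seed = child_seed(cfg.master_seed, "exclusivity")
        manifest["seeds"]["exclusivity"] = excl_seed
        rows = []
        modes = study.truth.tsg_modes.set_index("gene")
        for gene in focus_genes:
            for cohort in cohorts:
                part = partition_from_truth(cohort, gene, modes.loc[gene])
                res = bootstrap_exclusivity(
                    cohort, gene, part, B=cfg.exclusivity_B,
                    seed=child_seed(excl_seed, gene, cohort.cancer_type),
                    alpha=cfg.alpha, detection=cfg.detection,
                )
                row = {
                    "gene": gene,
                    "cancer_type": cohort.cancer_type,
                    "mode": modes.loc[gene, "mode"],
                    "pi_AA": res.pi_AA,
                    "pi_BB": res.pi_BB,
                    "pi_AB": res.pi_AB,
                }
                for lab, obs, pct in res.differences:
                    row[f"{lab}_obs"] = obs
                    row[f"{lab}_pct"] = pct
                rows.append(row)
        _write(pd.DataFrame(rows), "exclusivity.tsv", index=False)

    # recovery report vs planted truth ------------------------------------
    if study.truth is not None and len(study.truth.drivers):
        tp = study.truth.drivers.drop_duplicates(subset=["signature", "mirna"])
        rows = []
        for _, r in tp.iterrows():
            called = (
                r["mirna"] in assoc_pos.get(r["signature"], [])
                if r["sign"] > 0
                else r["mirna"] in assoc_neg.get(r["signature"], [])
            )
            rows.append(
                {
                    "signature": r["signature"],
                    "mirna": r["mirna"],
                    "sign": r["sign"],
                    "recovered": bool(called),
                }
            )
        recovery = pd.DataFrame(rows)
        _write(recovery, "recovery.tsv", index=False)
        manifest["counts"]["drivers_recovered"] = int(recovery["recovered"].sum())
        manifest["counts"]["drivers_planted"] = int(len(recovery))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def small_run_config(master_seed: int = 0, outdir: str = "panmir_run") -> RunConfig:
    """A reduced-size configuration for smoke tests and determinism checks."""
    sim = default_config(seed=0)
    sim.n_cancer_types = 6
    sim.n_samples_per_type = 60
    sim.n_genes = 300
    sim.n_mirnas = 80
    sim.n_probes = 60
    sim.n_decoy_pairs = 600
    sim.n_weak_source_pairs = 10
    genes, mirnas = sim.gene_ids, sim.mirna_ids
    from .simulate import SignatureSpec

    sim.signatures = [
        SignatureSpec(
            name="SIG1",
            genes=genes[:30],
            driver_mirnas=mirnas[:6],
            driver_signs=[1, 1, 1, -1, -1, -1],
            driver_effect=0.5,
        )
    ]
    sim.tsg_genes = genes[-60:]
    drivers = sim.signatures[0].driver_mirnas
    sim.repressive_pairs = [
        (drivers[j], sim.tsg_genes[2 * j + k], -0.5, 1.0)
        for j in range(len(drivers))
        for k in range(2)
    ]
    mode_genes = sim.tsg_genes[12:14]
    sim.tsg_modes = {mode_genes[0]: "exclusive", mode_genes[1]: "cooccurring"}
    sim.cognate_mirnas = {
        mode_genes[0]: mirnas[6:10],
        mode_genes[1]: mirnas[10:14],
    }
    sim.n_cognate_probes = 4
    sim.validate()
    return RunConfig(
        master_seed=master_seed,
        outdir=outdir,
        simulate=config_to_json(sim),
        min_types=4,
        rp_n_perm=2000,
        screen_n_perm=1000,
        bootstrap_B=100,
        exclusivity_B=200,
        min_cohort_n=9,
    )
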