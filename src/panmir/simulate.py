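"""Synthetic multi-cancer-type cohorts with planted ground truth.

The generator emulates the structure the analysis is designed to detect:

* each cohort carries one latent hallmark phenotype per signature and sample
  (``h ~ N(0,1)``); signature genes load linearly on it;
* "driver" miRNAs load on the same phenotype with a chosen standardized
  effect and sign, on top of independent noise — these are the items the
  penalised-regression / rank-product stage should recover;
* planted repressive miRNA->target pairs subtract ``|slope|`` times the
  (centred) miRNA log-expression from the target's log-expression;
* every gene receives an integer copy-number dosage effect and a fixed
  expression penalty for non-silent mutations;
* methylation probes carry a per-gene latent level plus probe noise;
* designated tumour-suppressor genes are regulated in an ``exclusive``
  (miRNA XOR methylation arm per sample) or ``cooccurring`` (both together)
  mode by cognate miRNA and probe sets.

Expression layers are emitted on the raw scale (2^x - 1, clipped at zero) so
the pipeline's own log2(x+1) transform is exercised; a fraction of features
is generated at near-zero baseline so the detection filter has work to do.
All randomness flows from a single seeded generator in a fixed draw order,
so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSignature,
    MutationTable,
    OmicsCohort,
    TargetMap,
    ValidationError,
)

_CLASS_PROBS = {
    "Missense_Mutation": 0.50,
    "Silent": 0.15,
    "Nonsense_Mutation": 0.10,
    "Frame_Shift_Del": 0.10,
    "Splice_Site": 0.10,
    "Intron": 0.05,
}
_SILENT = {"Silent", "Intron"}


@dataclass
class SignatureSpec:
    """One planted hallmark signature: its genes and driver miRNAs."""

    name: str
    genes: list[str]
    driver_mirnas: list[str]
    driver_signs: list[int]
    driver_effect: float = 0.4
    gene_loading: float = 1.0


@dataclass
class SimConfig:
    """Full description of a synthetic multi-omic study.

    Identifiers are explicit so the planted truth is readable; use
    :func:`default_config` for the standard study conditions.
    """

    n_cancer_types: int = 6
    n_samples_per_type: int = 150
    n_genes: int = 800
    n_mirnas: int = 300
    n_probes: int = 300
    signatures: list[SignatureSpec] = field(default_factory=list)
    # (mirna, gene, slope < 0, noise_sd)
    repressive_pairs: list[tuple] = field(default_factory=list)
    tsg_modes: dict = field(default_factory=dict)  # gene -> exclusive|cooccurring|none
    cognate_mirnas: dict = field(default_factory=dict)  # gene -> list of miRNAs
    tsg_genes: list[str] = field(default_factory=list)
    n_decoy_pairs: int = 1960
    n_weak_source_pairs: int = 100  # decoys with source_count 1, dropped at load
    n_cognate_probes: int = 5
    mutation_rate: float = 0.02
    mutation_offset: float = 1.0
    cnv_effect: float = 0.6
    mirna_noise_sd: float = 1.0
    gene_noise_sd: float = 1.0
    meth_mirna_slope: float = 1.0  # repression of mode genes by cognate miRNA mean
    meth_beta_slope: float = 4.0  # repression of mode genes per unit mean beta
    arm_mirna_amp: float = 1.5
    arm_beta_amp: float = 0.3
    frac_low_expressed: float = 0.1
    gene_baseline: tuple = (5.0, 9.0)
    mirna_baseline: tuple = (4.0, 8.0)
    seed: int = 0

    # -- derived id lists ---------------------------------------------------
    @property
    def cancer_types(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_cancer_types)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_mirnas)]

    @property
    def probe_ids(self) -> list[str]:
        return [f"cg{i + 1:06d}" for i in range(self.n_probes)]

    def validate(self) -> None:
        for n, label in [
            (self.n_cancer_types, "n_cancer_types"),
            (self.n_samples_per_type, "n_samples_per_type"),
            (self.n_genes, "n_genes"),
            (self.n_mirnas, "n_mirnas"),
            (self.n_probes, "n_probes"),
        ]:
            if n < 1:
                raise ValidationError(f"{label} must be positive")
        genes, mirnas = set(self.gene_ids), set(self.mirna_ids)
        n_drivers = sum(len(s.driver_mirnas) for s in self.signatures)
        if n_drivers > self.n_mirnas:
            raise ValidationError("more driver miRNAs than miRNAs")
        for s in self.signatures:
            if not set(s.genes) <= genes:
                raise ValidationError(f"signature {s.name}: unknown genes")
            if not set(s.driver_mirnas) <= mirnas:
                raise ValidationError(f"signature {s.name}: unknown driver miRNAs")
            if len(s.driver_signs) != len(s.driver_mirnas):
                raise ValidationError(f"signature {s.name}: signs/drivers length mismatch")
        for mi, g, slope, noise_sd in self.repressive_pairs:
            if mi not in mirnas or g not in genes:
                raise ValidationError(f"repressive pair ({mi}, {g}): unknown ids")
            if slope >= 0:
                raise ValidationError(f"repressive pair ({mi}, {g}): slope must be < 0")
        if not set(self.tsg_modes) <= genes:
            raise ValidationError("tsg_modes references unknown genes")
        for g, mode in self.tsg_modes.items():
            if mode not in ("exclusive", "cooccurring", "none"):
                raise ValidationError(f"unknown tsg mode {mode!r} for {g}")


def default_config(seed: int = 0, driver_effect: float = 0.4, **overrides) -> SimConfig:
    """The standard study conditions: 6 cohorts x 150 samples, 300 miRNAs,
    800 genes; 2 hallmark signatures of 50 genes with 10 drivers each
    (|standardized effect| 0.4, half positive, half negative); 40 repressive
    pairs (slope -0.5, noise sd 1) from the 20 drivers onto a 140-gene
    synthetic TSG list, hidden among 2000 candidate target pairs; two
    exclusive-mode and two cooccurring-mode TSGs with 5 cognate miRNAs and
    probes each.
    """
    cfg = SimConfig(seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown SimConfig field {k!r}")
        setattr(cfg, k, v)
    genes, mirnas = cfg.gene_ids, cfg.mirna_ids

    n_sig_genes, n_drivers = 50, 10
    cfg.signatures = []
    for s in range(2):
        signs = [1] * 5 + [-1] * 5
        cfg.signatures.append(
            SignatureSpec(
                name=f"SIG{s + 1}",
                genes=genes[s * n_sig_genes : (s + 1) * n_sig_genes],
                driver_mirnas=mirnas[s * n_drivers : (s + 1) * n_drivers],
                driver_signs=signs,
                driver_effect=driver_effect,
            )
        )
    # 140-gene synthetic TSG list at the top of the gene range.
    cfg.tsg_genes = genes[cfg.n_genes - 140 :]
    # Each driver represses two distinct TSGs.
    drivers = [m for s in cfg.signatures for m in s.driver_mirnas]
    cfg.repressive_pairs = [
        (drivers[j], cfg.tsg_genes[2 * j + k], -0.5, 1.0)
        for j in range(len(drivers))
        for k in range(2)
    ]
    # Mode genes sit in the TSG list past the repressed targets.
    mode_genes = cfg.tsg_genes[40:44]
    cfg.tsg_modes = {
        mode_genes[0]: "exclusive",
        mode_genes[1]: "exclusive",
        mode_genes[2]: "cooccurring",
        mode_genes[3]: "cooccurring",
    }
    base = 2 * n_drivers
    cfg.cognate_mirnas = {
        g: mirnas[base + 5 * i : base + 5 * (i + 1)] for i, g in enumerate(mode_genes)
    }
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Machine-readable record of every planted parameter."""

    drivers: pd.DataFrame  # signature, cancer_type, mirna, sign, effect
    pairs: pd.DataFrame  # mirna, gene, slope, noise_sd
    tsg_modes: pd.DataFrame  # gene, mode, cognate_mirnas, cognate_probes
    phenotypes: pd.DataFrame  # cancer_type, signature, sample, h


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, plus the truth that generated it."""

    cohorts: list[OmicsCohort]
    truth: SyntheticTruth
    signatures: list[GeneSignature]
    target_map: TargetMap
    tsg_genes: set
    config: SimConfig


def _probe_map(cfg: SimConfig) -> dict[str, str]:
    """Deterministic probe->gene assignment; cognate probes for mode genes first."""
    probes = cfg.probe_ids
    mapping: dict[str, str] = {}
    i = 0
    for g in sorted(cfg.tsg_modes):
        for _ in range(cfg.n_cognate_probes):
            if i < len(probes):
                mapping[probes[i]] = g
                i += 1
    genes = cfg.gene_ids
    j = 0
    while i < len(probes):
        mapping[probes[i]] = genes[j % len(genes)]
        i += 1
        j += 1
    return mapping


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate all cohorts, input side-tables and the truth record."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, mirnas, probes = cfg.gene_ids, cfg.mirna_ids, cfg.probe_ids
    gene_idx = {g: i for i, g in enumerate(genes)}
    mirna_idx = {m: i for i, m in enumerate(mirnas)}
    probe_map = _probe_map(cfg)
    probes_of: dict[str, list[str]] = {}
    for p, g in probe_map.items():
        probes_of.setdefault(g, []).append(p)

    # Low-expressed features (exercise the detection filter). Kept clear of
    # signature genes and the TSG list.
    n_low_g = int(cfg.frac_low_expressed * cfg.n_genes)
    n_sig_g = sum(len(s.genes) for s in cfg.signatures)
    lo_start = min(max(n_sig_g, cfg.n_genes - 140 - n_low_g), cfg.n_genes - n_low_g)
    low_genes = set(genes[lo_start : lo_start + n_low_g])
    n_low_m = int(cfg.frac_low_expressed * cfg.n_mirnas)
    low_mirnas = set(mirnas[cfg.n_mirnas - n_low_m :]) if n_low_m else set()

    class_names = list(_CLASS_PROBS)
    class_p = np.array(list(_CLASS_PROBS.values()))

    cohorts: list[OmicsCohort] = []
    drivers_rows, pheno_rows = [], []
    for t in cfg.cancer_types:
        n = cfg.n_samples_per_type
        samples = [f"{t}_S{j + 1:03d}" for j in range(n)]

        # 1. latent hallmark phenotypes
        h = {s.name: rng.standard_normal(n) for s in cfg.signatures}
        # 2. copy number dosage
        cnv = rng.choice([-2, -1, 0, 1, 2], size=(cfg.n_genes, n), p=[0.02, 0.08, 0.8, 0.08, 0.02])
        # 3. mutations
        mut_mask = rng.random((cfg.n_genes, n)) < cfg.mutation_rate
        mut_class = rng.choice(class_names, size=(cfg.n_genes, n), p=class_p)
        nonsilent = mut_mask & ~np.isin(mut_class, list(_SILENT))
        # 4. methylation: per-gene latent level plus probe noise
        gene_meth = {g: rng.standard_normal(n) for g in sorted(probes_of)}
        beta = np.zeros((cfg.n_probes, n))
        for i, p in enumerate(probes):
            g = probe_map[p]
            beta[i] = 0.35 + 0.08 * gene_meth[g] + 0.05 * rng.standard_normal(n)
        # 5. regulation-mode activations
        arm = {g: rng.integers(0, 2, size=n) for g in sorted(cfg.tsg_modes)}

        # 6. miRNA log-expression
        m_base = rng.uniform(*cfg.mirna_baseline, size=cfg.n_mirnas)
        M = m_base[:, None] + cfg.mirna_noise_sd * rng.standard_normal((cfg.n_mirnas, n))
        for s in cfg.signatures:
            for mi, sign in zip(s.driver_mirnas, s.driver_signs):
                M[mirna_idx[mi]] += sign * s.driver_effect * h[s.name]
        for g, mode in sorted(cfg.tsg_modes.items()):
            if mode == "none":
                continue
            act = arm[g] if mode in ("exclusive", "cooccurring") else None
            for mi in cfg.cognate_mirnas.get(g, []):
                M[mirna_idx[mi]] += cfg.arm_mirna_amp * act
        for mi in low_mirnas:
            M[mirna_idx[mi]] = 0.2 + 0.5 * rng.standard_normal(n)

        # methylation arm: exclusive genes methylated when the miRNA arm is off
        for g, mode in sorted(cfg.tsg_modes.items()):
            act = (1 - arm[g]) if mode == "exclusive" else arm[g]
            if mode == "none":
                continue
            for p in probes_of.get(g, []):
                beta[probes.index(p)] += cfg.arm_beta_amp * act
        beta = np.clip(beta, 0.01, 0.99)

        # 7. gene log-expression
        g_base = rng.uniform(*cfg.gene_baseline, size=cfg.n_genes)
        G = g_base[:, None] + cfg.gene_noise_sd * rng.standard_normal((cfg.n_genes, n))
        for s in cfg.signatures:
            for g in s.genes:
                G[gene_idx[g]] += s.gene_loading * h[s.name]
        for mi, g, slope, noise_sd in cfg.repressive_pairs:
            x = M[mirna_idx[mi]]
            G[gene_idx[g]] = (
                g_base[gene_idx[g]]
                - abs(slope) * (x - x.mean())
                + noise_sd * rng.standard_normal(n)
            )
        for g, mode in sorted(cfg.tsg_modes.items()):
            if mode == "none":
                continue
            gi = gene_idx[g]
            cog_m = np.mean([M[mirna_idx[mi]] for mi in cfg.cognate_mirnas.get(g, [])], axis=0)
            cog_b = np.mean([beta[probes.index(p)] for p in probes_of.get(g, [])], axis=0)
            G[gi] = (
                g_base[gi]
                - cfg.meth_mirna_slope * (cog_m - cog_m.mean())
                - cfg.meth_beta_slope * (cog_b - cog_b.mean())
                + 0.5 * rng.standard_normal(n)
            )
        G += cfg.cnv_effect * cnv
        G -= cfg.mutation_offset * nonsilent
        for g in low_genes:
            G[gene_idx[g]] = 0.2 + 0.5 * rng.standard_normal(n)

        # 8. emit on the raw scale
        mrna_raw = np.maximum(np.exp2(G) - 1.0, 0.0)
        mirna_raw = np.maximum(np.exp2(M) - 1.0, 0.0)

        gi_arr, si_arr = np.where(mut_mask)
        maf = pd.DataFrame(
            {
                "gene": [genes[i] for i in gi_arr],
                "sample": [samples[j] for j in si_arr],
                "classification": mut_class[gi_arr, si_arr],
            }
        )
        cohorts.append(
            OmicsCohort(
                cancer_type=t,
                mrna=ExpressionMatrix(pd.DataFrame(mrna_raw, index=genes, columns=samples), "raw"),
                mirna=ExpressionMatrix(pd.DataFrame(mirna_raw, index=mirnas, columns=samples), "raw"),
                mutations=MutationTable(maf),
                cnv=ExpressionMatrix(
                    pd.DataFrame(cnv.astype(float), index=genes, columns=samples), "linear"
                ),
                methylation=ExpressionMatrix(
                    pd.DataFrame(beta, index=probes, columns=samples), "linear"
                ),
                probe_to_gene=dict(probe_map),
            )
        )
        for s in cfg.signatures:
            for mi, sign in zip(s.driver_mirnas, s.driver_signs):
                drivers_rows.append((s.name, t, mi, sign, s.driver_effect))
            for j, smp in enumerate(samples):
                pheno_rows.append((t, s.name, smp, h[s.name][j]))

    # Candidate target map: planted pairs + decoys (+ a few 1-source rows).
    planted = {(mi, g) for mi, g, _, _ in cfg.repressive_pairs}
    rows = [
        {"mirna": mi, "gene": g, "source_count": int(rng.integers(2, 6))}
        for mi, g, _, _ in cfg.repressive_pairs
    ]
    seen = set(planted)
    n_wanted = cfg.n_decoy_pairs + cfg.n_weak_source_pairs
    while len(seen) - len(planted) < n_wanted:
        mi = mirnas[rng.integers(0, cfg.n_mirnas)]
        g = genes[rng.integers(0, cfg.n_genes)]
        if (mi, g) in seen:
            continue
        seen.add((mi, g))
        k = len(seen) - len(planted)
        src = 1 if k > cfg.n_decoy_pairs else int(rng.integers(2, 6))
        rows.append({"mirna": mi, "gene": g, "source_count": src})
    target_map = TargetMap(pd.DataFrame(rows))

    truth = SyntheticTruth(
        drivers=pd.DataFrame(
            drivers_rows, columns=["signature", "cancer_type", "mirna", "sign", "effect"]
        ),
        pairs=pd.DataFrame(
            cfg.repressive_pairs, columns=["mirna", "gene", "slope", "noise_sd"]
        ),
        tsg_modes=pd.DataFrame(
            [
                {
                    "gene": g,
                    "mode": mode,
                    "cognate_mirnas": ",".join(cfg.cognate_mirnas.get(g, [])),
                    "cognate_probes": ",".join(probes_of.get(g, [])),
                }
                for g, mode in sorted(cfg.tsg_modes.items())
            ],
            columns=["gene", "mode", "cognate_mirnas", "cognate_probes"],
        ),
        phenotypes=pd.DataFrame(
            pheno_rows, columns=["cancer_type", "signature", "sample", "h"]
        ),
    )
    gmt = [
        GeneSignature(name=s.name, genes=frozenset(s.genes), hallmark=f"hallmark_{s.name}")
        for s in cfg.signatures
    ]
    return SimulatedStudy(cohorts, truth, gmt, target_map, set(cfg.tsg_genes), cfg)


def generate_cohorts(cfg: SimConfig) -> tuple[list[OmicsCohort], SyntheticTruth]:
    """Cohorts plus truth (see :func:`simulate_study` for the full bundle)."""
    study = simulate_study(cfg)
    return study.cohorts, study.truth


_TRUTH_FILES = {
    "drivers": "truth_drivers.tsv",
    "pairs": "truth_pairs.tsv",
    "tsg_modes": "truth_tsg_modes.tsv",
    "phenotypes": "truth_phenotypes.tsv",
}


def truth_report(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the truth tables as TSV; lossless under :func:`read_truth`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in _TRUTH_FILES.items():
        path = outdir / fname
        getattr(truth, attr).to_csv(path, sep="\t", index=False, float_format="%.12g")
        paths[attr] = path
    return paths


def read_truth(outdir: str | Path) -> SyntheticTruth:
    outdir = Path(outdir)
    frames = {}
    for attr, fname in _TRUTH_FILES.items():
        frames[attr] = pd.read_csv(outdir / fname, sep="\t")
        # pandas reads an empty table's dtypes as object; enforce nothing here
    return SyntheticTruth(**frames)


def config_to_json(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["signatures"] = [asdict(s) for s in cfg.signatures]
    return d


def config_from_json(d: dict) -> SimConfig:
    d = dict(d)
    d["signatures"] = [SignatureSpec(**s) for s in d.get("signatures", [])]
    d["repressive_pairs"] = [tuple(p) for p in d.get("repressive_pairs", [])]
    d["gene_baseline"] = tuple(d.get("gene_baseline", (5.0, 9.0)))
    d["mirna_baseline"] = tuple(d.get("mirna_baseline", (4.0, 8.0)))
    return SimConfig(**d)
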