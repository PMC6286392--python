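import numpy as np
import pandas as pd
import pytest

from panmir.datatypes import ExpressionMatrix
from panmir.simulate import SignatureSpec, SimConfig


def tiny_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A small but structurally complete synthetic study for unit tests."""
    cfg = SimConfig(
        n_cancer_types=3,
        n_samples_per_type=60,
        n_genes=120,
        n_mirnas=40,
        n_probes=30,
        n_decoy_pairs=60,
        n_weak_source_pairs=5,
        n_cognate_probes=4,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    genes, mirnas = cfg.gene_ids, cfg.mirna_ids
    cfg.signatures = [
        SignatureSpec(
            name="SIG1",
            genes=genes[:20],
            driver_mirnas=mirnas[:6],
            driver_signs=[1, 1, 1, -1, -1, -1],
            driver_effect=0.5,
        )
    ]
    cfg.tsg_genes = genes[-40:]
    cfg.repressive_pairs = [
        (mirnas[j], cfg.tsg_genes[j], -0.5, 1.0) for j in range(6)
    ]
    mode_genes = cfg.tsg_genes[6:8]
    cfg.tsg_modes = {mode_genes[0]: "exclusive", mode_genes[1]: "cooccurring"}
    cfg.cognate_mirnas = {mode_genes[0]: mirnas[6:10], mode_genes[1]: mirnas[10:14]}
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def tiny_study():
    from panmir.simulate import simulate_study

    return simulate_study(tiny_sim_config(seed=42))


@pytest.fixture
def expr3x2():
    return ExpressionMatrix(
        pd.DataFrame(
            [[0.0, 1.0], [3.0, 7.0], [1.0, 0.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        ),
        "raw",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
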