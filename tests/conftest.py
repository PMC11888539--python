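import numpy as np
import pytest

from bactexclude.preprocess import compute_cpm
from bactexclude.simulate import (
    UP_IN_BACTERIAL,
    UP_IN_VIRAL,
    SignatureGeneSpec,
    SimConfig,
    generate_cohort,
)


def planted_signature(e_bact: float = 0.9, e_viral: float = 1.1):
    """Four planted genes: three bacterial-elevated, one interferon-like."""
    return (
        SignatureGeneSpec(11, UP_IN_BACTERIAL, e_bact),
        SignatureGeneSpec(57, UP_IN_BACTERIAL, e_bact),
        SignatureGeneSpec(131, UP_IN_BACTERIAL, e_bact),
        SignatureGeneSpec(211, UP_IN_VIRAL, e_viral),
    )


def recovery_config(seed: int, n_genes: int = 2000, n_samples: int = 250) -> SimConfig:
    """Scaled cohort for simulation studies: 7 batches, study class ratios,
    planted single-gene AUC around 0.83-0.90."""
    return SimConfig(signature=planted_signature()).scaled_down(
        n_genes, n_samples, seed=seed
    )


def cohort_arrays(cm, ann):
    """(X_log, y, batches, gene names) for the ARI samples of a cohort."""
    labels = ann.binary_labels()
    ari = labels.index
    cpm = compute_cpm(cm)
    X_log = np.log2(cpm.values[ari].to_numpy().T + 1.0)
    return X_log, labels.to_numpy(), ann.batch.loc[ari].to_numpy(), list(cm.genes)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests (seed fixed)."""
    cfg = recovery_config(seed=7, n_genes=400, n_samples=140)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
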