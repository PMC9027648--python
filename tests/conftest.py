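import numpy as np
import pandas as pd
import pytest

from etkras.iokit import OmicsMatrix, SampleMeta
from etkras.synthetic_data import SimulationConfig, simulate_multiomics

CONDITIONS = ("HPNE", "HPNE_EtOH", "HPNE_KRAS", "HPNE_KRAS_EtOH")
DESIGN = {
    "HPNE": ("WT", "control"),
    "HPNE_EtOH": ("WT", "treated"),
    "HPNE_KRAS": ("MUT", "control"),
    "HPNE_KRAS_EtOH": ("MUT", "treated"),
}


def make_protein_matrix(values: np.ndarray, n_rep: int = 3,
                        conditions=CONDITIONS, features=None) -> OmicsMatrix:
    """Wrap a (features x conditions*n_rep) array as a protein OmicsMatrix."""
    n_feat = values.shape[0]
    features = features or [f"P{i+1:03d}" for i in range(n_feat)]
    metas, cols = [], []
    for cond in conditions:
        geno, expo = DESIGN.get(cond, ("WT", "control"))
        for r in range(1, n_rep + 1):
            sid = f"{cond}_P{r}"
            cols.append(sid)
            metas.append(SampleMeta(sid, cond, geno, expo, r))
    df = pd.DataFrame(values, index=features, columns=cols)
    return OmicsMatrix(values=df, assay="protein_ratio", samples=metas)


def make_rna_matrix(values: np.ndarray, conditions=CONDITIONS,
                    features=None) -> OmicsMatrix:
    """Wrap a (features x conditions) count array: one library per condition."""
    n_feat = values.shape[0]
    features = features or [f"G{i+1:03d}" for i in range(n_feat)]
    metas, cols = [], []
    for cond in conditions:
        geno, expo = DESIGN.get(cond, ("WT", "control"))
        sid = f"{cond}_R1"
        cols.append(sid)
        metas.append(SampleMeta(sid, cond, geno, expo, 1))
    df = pd.DataFrame(np.asarray(values, dtype=float), index=features, columns=cols)
    return OmicsMatrix(values=df, assay="rna_counts", samples=metas)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-size generator config for fast tests (structure unchanged)."""
    return SimulationConfig(seed=7, n_transcripts=2000, n_proteins=600,
                            de_fraction=0.05)


@pytest.fixture(scope="session")
def small_simulation(small_config):
    return simulate_multiomics(small_config)
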