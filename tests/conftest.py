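import numpy as np
import pytest

from ccaae.data import OmicsMatrix, PairedDataset
from ccaae.networks import build_networks
from ccaae.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    """Small, clean synthetic paired dataset (300 cells, 3 types, 25 dB)."""
    return generate(
        SyntheticConfig(
            n_cells=300, n_types=3, dim_rna=40, dim_atac=50, latent_dim_true=6,
            snr_db=25.0, seed=42,
        )
    )


@pytest.fixture
def tiny_nets(small_dataset):
    return build_networks(
        dim_rna=small_dataset.rna.n_features,
        dim_atac=small_dataset.atac.n_features,
        latent_dim=8,
        hidden=(16,),
        disc_hidden=(16,),
        classes=sorted(np.unique(small_dataset.labels.astype(str))),
        seed=0,
    )


def make_matrix(values, modality="rna", labels=None, prefix="c"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        values=values,
        cell_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        feature_ids=[f"f{j}" for j in range(values.shape[1])],
        modality=modality,
        labels=labels,
    )


def make_paired(rna_values, atac_values, labels):
    return PairedDataset(
        rna=make_matrix(rna_values, "rna"),
        atac=make_matrix(atac_values, "atac"),
        labels=np.asarray(labels, dtype=object),
    )
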