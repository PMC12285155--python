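import numpy as np
import pytest

from fedbatch import simulate
from fedbatch.data import ExpressionDataset, LayerTag, preprocess
from fedbatch.vae import VAEConfig, init_vae, train_local


def small_config(seed: int = 0) -> simulate.SimulationConfig:
    """180-cell, 2-batch, 3-type design used across unit tests."""
    return simulate.SimulationConfig(
        n_genes=120,
        composition={
            "B0": {"alpha": 40, "beta": 30, "gamma": 20},
            "B1": {"alpha": 30, "beta": 40, "gamma": 20},
        },
        batch_effect={"B0": 0.0, "B1": 0.6},
        n_markers_per_type=12,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_raw() -> ExpressionDataset:
    ds, _ = simulate.generate(small_config())
    return ds


@pytest.fixture(scope="session")
def small_prepped(small_raw) -> ExpressionDataset:
    return preprocess(small_raw, min_genes=30, target_sum=float(small_raw.n_genes))


@pytest.fixture(scope="session")
def tiny_vae_config(small_prepped) -> VAEConfig:
    return VAEConfig(input_dim=small_prepped.n_genes, hidden_dims=(32, 32), latent_dim=8, seed=0)


@pytest.fixture(scope="session")
def trained_model(small_prepped, tiny_vae_config):
    params = init_vae(tiny_vae_config)
    params, _, _ = train_local(params, small_prepped, 10, tiny_vae_config, seed=0)
    return params


def make_dataset(matrix, batches, types, layer=LayerTag.raw_counts) -> ExpressionDataset:
    matrix = np.asarray(matrix, dtype=np.float64)
    n, g = matrix.shape
    return ExpressionDataset(
        matrix=matrix,
        batch_labels=np.asarray(batches, dtype=object),
        cell_type_labels=np.asarray(types, dtype=object),
        gene_ids=np.asarray([f"g{i}" for i in range(g)], dtype=object),
        cell_ids=np.asarray([f"c{i}" for i in range(n)], dtype=object),
        layer_tag=layer,
    )
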