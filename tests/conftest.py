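"""Shared fixtures: small synthetic study sets and a fast hyperparameter grid."""

import numpy as np
import pytest

import pocketboost as pb
from pocketboost.model import HyperGrid


@pytest.fixture(scope="session")
def tiny_grid() -> HyperGrid:
    """A 2x2x2 grid cheap enough for unit tests."""
    return HyperGrid(n_rounds=(50, 100), max_depth=(2, 4), learning_rate=(0.1, 0.3))


@pytest.fixture(scope="session")
def small_sim() -> pb.synthetic.SyntheticComplexSet:
    """150 pairs over 15 proteins, moderate noise."""
    return pb.gen_dataset(n_proteins=15, ligands_per_protein=10, noise_sd=0.3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_sim) -> pb.Dataset:
    return small_sim.to_dataset()


@pytest.fixture(scope="session")
def desk_sim() -> pb.synthetic.SyntheticComplexSet:
    """The desk-scale study set: 1000 pairs over 50 proteins, noise SD 0.3."""
    return pb.gen_dataset(n_proteins=50, ligands_per_protein=20, noise_sd=0.3, seed=2024)


@pytest.fixture(scope="session")
def desk_ablation(desk_sim):
    """Paired block ablation on the desk-scale set (shared: it is expensive)."""
    return pb.ablation_report(
        desk_sim.to_dataset(), k=5, seed=5, grid=HyperGrid.reduced()
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
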