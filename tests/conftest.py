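"""Shared fixtures: grids, bases, providers and small synthetic datasets."""

import numpy as np
import pytest

from awespec.descriptors import WacsfProvider
from awespec.io_formats import EnergyGrid, Molecule
from awespec.spectral_basis import BasisConfig, build_basis
from awespec.synthetic_data import (GroundTruthParams, SyntheticConfig,
                                    generate_dataset)


@pytest.fixture(scope="session")
def grid() -> EnergyGrid:
    return GroundTruthParams().grid()


@pytest.fixture(scope="session")
def default_basis(grid):
    return build_basis(grid, BasisConfig())


@pytest.fixture(scope="session")
def wacsf_provider():
    return WacsfProvider()


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic complexes with deterministic ground-truth spectra."""
    return generate_dataset(SyntheticConfig(n_samples=60, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_molecule(rng: np.random.Generator, n_atoms: int = 10) -> Molecule:
    """Random well-separated molecule for round-trip and invariance tests."""
    elements = tuple(rng.choice(["Fe", "O", "N", "C", "S"], size=n_atoms))
    coords = rng.uniform(-4.0, 4.0, size=(n_atoms, 3))
    return Molecule(elements, coords, absorber_index=int(rng.integers(n_atoms)))
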