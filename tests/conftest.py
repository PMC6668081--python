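"""Shared fixtures: planted models, datasets, and a small structure corpus."""

from __future__ import annotations

import numpy as np
import pytest

from redalpha import (
    AA_ORDER,
    ContactDiscretization,
    PlantedModel,
    default_backbone_partition,
    default_model,
    generate_coordinate_files,
    generate_observations,
)
from redalpha.structure_io import load_dataset


@pytest.fixture(scope="session")
def table16():
    """The packaged 16-seed Voronoi partition."""
    return default_backbone_partition()


@pytest.fixture(scope="session")
def disc_10_50():
    return ContactDiscretization(d_max=10.0, m=50)


@pytest.fixture(scope="session")
def two_basin_model():
    """Two letter groups emitting into two well-separated basins."""
    groups = {a: (0 if a in "ACDEFGHIK" else 1) for a in AA_ORDER}
    return PlantedModel(
        group_partition=groups,
        basin_centers=np.array([[0.9, 0.9], [4.0, 4.0]]),
        backbone_emission=np.array([[0.9, 0.1], [0.1, 0.9]]),
        sigma=0.15,
        contact_mu=np.array([[5.0, 7.0], [7.0, 9.0]]),
        contact_tau=0.8,
        contact_rate=1.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def planted_dataset(two_basin_model):
    return generate_observations(two_basin_model, 20_000, seed=42)


@pytest.fixture(scope="session")
def small_dataset(two_basin_model):
    return generate_observations(two_basin_model, 2_000, seed=7)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Twenty 80-residue synthetic chains read back through structure_io."""
    out = tmp_path_factory.mktemp("corpus")
    model = default_model(seed=21)
    paths, sidecar = generate_coordinate_files(model, 20, 80, out, seed=31)
    return load_dataset(paths, sidecar)


def pure_state_model(center=(0.87, 0.87), sigma=0.0, seed=1) -> PlantedModel:
    """Single-basin model: every residue emits the same dihedral pair."""
    return PlantedModel(
        group_partition={a: 0 for a in AA_ORDER},
        basin_centers=np.array([list(center)]),
        backbone_emission=np.array([[1.0]]),
        sigma=sigma,
        contact_mu=np.array([[6.0]]),
        contact_tau=1.0,
        contact_rate=0.5,
        seed=seed,
    )
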