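"""Shared fixtures: canonical meshes and one scaled-down trained model.

The trained-model fixture is deliberately session-scoped — the overfit tiny
hybrid decoder backs the reconstruction-quality and latent-utility tests.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from kneeshape.decoders import HybridConfig, make_decoder
from kneeshape.geometry import TriangleMesh
from kneeshape.sampling import BatchSpec, SamplingConfig
from kneeshape.synthetic import (
    SynthConfig,
    constant_shell_pair,
    generate_population,
    graded_shell_pair,
)
from kneeshape.training import TrainConfig, prepare_training_set, train

TRAIN_SEED = 11
TRAIN_EPOCHS = 300


def icosphere_mesh(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def sphere():
    return icosphere_mesh()


@pytest.fixture(scope="session")
def ellipsoid():
    s = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return TriangleMesh(np.asarray(s.vertices) * np.array([1.0, 0.6, 0.4]), np.asarray(s.faces))


@pytest.fixture(scope="session")
def shell_pair():
    return constant_shell_pair()


@pytest.fixture(scope="session")
def graded_pair():
    return graded_shell_pair()


@pytest.fixture(scope="session")
def population():
    return generate_population(SynthConfig(seed=TRAIN_SEED, population=10))


GRID_RES = 64
SPACING = 2.0 / (GRID_RES - 1)  # normalized units


def refit_config(epochs: int = 300):
    from kneeshape.reconstruction import FitConfig

    return FitConfig(
        epochs=epochs,
        n_surface_points=2000,
        delta=1.0,  # matched to the hybrid decoder's clamp bound
        patience=50,
        mean_grid_resolution=48,
    )


@pytest.fixture(scope="session")
def refit(trained_tiny):
    """One training shape refit from a random latent, reused across tests."""
    from kneeshape.reconstruction import fit_latent, reconstruct

    decoder = trained_tiny["decoder"]
    params = trained_tiny["result"].params
    sid = sorted(trained_tiny["pairs"])[2]
    pair = trained_tiny["pairs"][sid]
    result = fit_latent(decoder, params, pair, refit_config(), seed=4)
    recon = reconstruct(decoder, params, result.latent, result.transform, resolution=GRID_RES)
    return {"sid": sid, "pair": pair, "result": result, "recon": recon}


@pytest.fixture(scope="session")
def trained_tiny(population):
    """Tiny hybrid autodecoder overfit on the 10-shape synthetic population."""
    from kneeshape.cli import scaled_schedules

    pairs = [s.pair for s in population]
    dataset, transforms = prepare_training_set(pairs, SamplingConfig(n_total=15_000), seed=7)
    cfg = TrainConfig(
        epochs=TRAIN_EPOCHS,
        batch=BatchSpec(points_per_step=1024),
        schedules=scaled_schedules(TRAIN_EPOCHS),
        seed=3,
    )
    decoder = make_decoder(HybridConfig.tiny())
    result = train(dataset, decoder, cfg)
    return {
        "decoder": decoder,
        "result": result,
        "dataset": dataset,
        "transforms": transforms,
        "pairs": {p.frame_id: p for p in pairs},
    }
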