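"""Shared fixtures: small phantoms and analytic warps, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lungstrain.synthetic_data import GradedDorsoventralWarp, PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_phantom_cfg() -> PhantomConfig:
    """A 48^3, 4 mm phantom: fast, yet >= 10 voxels across each lung axis."""
    return PhantomConfig(shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0),
                         lung_semiaxes_mm=(62.0, 48.0, 26.0), noise_sd=5.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_cfg):
    return make_phantom(small_phantom_cfg)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and texture-free phantom: exact ramp HU inside exact ellipsoids."""
    cfg = PhantomConfig(shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0),
                        lung_semiaxes_mm=(62.0, 48.0, 26.0),
                        noise_sd=0.0, texture_sd=0.0, seed=0)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def graded_warp(small_phantom_cfg):
    ctr = small_phantom_cfg.center_mm
    b = small_phantom_cfg.lung_semiaxes_mm[1]
    return GradedDorsoventralWarp(y0_mm=ctr[1] - b, y1_mm=ctr[1] + b,
                                  strain_ventral_pct=15.0, strain_dorsal_pct=40.0)


def grid_points_mm(shape, spacing) -> np.ndarray:
    """Physical coordinates (..., 3) of every voxel centre."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
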