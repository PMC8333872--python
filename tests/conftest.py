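"""Shared fixtures: default geometry and small synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from gazekit.geometry import ScreenGeometry
from gazekit.synthetic import (
    CameraModel,
    FaceModel,
    SimulationConfig,
    generate_calibration_path,
    simulate_session,
)


@pytest.fixture(scope="session")
def geom() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def face() -> FaceModel:
    return FaceModel()


@pytest.fixture(scope="session")
def cam() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def short_path(geom):
    """A fast two-line raster (~150 frames) for unit-level session tests."""
    return generate_calibration_path(geom, n_lines=2, base_speed_px_s=2000.0)


@pytest.fixture(scope="session")
def small_session(geom, face, cam, short_path):
    """A three-pose session over the short raster, 1 px noise, with blinks."""
    cfg = SimulationConfig(seed=11)
    landmarks, targets = simulate_session(short_path, face, cam, geom, cfg)
    return landmarks, targets, cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
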