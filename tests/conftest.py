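"""Shared fixtures: simulated seasons and a cross-season image set.

The heavier artifacts (the 100-day noiseless stream, the two-season image
set) are session-scoped so every test that needs them shares one
simulation.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from phenoscale import IrrigationPolicy, SubstrateSpec
from phenoscale.images import preprocess_image
from phenoscale.simulate import (
    CameraSpec,
    GrowthParams,
    SensorSimConfig,
    default_capture_times,
    simulate_camera_day,
    simulate_growth,
    simulate_sensors_with_log,
)
from phenoscale.types import LabelTable


@pytest.fixture(scope="session")
def substrate():
    return SubstrateSpec()


@pytest.fixture(scope="session")
def policy():
    return IrrigationPolicy()


@pytest.fixture(scope="session")
def truth_season():
    """101 days of default logistic growth (deterministic)."""
    return simulate_growth(GrowthParams(), 101, seed=1)


@pytest.fixture(scope="session")
def equilibrium_stream(truth_season, substrate, policy):
    """Noiseless stream with the controller holding the slab at capacity
    (no transpiration drawdown): the configuration in which daily
    aggregation is exactly mass-conserving."""
    cfg = SensorSimConfig(weight_sd=0.0, vwc_sd=0.0, transpiration_coeff=0.0)
    return simulate_sensors_with_log(truth_season, substrate, policy, cfg, seed=2)


@pytest.fixture(scope="session")
def drawdown_stream(truth_season, substrate, policy):
    """Noiseless stream with transpiration on (daytime VWC drawdown)."""
    cfg = SensorSimConfig(weight_sd=0.0, vwc_sd=0.0)
    return simulate_sensors_with_log(truth_season, substrate, policy, cfg, seed=2)


def _render_season(growth, camera, n_days, per_day, seed):
    truth = simulate_growth(growth, n_days, seed)
    times = default_capture_times(8, 16, per_day)
    tensors = []
    for di, t in enumerate(truth):
        date = datetime(2020, 3, 1) + pd.Timedelta(days=di)
        frames = simulate_camera_day(
            t, camera, date, seed * 1009 + di, capture_times=times
        )
        tensors.extend(preprocess_image(f) for f in frames)
    labels = LabelTable(
        dat=np.array([t.dat for t in truth]),
        leaf_area_label=np.array([t.leaf_area for t in truth]),
    )
    return truth, tensors, labels


@pytest.fixture(scope="session")
def cross_season_imageset():
    """Two rendered seasons with different growth parameters and
    illumination, preprocessed once and shared by the image-model tests.

    Season A (training): 80 days x 5 frames; season B (test): 60 days x 8
    frames — more test frames per day stabilise the daily means the model
    is scored on.
    """
    growth_a = GrowthParams()
    growth_b = GrowthParams(
        fw_asymptote=2.8,
        la_asymptote=4200.0,
        la_rate=0.09,
        la_midpoint=45.0,
        la_baseline=80.0,
        topping_dat=70,
    )
    cam_a = CameraSpec()
    cam_b = CameraSpec(illumination=0.85)
    truth_a, tensors_a, labels_a = _render_season(growth_a, cam_a, 80, 5, seed=11)
    truth_b, tensors_b, labels_b = _render_season(growth_b, cam_b, 60, 8, seed=22)
    return {
        "train": (tensors_a, labels_a),
        "test": (tensors_b, labels_b),
    }


@pytest.fixture(scope="session")
def trained_canopy_model(cross_season_imageset):
    """Canopy regressor trained once on season A; shared by the
    cross-season accuracy, signal-dependence and control tests."""
    from phenoscale.images import CanopyRegressor, RegressorSpec

    tensors_a, labels_a = cross_season_imageset["train"]
    return CanopyRegressor(tensors_a, labels_a, RegressorSpec()).fit(seed=5)
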