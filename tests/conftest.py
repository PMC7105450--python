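"""Shared fixtures: default parameters, small geometries, and one small
lattice-Boltzmann solve reused across flow tests."""

from __future__ import annotations

import numpy as np
import pytest

from ecmigrate.model_core import ModelParams
from ecmigrate import geometry, flow


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def small_flat_geom() -> geometry.ChannelGeometry:
    return geometry.flat_channel(length=2.0, height=0.5, width=0.45)


@pytest.fixture(scope="session")
def lb_flat_field(small_flat_geom, params):
    """LB solution of a short flat channel (analytic profile is the oracle)."""
    return flow.solve_channel_flow(small_flat_geom, params, force_lb=True)


@pytest.fixture(scope="session")
def small_ridged_geom() -> geometry.ChannelGeometry:
    return geometry.ridged_channel(length=4.0, width=0.45, first_ridge_x=2.0,
                                   n_ridges=1)


@pytest.fixture(scope="session")
def ridged_result(small_ridged_geom):
    """One scaled-down ridged scenario (12 h, single strut) shared by the
    flow diagnostics and the end-to-end scenario checks."""
    from ecmigrate.scenarios import ScenarioConfig, run_scenario

    cfg = ScenarioConfig.for_scenario(
        "ridged", hours=12.0, seed=3, seed_region=(1.0, 2.0),
        geometry_kwargs={"length": 4.0, "width": 0.45,
                         "first_ridge_x": 2.0, "n_ridges": 1})
    return run_scenario(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
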