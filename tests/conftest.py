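"""Shared fixtures: baseline parameters, compiled model, cached trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from dsbrepair import (
    ExposureProtocol,
    RepairModel,
    build_network,
    default_parameters,
    run_protocol,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def model(params):
    return RepairModel(params)


@pytest.fixture(scope="session")
def network(params):
    return build_network(params)


@pytest.fixture(scope="session")
def trajectory_at(params, model):
    """Memoized baseline trajectory per dose (dense 24-h output grid)."""
    cache: dict[float, object] = {}

    def get(dose_mgy: float):
        if dose_mgy not in cache:
            cache[dose_mgy] = run_protocol(
                ExposureProtocol.from_mgy(dose_mgy), params, model=model
            )
        return cache[dose_mgy]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20230909)
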