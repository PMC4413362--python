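"""Shared fixtures: small phantoms and regressor series reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvrbh import (
    HrfSpec,
    Paradigm,
    RegressorBuilder,
    build_regressor_series,
    make_stroke_phantom,
    run_phantom_study,
    simulate_capnograph,
)

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

# small phantom geometry used where full size is unnecessary
SMALL = dict(
    shape=(20, 24, 20),
    voxel_size_mm=(3.5, 3.5, 3.0),
    lesion_center_mm=(-20.0, 3.0, 4.0),
    lesion_radius_mm=10.0,
)


@pytest.fixture(scope="session")
def small_geom() -> dict:
    return dict(SMALL)


@pytest.fixture(scope="session")
def paradigm() -> Paradigm:
    return Paradigm()


@pytest.fixture(scope="session")
def co2_series(paradigm):
    """Noiseless capnograph run through the full regressor chain."""
    trace = simulate_capnograph(paradigm, noise_sd=0.0, seed=0)
    return build_regressor_series(trace, paradigm, HrfSpec())


@pytest.fixture(scope="session")
def co2_builder(paradigm, co2_series):
    n = paradigm.n_frames(drop_first=1)
    return RegressorBuilder(co2_series, tr=paradigm.tr, n_frames=n, t0=paradigm.tr)


@pytest.fixture(scope="session")
def small_truth():
    return make_stroke_phantom(seed=7, **SMALL)


@pytest.fixture(scope="session")
def noiseless_study():
    """Full pipeline on a small noiseless stroke phantom."""
    return run_phantom_study(
        seed=5, noise_sd=0.0, capno_noise_sd=0.0, rel_window=5.0, **SMALL
    )


@pytest.fixture(scope="session")
def noisy_study():
    """Small phantom with the default voxel noise (median voxel R2 near 0.4)."""
    return run_phantom_study(seed=9, noise_sd=0.5, rel_window=5.0, **SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
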