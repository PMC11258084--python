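"""Shared fixtures: small phantoms and scans reused across test modules."""

import numpy as np
import pytest

from cacsim import (
    AcquisitionProtocol,
    build_calibration_phantom,
    build_measurement_phantom,
    generate_fixtures,
)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Reduced-grid fixture bundle: phantoms, noiseless + noisy scans, masks."""
    return generate_fixtures("tiny", seed=3)


@pytest.fixture(scope="session")
def medium_low_phantom():
    return build_measurement_phantom("medium", "low")


@pytest.fixture(scope="session")
def gammex_phantom():
    return build_calibration_phantom(patient_size="medium")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fast_protocol():
    return AcquisitionProtocol(kv=120.0, exposure_mr=2.0, n_angles=180)
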