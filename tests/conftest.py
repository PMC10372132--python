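import numpy as np
import pytest
from hypothesis import settings

import hmrcal as h

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    return h.build_phantom()


@pytest.fixture(scope="session")
def calibrated(default_phantom):
    return h.calibrate_activities(default_phantom)


@pytest.fixture(scope="session")
def cache(calibrated):
    return h.ProjectionCache(calibrated)


@pytest.fixture(scope="session")
def rois(calibrated):
    return h.place_rois(calibrated)


@pytest.fixture()
def acq():
    return h.AcquisitionSpec(total_photons=1e7, seed=0)


@pytest.fixture(scope="session")
def discovery():
    return {
        label: h.get_collimator_preset("GE Discovery", label)
        for label in ("LEHR", "ELEGP", "MEGP")
    }


def synthetic_feature_table(n=120, seed=0, noise=0.005):
    """Smooth surrogate (d, t, L) -> coefficient table for fast ML tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    d = rng.uniform(1.0, 3.5, n)
    t = rng.uniform(0.15, 1.5, n)
    L = rng.uniform(20.0, 60.0, n)
    cc = (
        0.45
        + 0.5 * (1.0 - np.exp(-2.5 * t))
        + 0.05 * (L - 40.0) / 40.0
        - 0.03 * (d - 2.0)
        + rng.normal(0.0, noise, n)
    )
    return pd.DataFrame({"d_mm": d, "t_mm": t, "L_mm": L, "compensated_cc": cc})
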