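import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitphase as gp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    return gp.make_default_template()


@pytest.fixture(scope="session")
def small_dataset(template):
    """Balanced labelled frames: 20 per class at 4 km/h, default noise."""
    return gp.make_dataset(template, n_per_class=20, speed_kmh=4.0, seed=7)


@pytest.fixture(scope="session")
def calibrated_model(template):
    """A (profile, model) pair trained on calibrated 4 km/h frames."""
    standing = gp.simulate_standing(template, duration_s=10.0, noise_sd=0.03, seed=11)
    profile = gp.fit_calibration(standing)
    frames = gp.make_dataset(template, n_per_class=20, speed_kmh=4.0, seed=13)
    frames = [gp.apply_calibration(fv, profile) for fv in frames]
    model = gp.fit(frames, k=3, weighting=gp.DISTANCE_WEIGHTED)
    return profile, model


def make_frames(rows, labels=None):
    """Build FeatureVectors from an array-like of 5-value rows."""
    rows = np.asarray(rows, dtype=float)
    out = []
    for i, row in enumerate(rows):
        label = labels[i] if labels is not None else None
        out.append(gp.FeatureVector(values=row, t_start=0.05 * i, label=label))
    return out
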