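import numpy as np
import pytest

from ufib.synth import SynthConfig, make_cohort


def circular_arc(radius, theta_deg, center=(0.0, 0.0, 0.0), n=200, plane=("x", "y")):
    """Planar circular arc in closed form (oracle geometry for U-shape tests)."""
    theta = np.radians(theta_deg)
    phi = np.linspace(0.0, theta, n)
    pts = np.zeros((n, 3))
    axes = {"x": 0, "y": 1, "z": 2}
    pts[:, axes[plane[0]]] = radius * np.cos(phi)
    pts[:, axes[plane[1]]] = radius * np.sin(phi)
    return pts + np.asarray(center)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared by pipeline-level tests."""
    cfg = SynthConfig(
        n_controls=8,
        n_patients=8,
        n_bundles=3,
        streamlines_per_bundle_mean=15.0,
        streamlines_per_bundle_sd=3.0,
        n_distractor_straight=20,
        grid_shape=(40, 40, 40),
        seed=11,
    )
    return make_cohort(cfg)
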