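import numpy as np
import pytest

from shapemed import (
    LandmarkCurve,
    SimulationScenario,
    cc_like_template,
    normalize_landmarks,
    simulate_cohort,
    srvf_transform,
)


@pytest.fixture(scope="session")
def template():
    return cc_like_template(150)


@pytest.fixture(scope="session")
def template_srvf(template):
    return srvf_transform(normalize_landmarks(template, 100), unit_norm=True)


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate-size draw from the default simulation scenario."""
    return simulate_cohort(SimulationScenario(n=200, T=50, seed=42))


def fourier_curve(m: int = 120, seed: int = 0) -> LandmarkCurve:
    """A random smooth open curve for property-style checks."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, m)
    pts = np.zeros((m, 2))
    for k in range(1, 4):
        pts[:, 0] += rng.normal(0, 1 / k) * np.sin(np.pi * k * t) + rng.normal(0, 1 / k) * np.cos(np.pi * k * t)
        pts[:, 1] += rng.normal(0, 1 / k) * np.sin(np.pi * k * t) + rng.normal(0, 1 / k) * np.cos(np.pi * k * t)
    pts[:, 0] += t
    return LandmarkCurve(points=pts, subject_id=f"rand{seed}")
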