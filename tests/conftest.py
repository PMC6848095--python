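import numpy as np
import pytest

from spinerod import ProfileParams, generate_sagittal_profile
from spinerod.pipeline import default_config, run_experiment


@pytest.fixture(scope="session")
def default_report():
    """Full default experiment (six archetype solves), shared across tests."""
    return run_experiment(default_config())


@pytest.fixture(scope="session")
def group2_profile():
    """Default Group II archetype profile (kyphotic 12 / lordotic 5)."""
    return generate_sagittal_profile(ProfileParams(12, 5, 0.080, 0.050),
                                     group_tag="GroupII")


@pytest.fixture(scope="session")
def group1_profile():
    """Default Group I archetype profile (kyphotic 6 / lordotic 11)."""
    return generate_sagittal_profile(ProfileParams(6, 11, 0.070, 0.080),
                                     group_tag="GroupI")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sampled_helix(a=1.0, b=0.3, n=100, turns=2.0):
    """Circular helix with closed-form torsion b / (a^2 + b^2)."""
    theta = np.linspace(0.0, 2.0 * np.pi * turns, n)
    return np.column_stack([a * np.cos(theta), a * np.sin(theta), b * theta])
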