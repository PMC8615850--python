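"""Shared fixtures: phantoms are generated programmatically, never stored."""

from __future__ import annotations

import warnings

import pytest

from leadorient.cli import run_suite, summarize_suite
from leadorient.phantom import PhantomSpec, SuiteConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free upright phantom, yaw 30 deg."""
    spec = PhantomSpec(yaw_true_deg=30.0, polar_deg=0.0, noise_sigma_hu=0.0, seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tilted_noisy_phantom():
    """Realistic conditions: yaw 75, polar 20, sigma 15 HU, seed 7."""
    spec = PhantomSpec(
        yaw_true_deg=75.0,
        polar_deg=20.0,
        tilt_azimuth_deg=30.0,
        noise_sigma_hu=15.0,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Perfectly 180-degree-symmetric phantom: no window, no asymmetries."""
    spec = PhantomSpec(
        yaw_true_deg=30.0,
        polar_deg=0.0,
        noise_sigma_hu=0.0,
        window_angle_deg=0.0,
        a1_hu=0.0,
        a3_hu=0.0,
        seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def suite_rows():
    """Detection results over the standard 96-phantom validation suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_suite(SuiteConfig())


@pytest.fixture(scope="session")
def suite_summary(suite_rows):
    return summarize_suite(suite_rows)


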