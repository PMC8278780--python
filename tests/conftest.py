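"""Shared fixtures: reduced-scale acquisition settings so simulation-backed
tests run in seconds, and commonly reused simulated scans."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from srssoct import AcquisitionConfig, LaserConfig, layered_phantom, simulate_mscan

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


TINY_KW = dict(frames_per_ascan=256, n_pixels=512, ascans_per_bscan=6)


@pytest.fixture(scope="session")
def laser():
    return LaserConfig()


@pytest.fixture(scope="session")
def tiny_acq():
    """512 spectral pixels x 256 frames: ~1 mm depth range, 195 Hz bins."""
    return AcquisitionConfig(**TINY_KW)


@pytest.fixture(scope="session")
def tiny_acq_noiseless():
    return AcquisitionConfig(shot_noise_scale=0.0, pump_rin=0.0, **TINY_KW)


def tiny_phantom(**kw):
    """Phantom sized for the ~1 mm depth range of the tiny acquisition."""
    base = dict(
        surface_depth_um=120.0,
        thickness_um=600.0,
        depth_extent_um=900.0,
        attenuation_mm=8.17,
        srs_decay_mm=7.83,
    )
    base.update(kw)
    return layered_phantom(**base)


@pytest.fixture(scope="session")
def healthy_scan(tiny_acq):
    """One noisy healthy-tissue M-scan at tiny scale."""
    return simulate_mscan(tiny_phantom(label="healthy"), acq=tiny_acq, seed=7)


@pytest.fixture(scope="session")
def noiseless_scan(tiny_acq_noiseless):
    return simulate_mscan(tiny_phantom(label="healthy"), acq=tiny_acq_noiseless, seed=7)
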