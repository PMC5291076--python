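"""Shared fixtures: published-mass components and small synthetic spectra."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import lilbidms as L

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def kcsa():
    """KcsA target, theoretical mass, with labeled mass attached."""
    return L.construct_component("KcsA", L.Role.TARGET)


@pytest.fixture(scope="session")
def msp1e3d1():
    return L.construct_component("MSP1E3D1", L.Role.SCAFFOLD)


@pytest.fixture(scope="session")
def dmpg():
    return L.lipid_component("DMPG")


@pytest.fixture(scope="session")
def dopg():
    return L.lipid_component("DOPG")


@pytest.fixture(scope="session")
def kcsa_sample(kcsa, msp1e3d1):
    """KcsA in MSP1E3D1 discs: tetramer plus scaffold combinatorics."""
    return L.SampleDefinition(target=kcsa, scaffold=msp1e3d1, n_max=4, m_max=2)


def gaussian_spectrum(centers, sigmas, heights, lo, hi, step=0.005, metadata=None):
    """Analytic multi-Gaussian spectrum on a uniform grid (no noise)."""
    grid = np.arange(lo, hi + step / 2, step)
    y = np.zeros_like(grid)
    for c, s, h in zip(centers, sigmas, heights):
        y += h * np.exp(-0.5 * ((grid - c) / s) ** 2)
    return L.Spectrum(grid, y, metadata or {})


@pytest.fixture
def make_gaussian_spectrum():
    return gaussian_spectrum
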