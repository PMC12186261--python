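import numpy as np
import pytest

import sonosaxs as ss

CHI_1DEG = np.arange(0.0, 360.0, 1.0)


@pytest.fixture
def chi_grid():
    return CHI_1DEG.copy()


def delta_profile(chi_deg: float, height: float = 5.0) -> ss.AzimuthalProfile:
    """Azimuthal profile with all intensity in the bin nearest chi_deg."""
    chi = CHI_1DEG.copy()
    intensity = np.zeros_like(chi)
    intensity[int(round(chi_deg)) % 360] = height
    return ss.AzimuthalProfile(chi=chi, I=intensity, mask=np.ones_like(chi, dtype=bool))


def vonmises_profile(kappa: float, chi_pref: float = 0.0) -> ss.AzimuthalProfile:
    chi = CHI_1DEG.copy()
    intensity = np.exp(kappa * np.cos(2.0 * np.deg2rad(chi - chi_pref)))
    return ss.AzimuthalProfile(chi=chi, I=intensity, mask=np.ones_like(chi, dtype=bool))


def of_oracle_vonmises(kappa: float, n: int = 100_001) -> float:
    """Dense-grid quadrature of the sin-weighted Hermans integral, written
    independently of the implementation under test."""
    chi = np.linspace(0.0, np.pi / 2.0, n)
    w = np.exp(kappa * np.cos(2.0 * chi))
    cos2 = np.trapezoid(w * np.sin(chi) * np.cos(chi) ** 2, chi) / np.trapezoid(
        w * np.sin(chi), chi
    )
    return (3.0 * cos2 - 1.0) / 2.0


@pytest.fixture
def ring_pattern():
    """Noiseless isotropic diffraction ring, no background, default gaps."""
    cfg = ss.SaxsSimConfig(q0=0.1308, delta_q=0.0045, peak_amplitude=1000.0,
                           background_B=0.0, noise=False)
    return ss.simulate_saxs_pattern(cfg), cfg


@pytest.fixture(scope="session")
def small_scan():
    """21 x 21 banded scan with noise, reduced pattern resolution."""
    saxs = ss.SaxsSimConfig(
        q_grid=np.linspace(0.09, 0.18, 96),
        chi_grid=np.arange(0.0, 360.0, 5.0),
        peak_amplitude=2e4,
        background_B=1e-7,
        noise=True,
    )
    scan = ss.ScanSimConfig(nx=21, ny=21, seed=42)
    return ss.simulate_scan(scan, saxs)
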