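"""Synthetic SAXS patterns, raster scans, and bright-field micrographs.

No raw synchrotron or microscope data accompanies the study conditions this
package targets, so every downstream stage is exercised against generators
with known ground truth:

* a single-pattern model: lamellar diffraction ring at q0 ~ 0.13 A^-1 with a
  Gaussian radial cross-section, an axial (180-degree periodic) von Mises
  azimuthal weight, a low-q power-law background, an optional broad
  "capillary-wall" shoulder in q = 0.04-0.08 A^-1, detector-gap masks and
  Poisson counting noise;
* a raster scan whose per-point parameters are modulated by a sinusoidal
  band profile emulating the nodal planes of an ultrasound standing wave
  (default: 101 x 101 points, 20 um step, 0.3 mm band period);
* a grayscale micrograph with the same band shading plus elongated platelet
  silhouettes whose orientations follow an axial von Mises law.

All randomness flows from one seed through ``numpy.random.SeedSequence``
derived streams, so e.g. adding platelets does not perturb the band noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .reduction import ScatteringPattern

__all__ = [
    "SaxsSimConfig",
    "ScanSimConfig",
    "MicrographSimConfig",
    "ScanSimulation",
    "Micrograph",
    "simulate_saxs_pattern",
    "expected_saxs_intensity",
    "simulate_scan",
    "simulate_band_map",
    "simulate_micrograph",
    "axial_vonmises_weight",
    "of_from_kappa",
    "kappa_for_of",
]


class SimulationError(ValueError):
    """Raised for invalid generator configurations."""


def _default_q_grid() -> np.ndarray:
    return np.linspace(0.005, 0.20, 256)


def _default_chi_grid() -> np.ndarray:
    return np.arange(0.0, 360.0, 1.0)


@dataclass
class SaxsSimConfig:
    """Forward-model parameters for one synthetic scattering pattern.

    Intensity model (counts), evaluated on the (q, chi) grid::

        I(q, chi) = B * q**P
                  + A * exp(-4 ln2 (q - q0)^2 / delta_q^2) * g(chi)
                  [+ shoulder]

    with ``g`` an axial von Mises weight of concentration ``kappa`` about
    ``chi_pref`` normalized to unit circular mean (``g == 1`` for
    ``kappa=0``), so the azimuthally averaged ring is independent of the
    degree of orientation.
    """

    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    chi_grid: np.ndarray = field(default_factory=_default_chi_grid)
    q0: float = 0.1308            # ring center, A^-1
    delta_q: float = 0.0045       # ring fwhm, A^-1
    peak_amplitude: float = 1000.0  # counts at ring maximum (isotropic part)
    background_B: float = 1e-3    # power-law prefactor, counts * A^P
    background_P: float = -3.5    # power-law exponent
    kappa: float = 0.0            # axial von Mises concentration (0 = isotropic)
    chi_pref: float = 0.0         # preferred azimuth of ring maximum, deg
    gap_period: float = 25.0      # detector-gap spacing, deg (0 disables)
    gap_width: float = 10.0       # deg
    shoulder_on: bool = False     # spurious broad shoulder at 0.04-0.08 A^-1
    noise: bool = False           # Poisson sampling of expected counts
    seed: int = 0

    def validate(self) -> None:
        q = np.asarray(self.q_grid, float)
        if q.size < 2 or np.any(np.diff(q) <= 0) or q[0] <= 0:
            raise SimulationError("q_grid must be strictly increasing and positive")
        if self.delta_q <= 0:
            raise SimulationError("delta_q must be positive")
        if self.kappa < 0:
            raise SimulationError("kappa must be >= 0")
        if not (q[0] <= self.q0 <= q[-1]):
            raise SimulationError("q0 outside q_grid")
        if self.peak_amplitude < 0 or self.background_B < 0:
            raise SimulationError("amplitudes must be non-negative")


@dataclass
class ScanSimConfig:
    """Raster-scan geometry and band modulation for a synthetic USW scan.

    Defaults mirror the acquisition of the sonicated samples: a 2 x 2 mm
    area covered in 101 x 101 points at 20 um step, with nodal bands of
    denser, more oriented, thicker crystals spaced 0.3 mm apart.
    """

    nx: int = 101
    ny: int = 101
    step: float = 0.020           # mm
    band_period: float = 0.3      # mm, nodal-band spacing
    band_axis: float = 0.0        # deg; direction normal to the bands
    band_contrast: float = 0.5    # relative peak-amplitude modulation, [0, 1]
    of_in_band: float = 0.8       # target orientation factor at band centers
    xi_in_band: float = 1770.0    # correlation length at band centers, A
    xi_out_band: float = 1440.0   # correlation length between bands, A
    seed: int = 0

    def validate(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise SimulationError("grid must be at least 2 x 2")
        if not (0.0 <= self.band_contrast <= 1.0):
            raise SimulationError("band_contrast must be in [0, 1]")
        if self.band_period <= 2 * self.step:
            raise SimulationError("band_period must exceed two grid steps")
        extent = max(self.nx, self.ny) * self.step
        if self.band_period > extent:
            raise SimulationError("grid too small to hold one band period")
        if self.xi_in_band <= 0 or self.xi_out_band <= 0:
            raise SimulationError("correlation lengths must be positive")


@dataclass
class MicrographSimConfig:
    """Synthetic bright-field micrograph: band shading + platelet silhouettes."""

    width: int = 512              # px
    height: int = 512             # px
    pixel_size: float = 1.0       # um/px (placeholder; instrument-dependent)
    band_period: float = 300.0    # um
    band_axis: float = 0.0        # deg; direction normal to the bands
    band_contrast: float = 0.3    # relative shading amplitude, [0, 1]
    n_platelets: int = 150
    platelet_length: tuple[float, float] = (20.0, 5.0)   # mean, sd (um)
    platelet_width: tuple[float, float] = (3.0, 0.8)     # mean, sd (um)
    kappa: float = 0.0            # axial von Mises concentration about band_axis
    blur_sigma: float = 1.5       # px
    noise_sigma: float = 3.0      # gray levels
    base_gray: float = 180.0
    platelet_gray: float = 70.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise SimulationError("image too small")
        if self.pixel_size <= 0:
            raise SimulationError("pixel_size must be positive")
        if self.n_platelets < 0:
            raise SimulationError("n_platelets must be >= 0")
        if not (0.0 <= self.band_contrast <= 1.0):
            raise SimulationError("band_contrast must be in [0, 1]")
        max_extent = max(self.width, self.height) * self.pixel_size
        if self.n_platelets and self.platelet_length[0] > max_extent:
            raise SimulationError("platelet length exceeds image extent")


@dataclass
class Micrograph:
    """Grayscale image with physical pixel size (um/pixel)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise SimulationError("micrograph must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise SimulationError("micrograph contains non-finite values")
        if self.pixel_size <= 0:
            raise SimulationError("pixel_size must be positive")


# --------------------------------------------------------------------------
# axial von Mises orientation weight and its Hermans orientation factor

def axial_vonmises_weight(chi_deg: np.ndarray, kappa: float, chi_pref: float = 0.0) -> np.ndarray:
    """Axial (180-deg periodic) von Mises weight with unit circular mean.

    g(chi) = exp(kappa * cos(2*(chi - chi_pref))) / I0(kappa); the mean of g
    over a full uniform circle equals 1 for every kappa, so total ring
    counts are conserved as the orientation sharpens.
    """
    rad = np.deg2rad(np.asarray(chi_deg, float) - chi_pref)
    return np.exp(kappa * np.cos(2.0 * rad)) / special.i0(kappa)


def of_from_kappa(kappa: float, n: int = 20001) -> float:
    """Hermans orientation factor of an axial von Mises profile about 0 deg.

    Dense trapezoidal quadrature of the sin-weighted <cos^2 chi> integral
    over [0, pi/2]; used to map a target orientation factor to a generator
    concentration, and serves as an independent reference in tests.
    """
    chi = np.linspace(0.0, np.pi / 2.0, n)
    g = np.exp(kappa * np.cos(2.0 * chi))
    num = np.trapezoid(g * np.sin(chi) * np.cos(chi) ** 2, chi)
    den = np.trapezoid(g * np.sin(chi), chi)
    return float((3.0 * num / den - 1.0) / 2.0)


def kappa_for_of(target_of: float) -> float:
    """Invert :func:`of_from_kappa` for a target in [0, ~0.99]."""
    if not (-1e-9 <= target_of < 0.995):
        raise SimulationError("target orientation factor must be in [0, 0.995)")
    if target_of <= 0:
        return 0.0
    return float(optimize.brentq(lambda k: of_from_kappa(k) - target_of, 0.0, 500.0))


# --------------------------------------------------------------------------
# single-pattern forward model

def _gap_mask(chi_grid: np.ndarray, gap_period: float, gap_width: float) -> np.ndarray:
    """True = valid bin; gaps of gap_width centered every gap_period degrees."""
    if gap_period <= 0 or gap_width <= 0:
        return np.ones_like(chi_grid, dtype=bool)
    dist = np.abs(np.mod(chi_grid + gap_period / 2.0, gap_period) - gap_period / 2.0)
    return dist > gap_width / 2.0


def expected_saxs_intensity(cfg: SaxsSimConfig) -> np.ndarray:
    """Noise-free expected counts on the (q, chi) grid of ``cfg``."""
    cfg.validate()
    q = np.asarray(cfg.q_grid, float)[:, None]
    chi = np.asarray(cfg.chi_grid, float)[None, :]
    bg = cfg.background_B * q ** cfg.background_P
    ring = cfg.peak_amplitude * np.exp(
        -4.0 * np.log(2.0) * (q - cfg.q0) ** 2 / cfg.delta_q ** 2
    )
    g = axial_vonmises_weight(chi, cfg.kappa, cfg.chi_pref)
    expected = bg + ring * g
    if cfg.shoulder_on:
        # broad nuisance bump spanning ~0.04-0.08 A^-1 (capillary-wall artifact)
        shoulder_amp = 0.2 * cfg.background_B * 0.06 ** cfg.background_P
        expected = expected + shoulder_amp * np.exp(-0.5 * ((q - 0.06) / 0.010) ** 2)
    if np.any(expected < 0):
        raise SimulationError("expected intensity negative; check config")
    return np.broadcast_to(expected, (q.size, chi.size)).copy()


def simulate_saxs_pattern(cfg: SaxsSimConfig, rng: np.random.Generator | None = None) -> ScatteringPattern:
    """Generate one scattering pattern; Poisson-sampled iff ``cfg.noise``.

    Masked (detector-gap) bins are flagged in the pattern mask, never
    zeroed, so downstream statistics can exclude them cleanly.
    """
    expected = expected_saxs_intensity(cfg)
    if cfg.noise:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        intensity = rng.poisson(expected).astype(float)
    else:
        intensity = expected
    mask_1d = _gap_mask(np.asarray(cfg.chi_grid, float), cfg.gap_period, cfg.gap_width)
    mask = np.broadcast_to(mask_1d[None, :], intensity.shape).copy()
    return ScatteringPattern(
        intensity=intensity,
        q_grid=np.asarray(cfg.q_grid, float).copy(),
        chi_grid=np.asarray(cfg.chi_grid, float).copy(),
        mask=mask,
        meta={"synthetic": True, "config": cfg},
    )


# --------------------------------------------------------------------------
# raster scan with band-modulated parameters

@dataclass
class ScanSimulation:
    """Lazy container of a simulated raster scan.

    Patterns are synthesized on demand (``pattern_at`` / iteration) so a
    full 101 x 101 scan never has to be held in memory at once.  The
    ``truth`` table records the per-point ground-truth parameters.
    """

    scan_cfg: ScanSimConfig
    saxs_cfg: SaxsSimConfig
    positions: np.ndarray          # (n, 2) in mm, columns x, y
    truth: pd.DataFrame            # one row per point
    _seeds: np.ndarray

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    def truth_map(self, column: str) -> np.ndarray:
        """Ground-truth column reshaped to the (ny, nx) grid."""
        return self.truth[column].to_numpy().reshape(self.scan_cfg.ny, self.scan_cfg.nx)

    def pattern_at(self, index: int) -> ScatteringPattern:
        row = self.truth.iloc[index]
        cfg = SaxsSimConfig(
            q_grid=self.saxs_cfg.q_grid,
            chi_grid=self.saxs_cfg.chi_grid,
            q0=self.saxs_cfg.q0,
            delta_q=float(row["delta_q"]),
            peak_amplitude=float(row["amplitude"]),
            background_B=self.saxs_cfg.background_B,
            background_P=self.saxs_cfg.background_P,
            kappa=float(row["kappa"]),
            chi_pref=self.saxs_cfg.chi_pref,
            gap_period=self.saxs_cfg.gap_period,
            gap_width=self.saxs_cfg.gap_width,
            shoulder_on=self.saxs_cfg.shoulder_on,
            noise=self.saxs_cfg.noise,
        )
        rng = np.random.default_rng(int(self._seeds[index]))
        pattern = simulate_saxs_pattern(cfg, rng=rng)
        pattern.meta["position_mm"] = (float(row["x_mm"]), float(row["y_mm"]))
        return pattern

    def __iter__(self) -> Iterator[tuple[tuple[float, float], ScatteringPattern]]:
        for i in range(self.n_points):
            p = self.pattern_at(i)
            yield p.meta["position_mm"], p


def _band_weight(x_mm: np.ndarray, y_mm: np.ndarray, period: float, axis_deg: float) -> np.ndarray:
    """Raised-cosine band profile in [0, 1]; 1 at band centers."""
    a = np.deg2rad(axis_deg)
    s = x_mm * np.cos(a) + y_mm * np.sin(a)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * s / period))


def simulate_scan(scan_cfg: ScanSimConfig, saxs_cfg: SaxsSimConfig) -> ScanSimulation:
    """Build a raster scan whose per-point ring parameters follow the bands.

    Peak amplitude is modulated as ``1 + band_contrast*cos`` about the base
    amplitude; the orientation concentration ramps from 0 (between bands) to
    the kappa matching ``of_in_band`` (band centers); the ring width ramps
    between 2*pi/xi_out_band and 2*pi/xi_in_band.  ``truth`` carries per
    point: position, band weight, in-band flag, amplitude, kappa, delta_q
    and the quadrature orientation factor ``of_true``.
    """
    scan_cfg.validate()
    saxs_cfg.validate()
    ix, iy = np.meshgrid(np.arange(scan_cfg.nx), np.arange(scan_cfg.ny))
    x = ix.ravel() * scan_cfg.step
    y = iy.ravel() * scan_cfg.step
    w = _band_weight(x, y, scan_cfg.band_period, scan_cfg.band_axis)

    amp = saxs_cfg.peak_amplitude * (1.0 + scan_cfg.band_contrast * (2.0 * w - 1.0))
    kappa_in = kappa_for_of(scan_cfg.of_in_band)
    kappa = kappa_in * w
    dq_in = 2.0 * np.pi / scan_cfg.xi_in_band
    dq_out = 2.0 * np.pi / scan_cfg.xi_out_band
    delta_q = dq_out + (dq_in - dq_out) * w

    # map kappa -> OF once on a grid; per-point quadrature would be wasteful
    kgrid = np.linspace(0.0, max(kappa_in, 1e-6), 64)
    ofgrid = np.array([of_from_kappa(k, n=4001) for k in kgrid])
    of_true = np.interp(kappa, kgrid, ofgrid)

    truth = pd.DataFrame(
        {
            "x_mm": x,
            "y_mm": y,
            "band_weight": w,
            "in_band": w >= 0.5,
            "amplitude": amp,
            "kappa": kappa,
            "delta_q": delta_q,
            "of_true": of_true,
        }
    )
    seeds = np.random.SeedSequence(scan_cfg.seed).generate_state(len(truth)) % (2**31)
    return ScanSimulation(
        scan_cfg=scan_cfg,
        saxs_cfg=saxs_cfg,
        positions=np.column_stack([x, y]),
        truth=truth,
        _seeds=seeds,
    )


def simulate_band_map(
    scan_cfg: ScanSimConfig,
    base_counts: float = 1000.0,
    noise: bool = True,
) -> np.ndarray:
    """Synthesize just the per-point ring-intensity map of a banded scan.

    Expected counts are ``base_counts`` modulated sinusoidally by the band
    profile (contrast ``scan_cfg.band_contrast``); Poisson-sampled when
    ``noise`` is set.  Shape (ny, nx), x along columns.
    """
    scan_cfg.validate()
    ix, iy = np.meshgrid(np.arange(scan_cfg.nx), np.arange(scan_cfg.ny))
    w = _band_weight(ix * scan_cfg.step, iy * scan_cfg.step,
                     scan_cfg.band_period, scan_cfg.band_axis)
    expected = base_counts * (1.0 + scan_cfg.band_contrast * (2.0 * w - 1.0))
    if not noise:
        return expected
    rng = np.random.default_rng(scan_cfg.seed)
    return rng.poisson(expected).astype(float)


# --------------------------------------------------------------------------
# bright-field micrograph

def simulate_micrograph(cfg: MicrographSimConfig) -> Micrograph:
    """Render a synthetic bright-field micrograph.

    Light background with sinusoidal dark-band shading of the configured
    period, dark elongated platelets (rotated rectangles) whose orientations
    are drawn from an axial von Mises law about ``band_axis``, Gaussian
    blur, additive Gaussian noise, and clamping to the 0-255 gray range.
    Platelet placement and pixel noise use independent derived streams so
    one does not perturb the other.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_platelets, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    cols, rows = np.meshgrid(np.arange(cfg.width), np.arange(cfg.height))
    x_um = cols * cfg.pixel_size
    y_um = rows * cfg.pixel_size
    a = np.deg2rad(cfg.band_axis)
    s = x_um * np.cos(a) + y_um * np.sin(a)
    img = cfg.base_gray * (1.0 - 0.5 * cfg.band_contrast * (1.0 + np.cos(2.0 * np.pi * s / cfg.band_period)))

    for _ in range(cfg.n_platelets):
        cx = rng_platelets.uniform(0, cfg.width)
        cy = rng_platelets.uniform(0, cfg.height)
        # doubling the angle makes the circular von Mises axial (180-deg period)
        theta = np.deg2rad(cfg.band_axis) + 0.5 * rng_platelets.vonmises(0.0, cfg.kappa) \
            if cfg.kappa > 0 else rng_platelets.uniform(0, np.pi)
        length = max(rng_platelets.normal(*cfg.platelet_length), cfg.pixel_size) / cfg.pixel_size
        width = max(rng_platelets.normal(*cfg.platelet_width), cfg.pixel_size) / cfg.pixel_size
        _stamp_rectangle(img, cx, cy, length, width, theta, cfg.platelet_gray)

    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma)
    if cfg.noise_sigma > 0:
        img = img + rng_noise.normal(0.0, cfg.noise_sigma, img.shape)
    return Micrograph(pixels=np.clip(img, 0.0, 255.0), pixel_size=cfg.pixel_size)


def _stamp_rectangle(img: np.ndarray, cx: float, cy: float, length: float,
                     width: float, theta: float, gray: float) -> None:
    """Paint a rotated length x width rectangle (pixels) centered at (cx, cy)."""
    h, w = img.shape
    half = int(np.ceil(0.5 * np.hypot(length, width))) + 1
    r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    dx = cc - cx
    dy = rr - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)     # along the long axis
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (np.abs(u) <= length / 2.0) & (np.abs(v) <= width / 2.0)
    region = img[r0:r1, c0:c1]
    region[inside] = gray
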