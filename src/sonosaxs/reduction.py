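"""Reduction of 2D scattering patterns to scalar structural descriptors.

A scanning-SAXS experiment yields, at every raster point, a detector image
already remapped to a regular (q, chi) grid: ``q`` is the magnitude of the
scattering vector (A^-1) and ``chi`` the azimuthal angle around the beam
(degrees).  This module reduces one such pattern to

* a radial profile I(q) (azimuthal average) -> lamellar d-spacing from the
  main diffraction peak position (Bragg, d = 2*pi/q_peak), correlation
  length from its width (Scherrer, xi = 2*pi/delta_q), and a low-q
  power-law exponent P with the surface fractal dimension D_s = 6 - |P|;
* an azimuthal profile I(chi) over the Debye-Scherrer ring -> the Hermans
  orientation factor f2 = (3*<cos^2 chi> - 1)/2, where <cos^2 chi> is the
  sin-weighted integral over the quarter circle.

All statistics honour the per-bin validity mask (detector gaps are flagged,
never imputed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ScatteringPattern",
    "RadialProfile",
    "AzimuthalProfile",
    "PeakFit",
    "PowerLawFit",
    "OrientationFactor",
    "radial_average",
    "azimuthal_profile",
    "smooth_azimuthal",
    "fit_main_peak",
    "fit_power_law",
    "hermans_of",
    "scherrer_ratio",
    "percent_change",
    "d_spacing",
    "correlation_length",
    "DEFAULT_Q_BAND",
    "DEFAULT_PEAK_WINDOW",
    "DEFAULT_POWER_LAW_RANGE",
]

TWO_PI = 2.0 * np.pi

#: azimuthal averaging band around the main diffraction ring (A^-1)
DEFAULT_Q_BAND = (0.11, 0.15)
#: window for the Gaussian peak fit (A^-1)
DEFAULT_PEAK_WINDOW = (0.10, 0.16)
#: low-q range for the power-law fit (A^-1)
DEFAULT_POWER_LAW_RANGE = (0.005, 0.05)


class ReductionError(ValueError):
    """Raised when a pattern or profile violates a reduction precondition."""


@dataclass
class ScatteringPattern:
    """One scan point's intensity on a regular (q, chi) grid.

    Parameters
    ----------
    intensity : ndarray, shape (nq, nchi)
        Counts per bin; must be non-negative on valid bins.
    q_grid : ndarray, shape (nq,)
        Scattering-vector magnitudes in A^-1, strictly increasing, positive.
    chi_grid : ndarray, shape (nchi,)
        Azimuthal angles in degrees, strictly increasing, spanning < 360 deg
        plus one step.
    mask : ndarray of bool, shape (nq, nchi), optional
        True marks a valid bin.  Defaults to all-valid.
    meta : dict
        Free-form acquisition metadata (photon energy in keV,
        sample-detector distance in m, scan position in mm, ...).
    """

    intensity: np.ndarray
    q_grid: np.ndarray
    chi_grid: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.chi_grid = np.asarray(self.chi_grid, dtype=float)
        if self.intensity.shape != (self.q_grid.size, self.chi_grid.size):
            raise ReductionError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(nq, nchi) = ({self.q_grid.size}, {self.chi_grid.size})"
            )
        if self.q_grid.size < 2 or np.any(np.diff(self.q_grid) <= 0) or self.q_grid[0] <= 0:
            raise ReductionError("q_grid must be strictly increasing and positive")
        dchi = np.diff(self.chi_grid)
        if self.chi_grid.size < 2 or np.any(dchi <= 0):
            raise ReductionError("chi_grid must be strictly increasing")
        span = self.chi_grid[-1] - self.chi_grid[0]
        if span >= 360.0 + float(np.median(dchi)):
            raise ReductionError("chi_grid spans more than a full circle")
        if self.mask is None:
            self.mask = np.ones_like(self.intensity, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise ReductionError("mask shape does not match intensity")
        if np.any(self.intensity[self.mask] < 0):
            raise ReductionError("negative intensity on valid bins")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity I(q); NaN where a q row is fully masked."""

    q: np.ndarray
    I: np.ndarray
    n_valid: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.n_valid = np.asarray(self.n_valid, dtype=int)
        if not (self.q.shape == self.I.shape == self.n_valid.shape):
            raise ReductionError("RadialProfile arrays must share a shape")


@dataclass
class AzimuthalProfile:
    """Ring intensity I(chi) averaged over a q band; invalid bins masked."""

    chi: np.ndarray
    I: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.chi.shape == self.I.shape == self.mask.shape):
            raise ReductionError("AzimuthalProfile arrays must share a shape")


@dataclass(frozen=True)
class PeakFit:
    """Gaussian + linear-baseline fit of the main diffraction peak.

    ``d`` and ``xi`` are derived properties so the reciprocal identities
    d * q_peak = 2*pi and xi * delta_q = 2*pi hold by construction.
    """

    q_peak: float
    delta_q: float
    amplitude: float
    baseline: tuple[float, float]  # (slope, intercept)
    fit_window: tuple[float, float]
    converged: bool
    message: str = ""

    @property
    def d(self) -> float:
        """Interplanar (lamellar) distance 2*pi/q_peak in Angstrom."""
        return TWO_PI / self.q_peak

    @property
    def xi(self) -> float:
        """Scherrer correlation length 2*pi/delta_q in Angstrom."""
        return TWO_PI / self.delta_q


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of I(q) = B * q**P on a log-log scale."""

    B: float
    P: float
    fit_range: tuple[float, float]
    residual: float
    n_points: int

    @property
    def abs_P(self) -> float:
        return abs(self.P)

    @property
    def D_s(self) -> float:
        """Surface fractal dimension 6 - |P| (meaningful for 3 < |P| < 4)."""
        return 6.0 - self.abs_P


@dataclass(frozen=True)
class OrientationFactor:
    """Hermans orientation factor derived from <cos^2 chi>.

    ``of`` is (3*<cos^2 chi> - 1)/2: -0.5 for alignment perpendicular to the
    director, 0 for isotropy, +1 for parallel alignment.
    """

    cos2_mean: float
    n_valid_bins: int

    @property
    def of(self) -> float:
        return (3.0 * self.cos2_mean - 1.0) / 2.0


def d_spacing(q_peak: float) -> float:
    """Bragg interplanar distance d = 2*pi/q_peak (Angstrom for q in A^-1)."""
    if q_peak <= 0:
        raise ReductionError("q_peak must be positive")
    return TWO_PI / q_peak


def correlation_length(delta_q: float) -> float:
    """Scherrer correlation length xi = 2*pi/delta_q (Angstrom for A^-1)."""
    if delta_q <= 0:
        raise ReductionError("delta_q must be positive")
    return TWO_PI / delta_q


def radial_average(pattern: ScatteringPattern) -> RadialProfile:
    """Average over azimuth chi, valid bins only.

    Rows with no valid bin get I = NaN (flagged via ``n_valid == 0``),
    never a fabricated zero.
    """
    n_valid = pattern.mask.sum(axis=1)
    total = np.where(pattern.mask, pattern.intensity, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
    return RadialProfile(q=pattern.q_grid.copy(), I=mean, n_valid=n_valid)


def azimuthal_profile(
    pattern: ScatteringPattern,
    q_band: tuple[float, float] = DEFAULT_Q_BAND,
) -> AzimuthalProfile:
    """Average over the q band (default 0.11-0.15 A^-1) to get I(chi).

    A chi bin with no valid pixel anywhere in the band is flagged invalid in
    the output mask rather than set to zero.
    """
    lo, hi = q_band
    in_band = (pattern.q_grid >= lo) & (pattern.q_grid <= hi)
    if not in_band.any():
        raise ReductionError(f"q band {q_band} does not overlap the q grid")
    sub_i = pattern.intensity[in_band]
    sub_m = pattern.mask[in_band]
    n = sub_m.sum(axis=0)
    total = np.where(sub_m, sub_i, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return AzimuthalProfile(chi=pattern.chi_grid.copy(), I=mean, mask=n > 0)


def smooth_azimuthal(profile: AzimuthalProfile, kernel_size: int = 30) -> AzimuthalProfile:
    """Circular normalized boxcar smoothing of an azimuthal profile.

    The kernel renormalizes over valid bins only, so masked gaps do not pull
    the smoothed curve toward zero; with an all-valid mask the mean intensity
    is conserved exactly.  ``kernel_size=1`` is the identity.
    """
    if kernel_size < 1:
        raise ReductionError("kernel_size must be >= 1")
    if kernel_size > profile.chi.size:
        raise ReductionError("kernel wider than the profile")
    valid = profile.mask.astype(float)
    filled = np.where(profile.mask, profile.I, 0.0)
    num = ndimage.uniform_filter1d(filled, size=kernel_size, mode="wrap")
    den = ndimage.uniform_filter1d(valid, size=kernel_size, mode="wrap")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, np.nan)
    return AzimuthalProfile(chi=profile.chi.copy(), I=sm, mask=profile.mask & (den > 0))


def _gauss_line(q, amp, mu, sigma, slope, intercept):
    return amp * np.exp(-0.5 * ((q - mu) / sigma) ** 2) + slope * q + intercept


_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fit_main_peak(
    profile: RadialProfile,
    window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
) -> PeakFit:
    """Fit a Gaussian plus linear baseline to the main diffraction peak.

    The peak position gives the d-spacing (d = 2*pi/q_peak) and the fwhm the
    Scherrer correlation length (xi = 2*pi/delta_q).  Initial values come
    from the discrete argmax and the background-subtracted second moment.
    Non-convergence or a peak escaping the window is reported through
    ``converged=False`` with a diagnostic message, not an exception.
    """
    lo, hi = window
    sel = (profile.q >= lo) & (profile.q <= hi) & np.isfinite(profile.I)
    q = profile.q[sel]
    y = profile.I[sel]
    if q.size < 6:
        return PeakFit(np.nan, np.nan, np.nan, (np.nan, np.nan), window, False,
                       "fewer than 6 valid points in fit window")

    # endpoint line as baseline guess
    slope0 = (y[-1] - y[0]) / (q[-1] - q[0])
    icpt0 = y[0] - slope0 * q[0]
    resid = y - (slope0 * q + icpt0)
    k = int(np.argmax(resid))
    amp0 = max(resid[k], np.ptp(y) * 0.1, 1e-12)
    mu0 = q[k]
    w = np.clip(resid, 0.0, None)
    if w.sum() > 0:
        sigma0 = float(np.sqrt(np.sum(w * (q - mu0) ** 2) / w.sum()))
    else:
        sigma0 = (hi - lo) / 10.0
    sigma0 = float(np.clip(sigma0, np.min(np.diff(q)), (hi - lo) / 2.0))

    try:
        popt, _ = optimize.curve_fit(
            _gauss_line, q, y, p0=[amp0, mu0, sigma0, slope0, icpt0], maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        return PeakFit(np.nan, np.nan, np.nan, (np.nan, np.nan), window, False, str(exc))
    amp, mu, sigma, slope, icpt = popt
    sigma = abs(float(sigma))
    fwhm = _FWHM_SIGMA * sigma
    significant = amp > 1e-6 * max(np.max(np.abs(y)), 1e-300)
    ok = lo <= mu <= hi and 0 < fwhm < (hi - lo) and significant
    msg = "" if ok else "peak parameters outside window bounds"
    return PeakFit(
        q_peak=float(mu),
        delta_q=float(fwhm),
        amplitude=float(amp),
        baseline=(float(slope), float(icpt)),
        fit_window=window,
        converged=bool(ok),
        message=msg,
    )


def fit_power_law(
    profile: RadialProfile,
    fit_range: tuple[float, float] = DEFAULT_POWER_LAW_RANGE,
) -> PowerLawFit:
    """Fit I(q) = B*q**P by least squares of log I on log q.

    Non-positive intensities inside the range are excluded with a warning;
    at least five positive points must remain.  The surface fractal
    dimension D_s = 6 - |P| is exposed on the result.
    """
    lo, hi = fit_range
    sel = (profile.q >= lo) & (profile.q <= hi) & np.isfinite(profile.I)
    q = profile.q[sel]
    y = profile.I[sel]
    pos = y > 0
    if (~pos).any():
        warnings.warn(
            f"excluding {int((~pos).sum())} non-positive intensities from power-law fit",
            stacklevel=2,
        )
    q, y = q[pos], y[pos]
    if q.size < 5:
        raise ReductionError("fewer than 5 positive points in power-law range")
    slope, intercept = np.polyfit(np.log(q), np.log(y), 1)
    pred = slope * np.log(q) + intercept
    rms = float(np.sqrt(np.mean((np.log(y) - pred) ** 2)))
    return PowerLawFit(
        B=float(np.exp(intercept)),
        P=float(slope),
        fit_range=fit_range,
        residual=rms,
        n_points=int(q.size),
    )


def _fold_quadrant(chi_deg: np.ndarray) -> np.ndarray:
    """Map azimuths onto [0, 90] deg assuming axial (180 deg) symmetry."""
    a = np.mod(chi_deg, 180.0)
    return np.where(a > 90.0, 180.0 - a, a)


def hermans_of(profile: AzimuthalProfile) -> OrientationFactor:
    """Hermans orientation factor from an azimuthal intensity profile.

    The profile is folded onto the quarter circle [0, 90] deg by averaging
    the four axially symmetric bins (chi, 180-chi, 180+chi, 360-chi); masked
    bins are dropped, not interpolated.  Then

        <cos^2 chi> = int I(chi) sin(chi) cos^2(chi) dchi
                      / int I(chi) sin(chi) dchi      over [0, pi/2]

    by trapezoidal quadrature on the folded grid, and
    of = (3*<cos^2 chi> - 1)/2.

    If the sin-weighted denominator vanishes while the profile still carries
    intensity, all of it sits at chi = 0 where the weight is zero; the
    analytic limit of a narrowing peak at 0 gives <cos^2 chi> -> 1, which is
    what is returned (so a delta at 0 deg reports of = +1 and one at 90 deg
    reports of = -0.5, the textbook endpoints).
    """
    valid = profile.mask & np.isfinite(profile.I)
    if valid.sum() < 2:
        raise ReductionError("need at least 2 valid azimuthal bins")
    if np.any(profile.I[valid] < 0):
        raise ReductionError("negative intensities in azimuthal profile")

    folded = np.round(_fold_quadrant(profile.chi[valid]), 9)
    uniq, inv = np.unique(folded, return_inverse=True)
    sums = np.bincount(inv, weights=profile.I[valid])
    counts = np.bincount(inv)
    mean_i = sums / counts
    if uniq.size < 2:
        raise ReductionError("folded profile collapses to a single angle")

    chi_rad = np.deg2rad(uniq)
    sin_w = np.sin(chi_rad)
    cos2 = np.cos(chi_rad) ** 2
    den = np.trapezoid(mean_i * sin_w, chi_rad)
    num = np.trapezoid(mean_i * sin_w * cos2, chi_rad)
    total = np.trapezoid(mean_i, chi_rad)
    if den <= 0:
        if total > 0:
            # all intensity at the sin-weight zero (chi = 0): analytic limit
            cos2_mean = 1.0
        else:
            raise ReductionError("azimuthal profile carries no intensity")
    else:
        cos2_mean = float(num / den)
    return OrientationFactor(cos2_mean=cos2_mean, n_valid_bins=int(valid.sum()))


def scherrer_ratio(delta_q_a: float, delta_q_b: float) -> float:
    """Percent change of correlation length implied by two peak widths.

    Because xi = 2*pi/delta_q, the ratio of correlation lengths is the
    inverse ratio of widths: returns 100*(delta_q_a/delta_q_b - 1), i.e. the
    percent increase of xi_b relative to xi_a, independent of units.
    """
    if delta_q_a <= 0 or delta_q_b <= 0:
        raise ReductionError("peak widths must be positive")
    return 100.0 * (delta_q_a / delta_q_b - 1.0)


def percent_change(value: float, reference: float) -> float:
    """100*(value/reference - 1); the reporting layer rounds to integer %."""
    if reference == 0:
        raise ReductionError("reference must be nonzero")
    return 100.0 * (value / reference - 1.0)
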