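# Methods

`sonosaxs` quantifies how low-intensity ultrasound standing waves (USW)
restructure monoglyceride (MG) oleogels, from two complementary data
modalities: scanning small-angle X-ray scattering (SAXS) and bright-field
microscopy. This note records the models, the defaults and their rationale,
the numerical choices, and the known limitations.

## Scattering reduction

Each raster point contributes a 2D pattern on a regular (q, χ) grid, q in
Å⁻¹ and χ in degrees, as produced upstream by detector-image reduction.
Per-bin validity masks mark detector gaps; masked bins are excluded from
every statistic and never imputed.

**Radial profile and peak analysis.** I(q) is the mean over valid χ bins per
q row. The main lamellar reflection near q = 0.13 Å⁻¹ is fit with a single
Gaussian plus a linear baseline inside a window (default 0.10–0.16 Å⁻¹);
initial values come from the discrete argmax and the background-subtracted
second moment, and fwhm = 2√(2 ln 2)·σ. From the fit:

* d-spacing d = 2π/q_peak (Bragg) — lamellar repeat distance;
* correlation length ξ = 2π/Δq (Scherrer, uncorrected for instrument
  resolution) — coherently ordered platelet thickness.

Both are derived properties of the fit object, so the reciprocal identities
d·q_peak = 2π and ξ·Δq = 2π hold by construction. A fit whose peak escapes
the window, whose width reaches the window size, or whose amplitude is not
significant relative to the data is flagged `converged=False` with a
diagnostic, never silently accepted. Because the peak widths in this system
(~0.004 Å⁻¹) are far above the beamline resolution, no deconvolution is
applied; ξ is a lower bound on true platelet thickness.

**Power-law (Porod) analysis.** In the low-q region the intensity follows
I(q) = B·qᴾ; we fit log I against log q by ordinary least squares over
0.005–0.05 Å⁻¹ by default (the range is a configuration knob — the low-q
window is sometimes quoted as ending at 0.04 Å⁻¹, and the choice is left
explicit rather than hidden). Non-positive intensities are excluded with a
warning; at least five positive points are required. The surface fractal
dimension is D_s = 6 − |P|, meaningful for 3 < |P| < 4 (D_s → 2 means
smooth interfaces).

**Hermans orientation factor.** The azimuthal profile I(χ) is the mean over
the ring band q ∈ 0.11–0.15 Å⁻¹. The orientation factor is

    f₂ = (3⟨cos²χ⟩ − 1)/2,
    ⟨cos²χ⟩ = ∫₀^{π/2} I(χ) sin χ cos²χ dχ / ∫₀^{π/2} I(χ) sin χ dχ,

with the director at 0° = the horizontal scan axis. f₂ is −0.5 for
orientation perpendicular to the director, 0 for isotropy, +1 for parallel.
Numerical choices:

* *Folding.* The integral is stated on a quarter circle but data span
  360°. Platelet orientation is an axis, not a vector, so the four
  symmetric bins χ, 180°−χ, 180°+χ, 360°−χ are averaged (valid bins only)
  onto [0°, 90°]. This makes the integral well-defined on full-circle data
  and makes f₂ exactly invariant under a 180° rotation of the profile.
* *Quadrature.* Trapezoid on the (possibly non-uniform) folded grid;
  masked bins are dropped, not interpolated — no intensity is invented
  inside detector gaps.
* *The χ = 0 limit.* The sin χ weight vanishes at 0, so a profile entirely
  concentrated in the 0° bin makes both integrals zero. The analytic limit
  of a peak narrowing onto 0° is ⟨cos²χ⟩ → 1, and that limit is returned,
  so the endpoint values (+1 parallel, −0.5 perpendicular, 0 isotropic)
  are all reproduced exactly.
* *Smoothing.* The kernel-size-30 circular boxcar (normalized over valid
  bins, so gaps do not drag the curve down) exists to make profiles
  readable; it is **not** applied before f₂ by default, since the integral
  needs no smoothing — a configuration flag enables it.

The Hermans construction assumes uniaxial orientation; in these gels that
holds only approximately, so f₂ should be read as an orientation estimate,
not an exact order parameter.

## Scan mapping and band detection

Per-point results are arranged on the rectangular raster grid (default
101×101 at 20 μm step, the sonicated-sample geometry); off-grid or
duplicate positions are errors, failed fits become NaN with a validity
flag. Nodal-band spacing is estimated from a map (usually ring intensity)
by:

1. collapsing the map to a 1D profile along each candidate band-normal
   axis (default {0°, 90°}, since the USW bands are axis-aligned; a full
   angular search by image rotation is available);
2. choosing the axis with the highest spectral contrast of the
   mean-subtracted profile;
3. taking the lag of the first non-zero-lag maximum of the profile's
   unbiased autocorrelation, times the grid step.

Autocorrelation rather than an FFT-bin readout: a 0.3 mm spacing is exactly
15 steps of the 20 μm grid, but 2 mm of window holds a non-integer 6.67
periods, so FFT bins could only report 0.33 or 0.29 mm. The estimate is
invariant to intensity scaling and offset; the reported confidence is the
normalized-autocorrelation peak prominence clipped to [0, 1], and estimates
below a confidence threshold are returned with a warning rather than
suppressed. The spacing is inherently quantized to integer grid steps
(noted in the result metadata).

Acoustic geometry helpers: nodal spacing = λ/2 (0.65 mm at 2.25 MHz in oil
→ 0.325 mm, matching the observed ~0.3 mm bands) and the piston-source
near-field distance N = D²/(4λ) (D = 50 mm → ≈ 0.96 m, which is why
residual pressure-field inhomogeneity across a thin sample is plausible).
Percent changes (e.g. of ξ between band interiors and exteriors) are
reported rounded to integer percent, the convention for such comparisons.
Note that a ratio of mean widths is not a ratio of mean lengths —
2π/⟨Δq⟩ ≠ ⟨2π/Δq⟩ — so mean-ξ comparisons use per-point ξ averages.

## Micrograph FFT analysis

Five steps: (i) load the grayscale image with its pixel size; (ii) take the
complement (platelets are dark on a light background) and multiply by a
centered circular Gaussian window; (iii) 2D FFT, center-shifted, squared
magnitude normalized to unit total power, frequency axes in μm⁻¹;
(iv) binary annular bandpass on radial frequency, default 0.025–0.25 μm⁻¹
(element sizes 4–40 μm via size = 1/f); (v) polar integration by rounding
each pixel's polar angle to the nearest integer degree and summing —
a partition of the pixels, so total in-band power is conserved exactly.

Choices where the procedure is underdetermined:

* Gaussian window σ = 0.25 × min image dimension (configurable): small
  enough to suppress the edge cross artifact, large enough to keep most of
  the field of view contributing. The window trades the cross for faint
  rings at ~0.3 k μm⁻¹; the low-pass edge of the default band removes them.
* The bandpass is a sharp binary annulus (no taper) and is idempotent.
* Zero-padding is off by default and available as an option.
* Savitzky–Golay smoothing of the angular spectrum uses window 15°, order
  3, circular boundary — gentle enough to preserve genuine lobes.
* Spectra are normalized per image (unit total power before the bandpass)
  so angular profiles are comparable across images.
* Angle convention matches the SAXS director (0° = +x, toward +y). A
  spectral peak at angle φ corresponds to real-space elongation at φ ± 90°.

The anisotropy readout treats orientation as axial: with power-weighted
circular statistics on 2χ, the resultant length is a scale-invariant degree
of anisotropy in [0, 1] and half the resultant argument is the preferred
spectrum angle (mod 180°).

## Synthetic data

The generators define the test conditions; their defaults mirror the study
geometry and are not tuned per test.

**Single pattern.** Expected counts are B·q^P plus a Gaussian ring at
q₀ = 0.1308 Å⁻¹ (default fwhm 0.0045 Å⁻¹) weighted azimuthally by an axial
von Mises factor exp(κ cos 2(χ−χ_pref))/I₀(κ). The weight has unit
circular mean for every κ, so sharpening the orientation conserves ring
counts and leaves the radial profile unchanged — a property the tests
exploit. The von Mises form was chosen for its single concentration
parameter and closed-form normalization; a 180° period encodes that
platelet orientation is an axis. Optional components: a broad Gaussian
shoulder spanning q ≈ 0.04–0.08 Å⁻¹ (emulating a capillary-wall artifact;
off by default), detector-gap masks (10° gaps every 25°), and Poisson
sampling of the expected counts. With noise off every output equals its
closed-form expectation pointwise.

**Raster scan.** 101×101 points at 20 μm step by default. A raised-cosine
band profile of period 0.3 mm modulates, per point: ring amplitude
(contrast 0.5 by default), orientation concentration (from 0 between bands
up to the κ matching a target orientation factor of 0.8 at band centers,
inverted through dense quadrature), and ring width (between 2π/1440 Å⁻¹
and 2π/1770 Å⁻¹, the between-band/in-band correlation lengths of the
sonicated 10 % MG system). Ground-truth parameter maps are returned with
the data; patterns are synthesized lazily from per-point seeds derived
from one `SeedSequence`, so a full scan is reproducible point-by-point
without holding ~10⁴ patterns in memory.

**Micrograph.** Sinusoidal dark-band shading (default period 300 μm) plus
dark elongated platelets (rotated rectangles, lengths ~N(20, 5) μm) with
axial von Mises orientations about the band axis, Gaussian blur, additive
noise, clamped to the 0–255 gray range. The pixel size default of
1 μm/px is a placeholder — the real instrument's scale is not fixed here —
and is exposed in the configuration. Platelet placement and pixel noise
use independent derived random streams, so changing the platelet count
does not perturb the noise field.

What the generators deliberately do *not* emulate: the optical point-spread
function and depth-of-field blur of transmission microscopy, multiple
platelet polymorphs or multi-peak diffraction, instrument resolution
smearing, and spatially correlated detector noise. Passing the recovery
tests therefore demonstrates the correctness of the reduction chain under
the stated forward models, not robustness to every artifact of real
beamline or microscope data.

## Problem sizes and determinism

The full-scale recovery check runs the complete 101×101-point scan at
reduced pattern resolution (128 q-samples over 0.09–0.18 Å⁻¹, 5° azimuthal
bins), which preserves ~5 samples across the ring fwhm — enough for the
Gaussian fit to localize q_peak and Δq to ~10⁻⁵ Å⁻¹ at high counts — while
keeping a whole-scan reduction in the tens of seconds. All randomness
descends from explicit integer seeds; fixed seeds give bit-identical
outputs, including through the CLI.

## Known limitations

* Single-peak model only; polymorph mixtures with overlapping reflections
  would need multi-peak indexing.
* ξ is reported via the literal Scherrer relation with the 2π convention;
  published correlation-length tables in this field are not always
  dimensionally self-consistent with their quoted peak widths, so
  cross-study comparisons should use ratio-based quantities, which are
  unit-independent.
* The band-spacing estimator assumes near-axis-aligned straight bands;
  strongly curved nodal patterns would bias the projection.
* f₂ assumes uniaxial orientation statistics (see above).
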