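# sonosaxs

Quantitative analysis of **ultrasound-standing-wave (USW) structured
oleogels** from scanning small-angle X-ray scattering (SAXS) and
bright-field microscopy.

Edible oils can be structured into gels by crystalline networks of
monoglyceride (MG) platelets. Applying a low-intensity ultrasound standing
wave during crystallization concentrates and orients the platelets in the
nodal planes of the acoustic field, producing periodic bands of denser,
more aligned crystalline material. `sonosaxs` provides the analysis
pipeline to measure that restructuring:

* **SAXS reduction** — from a 2D pattern on a (q, χ) grid: the lamellar
  d-spacing via Bragg's law *d* = 2π/*q*_peak, the platelet correlation
  length via the Scherrer relation ξ = 2π/Δ*q* (Δ*q* = peak fwhm from a
  Gaussian + linear-baseline fit), the low-q power law *I*(*q*) = *B·qᴾ*
  with surface fractal dimension *D*_s = 6 − |*P*|, and the Hermans
  orientation factor *f*₂ = (3⟨cos²χ⟩ − 1)/2 with the sin-weighted
  ⟨cos²χ⟩ integral over the azimuthal ring profile.
* **Scan mapping** — per-point results assembled into intensity / OF / ξ
  maps on the raster grid, autocorrelation-based detection of the nodal
  band spacing and direction, in-band vs out-of-band summaries, and the
  acoustic geometry helpers λ/2 (nodal spacing) and *N* = *D*²/4λ
  (near-field distance).
* **Micrograph FFT analysis** — the five-step 2D-FFT procedure (complement
  + Gaussian window → power spectrum → 0.025–0.25 μm⁻¹ annular bandpass →
  polar integration per degree → Savitzky–Golay smoothing) with a
  circular-statistics anisotropy index and preferred-angle readout.
* **Synthetic data** — generators for single patterns, banded raster scans
  and platelet micrographs with known ground truth, since the raw
  beamline/microscope data of such studies are typically not deposited.

Intended users: soft-matter and food-materials scientists analysing
scanning-SAXS orientation maps or micrograph anisotropy, and anyone needing
a tested reference implementation of these classical reductions.

## Worked example

Simulate a banded raster scan (20 μm step, 0.3 mm band period, Poisson
noise), reduce every pattern, and map the results:

```python
import numpy as np
import sonosaxs as ss
from sonosaxs.pipeline import reduce_scan

saxs = ss.SaxsSimConfig(q_grid=np.linspace(0.09, 0.18, 128),
                        chi_grid=np.arange(0.0, 360.0, 5.0),
                        peak_amplitude=20000.0, background_B=1e-7, noise=True)
scan = ss.ScanSimConfig(nx=41, ny=41, seed=0)

sim = ss.simulate_scan(scan, saxs)
df = reduce_scan(sim)

m = ss.build_maps(df)
est = ss.estimate_band_spacing(m.intensity_map, scan.step)
summary = ss.map_summary(m, sim.truth_map("in_band"))
```

Output printed from this run:

```
median q_peak : 0.1308 A^-1  -> d = 4.8 nm
xi inside bands : 171 nm, outside: 149 nm (+15%)
OF inside bands : 0.74, outside: 0.22
band spacing : 0.300 mm along 0 deg (confidence 1.00)
near-field distance, 50 mm piston at 0.65 mm: 962 mm
```

Reading it: the lamellar reflection sits at 0.1308 Å⁻¹, i.e. a 4.8 nm
bilayer repeat. Correlation lengths and orientation factors are larger
inside the nodal bands — the regional means sit between the configured
between-band and band-center values (149 → 177 nm), since band interiors
average over the raised-cosine band profile. The band spacing is recovered
as exactly 15 grid steps = 0.300 mm, half the 0.65 mm acoustic wavelength,
and the near-field estimate (~1 m) shows why residual pressure-field
structure across a thin sample is plausible.

The same pipeline is scriptable from the shell:

```bash
sonosaxs simulate-scan -c run.yaml --out scan/
sonosaxs reduce -c run.yaml --scan scan/ --out results/results.csv
sonosaxs map -c run.yaml --results results/results.csv \
             --truth scan/truth.csv --out maps/
sonosaxs simulate-micrograph -c run.yaml --out img.tif
sonosaxs micrograph --image img.tif --pixel-size 1.0 --out fft/ --inverse-check
sonosaxs report --results results/results.csv --maps maps/ --out report.md
```

Every run writes its fully resolved configuration next to its outputs, so
any output directory can be regenerated from that file alone.

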