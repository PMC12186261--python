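"""On-disk formats: scan containers, result tables, map grids, micrographs.

A *scan container* is a directory holding one reduced 2D array per raster
point plus the shared axes and a positions table::

    scan/
      q.npy            # (nq,) scattering-vector axis, A^-1
      chi.npy          # (nchi,) azimuthal axis, deg
      mask.npy         # (nq, nchi) shared validity mask (bool)
      positions.csv    # index, x_mm, y_mm
      truth.csv        # optional per-point ground truth (synthetic scans)
      patterns/point_00000.npy ...

Chosen over a monolithic blob for inspectability: any point can be loaded
and eyeballed with numpy alone.  Result tables are CSV with a commented
header block documenting the units of every column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .reduction import ScatteringPattern
from .synthetic import Micrograph, ScanSimulation

__all__ = [
    "ScanContainer",
    "write_scan_container",
    "read_scan_container",
    "write_result_table",
    "read_result_table",
    "write_map_grid",
    "read_map_grid",
    "write_micrograph",
    "read_micrograph",
    "render_heatmap",
]


class ContainerError(ValueError):
    pass


RESULT_UNITS = {
    "x_mm": "mm", "y_mm": "mm",
    "intensity": "counts (mean over the azimuthal q band)",
    "q_peak": "A^-1", "delta_q": "A^-1 (fwhm)",
    "d_A": "Angstrom", "xi_A": "Angstrom",
    "d_nm": "nm", "xi_nm": "nm",
    "of": "dimensionless, [-0.5, 1]", "cos2_mean": "dimensionless",
    "B": "counts * A^P", "P": "dimensionless", "D_s": "dimensionless",
    "converged": "bool",
}


@dataclass
class ScanContainer:
    """Lazy reader over a scan-container directory."""

    path: Path
    positions: pd.DataFrame
    q_grid: np.ndarray
    chi_grid: np.ndarray
    mask: np.ndarray
    truth: pd.DataFrame | None = None

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def pattern_at(self, index: int) -> ScatteringPattern:
        row = self.positions.iloc[index]
        f = self.path / "patterns" / f"point_{int(row['index']):05d}.npy"
        if not f.exists():
            raise ContainerError(f"missing pattern file for point {int(row['index'])}")
        intensity = np.load(f)
        if intensity.shape != (self.q_grid.size, self.chi_grid.size):
            raise ContainerError(
                f"point {int(row['index'])}: array shape {intensity.shape} does not "
                f"match axes (nq={self.q_grid.size}, nchi={self.chi_grid.size}) — "
                "axis ordering corrupted?"
            )
        return ScatteringPattern(
            intensity=intensity,
            q_grid=self.q_grid,
            chi_grid=self.chi_grid,
            mask=self.mask,
            meta={"position_mm": (float(row["x_mm"]), float(row["y_mm"]))},
        )

    def __iter__(self):
        for i in range(self.n_points):
            yield self.pattern_at(i)


def write_scan_container(sim: ScanSimulation, path: str | Path) -> Path:
    """Materialize a simulated scan as a container directory (streaming)."""
    path = Path(path)
    (path / "patterns").mkdir(parents=True, exist_ok=True)
    first = sim.pattern_at(0)
    np.save(path / "q.npy", first.q_grid)
    np.save(path / "chi.npy", first.chi_grid)
    np.save(path / "mask.npy", first.mask)
    pos = pd.DataFrame(
        {"index": np.arange(sim.n_points),
         "x_mm": sim.positions[:, 0], "y_mm": sim.positions[:, 1]}
    )
    pos.to_csv(path / "positions.csv", index=False)
    sim.truth.to_csv(path / "truth.csv", index=False)
    for i in range(sim.n_points):
        p = first if i == 0 else sim.pattern_at(i)
        np.save(path / "patterns" / f"point_{i:05d}.npy", p.intensity)
    return path


def read_scan_container(path: str | Path) -> ScanContainer:
    """Open a container directory, validating axes and positions up front."""
    path = Path(path)
    for name in ("q.npy", "chi.npy", "positions.csv"):
        if not (path / name).exists():
            raise ContainerError(f"not a scan container: missing {name} in {path}")
    q = np.load(path / "q.npy")
    chi = np.load(path / "chi.npy")
    if q.ndim != 1 or chi.ndim != 1:
        raise ContainerError("axis files must be 1D")
    if np.any(np.diff(q) <= 0):
        raise ContainerError("q axis is not strictly increasing")
    mask_file = path / "mask.npy"
    mask = np.load(mask_file).astype(bool) if mask_file.exists() else np.ones((q.size, chi.size), bool)
    if mask.shape != (q.size, chi.size):
        raise ContainerError("mask shape does not match axes")
    positions = pd.read_csv(path / "positions.csv")
    for col in ("index", "x_mm", "y_mm"):
        if col not in positions.columns:
            raise ContainerError(f"positions.csv lacks column {col}")
    truth_file = path / "truth.csv"
    truth = pd.read_csv(truth_file) if truth_file.exists() else None
    return ScanContainer(path=path, positions=positions, q_grid=q,
                         chi_grid=chi, mask=mask, truth=truth)


def write_result_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with a commented unit-header block (lines starting with '#')."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("# per-point scanning-SAXS reduction results\n")
    for col in df.columns:
        buf.write(f"# {col}: {RESULT_UNITS.get(col, 'dimensionless')}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_map_grid(arr: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(arr, dtype=float), delimiter=",")
    return path


def read_map_grid(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_micrograph(img: Micrograph, path: str | Path) -> Path:
    """Write as grayscale TIFF (uint8); pixel size stored in the resolution tag."""
    path = Path(path)
    px = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    # TIFF resolution is pixels per unit; store px/cm from um/px
    ppcm = 1e4 / img.pixel_size
    tifffile.imwrite(path, px, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")
    return path


def read_micrograph(path: str | Path, pixel_size: float) -> Micrograph:
    """Load a TIFF as grayscale float; RGB images are averaged to gray."""
    px = tifffile.imread(path).astype(float)
    if px.ndim == 3:
        px = px.mean(axis=-1)
    return Micrograph(pixels=px, pixel_size=pixel_size)


def render_heatmap(arr: np.ndarray, path: str | Path, cmap: str = "viridis") -> Path:
    """Render a 2D field to an RGB TIFF via a matplotlib colormap."""
    import matplotlib

    path = Path(path)
    a = np.asarray(arr, dtype=float)
    finite = np.isfinite(a)
    lo = np.nanmin(a) if finite.any() else 0.0
    hi = np.nanmax(a) if finite.any() else 1.0
    norm = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    rgba = matplotlib.colormaps[cmap](np.nan_to_num(norm))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[~finite] = 0
    tifffile.imwrite(path, rgb)
    return path
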