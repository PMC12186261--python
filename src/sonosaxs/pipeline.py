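"""Per-point reduction loop: scan container / simulation -> result table."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reduction as red

__all__ = ["ReduceParams", "reduce_pattern", "reduce_scan"]


@dataclass(frozen=True)
class ReduceParams:
    """Knobs of the per-pattern reduction.

    ``smooth_before_of`` applies the kernel-size-30 circular boxcar to the
    azimuthal profile before the orientation factor; off by default — the
    smoothing exists to make profiles readable, and the sin-weighted
    integral does not need it.
    """

    q_band: tuple[float, float] = red.DEFAULT_Q_BAND
    peak_window: tuple[float, float] = red.DEFAULT_PEAK_WINDOW
    power_law_range: tuple[float, float] = red.DEFAULT_POWER_LAW_RANGE
    smooth_kernel: int = 30
    smooth_before_of: bool = False


def reduce_pattern(pattern: red.ScatteringPattern, params: ReduceParams = ReduceParams()) -> dict:
    """Reduce one pattern to a flat record of structural descriptors.

    Always reports the ring-band mean intensity and the orientation factor;
    the peak fit contributes q_peak/delta_q/d/xi (NaN with ``converged``
    False when the fit fails); the power-law fit contributes B/P/D_s only
    when the q grid actually covers its range (scan patterns are often
    acquired around the ring only).
    """
    x, y = pattern.meta.get("position_mm", (np.nan, np.nan))
    rec: dict = {"x_mm": x, "y_mm": y}

    radial = red.radial_average(pattern)
    azim = red.azimuthal_profile(pattern, q_band=params.q_band)
    if params.smooth_before_of and params.smooth_kernel > 1:
        azim = red.smooth_azimuthal(azim, params.smooth_kernel)
    band_vals = azim.I[azim.mask]
    rec["intensity"] = float(np.nanmean(band_vals)) if band_vals.size else np.nan

    peak = red.fit_main_peak(radial, window=params.peak_window)
    rec["q_peak"] = peak.q_peak
    rec["delta_q"] = peak.delta_q
    rec["d_A"] = peak.d if peak.converged else np.nan
    rec["xi_A"] = peak.xi if peak.converged else np.nan
    rec["converged"] = peak.converged

    try:
        of = red.hermans_of(azim)
        rec["of"] = of.of
        rec["cos2_mean"] = of.cos2_mean
    except red.ReductionError:
        rec["of"] = np.nan
        rec["cos2_mean"] = np.nan
        rec["converged"] = False

    lo, hi = params.power_law_range
    covered = np.count_nonzero((pattern.q_grid >= lo) & (pattern.q_grid <= hi)) >= 5
    if covered:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pl = red.fit_power_law(radial, fit_range=params.power_law_range)
            rec["B"] = pl.B
            rec["P"] = pl.P
            rec["D_s"] = pl.D_s
        except red.ReductionError:
            rec["B"] = rec["P"] = rec["D_s"] = np.nan
    else:
        rec["B"] = rec["P"] = rec["D_s"] = np.nan
    return rec


def reduce_scan(patterns, params: ReduceParams = ReduceParams(),
                progress: bool = False) -> pd.DataFrame:
    """Reduce an iterable of patterns (scan container or simulation) to a table."""
    rows = []
    for i, item in enumerate(patterns):
        pattern = item[1] if isinstance(item, tuple) else item
        rows.append(reduce_pattern(pattern, params))
        if progress and (i + 1) % 1000 == 0:
            print(f"  reduced {i + 1} patterns")
    df = pd.DataFrame(rows)
    df["xi"] = df["xi_A"]  # alias used by the mapping stage
    return df
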