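"""Run configuration: strict YAML loading and resolved-config provenance.

A run config collects the stage parameters of the whole pipeline.  Loading
is strict — unknown keys raise, so a typo cannot silently fall back to a
default — and every CLI run writes the fully resolved configuration next to
its outputs, which makes any output directory reconstructible from that
file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .micrograph import BandpassSpec
from .pipeline import ReduceParams
from .synthetic import MicrographSimConfig, SaxsSimConfig, ScanSimConfig

__all__ = ["RunConfig", "FftParams", "MapParams", "load_config", "save_resolved_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FftParams:
    """Micrograph-analysis knobs: bandpass bounds (um^-1), window, smoothing."""

    f_low: float = 0.025
    f_high: float = 0.25
    sigma_frac: float = 0.25
    sg_window: int = 15
    sg_order: int = 3

    @property
    def band(self) -> BandpassSpec:
        return BandpassSpec(self.f_low, self.f_high)


@dataclass(frozen=True)
class MapParams:
    axes: tuple[float, ...] = (0.0, 90.0)
    min_confidence: float = 0.1


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    saxs: SaxsSimConfig = field(default_factory=SaxsSimConfig)
    scan: ScanSimConfig = field(default_factory=ScanSimConfig)
    micrograph: MicrographSimConfig = field(default_factory=MicrographSimConfig)
    reduce: ReduceParams = field(default_factory=ReduceParams)
    map: MapParams = field(default_factory=MapParams)
    fft: FftParams = field(default_factory=FftParams)


_SECTIONS = {
    "saxs": SaxsSimConfig,
    "scan": ScanSimConfig,
    "micrograph": MicrographSimConfig,
    "reduce": ReduceParams,
    "map": MapParams,
    "fft": FftParams,
}

# array-valued fields accepted either as explicit lists or [start, stop, num]
_LINSPACE_FIELDS = {("saxs", "q_grid"), ("saxs", "chi_grid")}


def _build_section(section: str, cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if (section, key) in _LINSPACE_FIELDS:
            value = np.asarray(value, dtype=float)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; missing sections take package defaults.

    ``overrides`` is a flat {'section.key': value} mapping applied on top
    (used for CLI flags).  Unknown sections or keys raise ``ConfigError``.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded

    top_known = {"schema_version", "seed", *_SECTIONS}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {version}")

    sections = {}
    for name, cls in _SECTIONS.items():
        data = dict(raw.get(name, {}) or {})
        for dotted, value in (overrides or {}).items():
            sec, _, key = dotted.partition(".")
            if sec == name and key:
                data[key] = value
        sections[name] = _build_section(name, cls, data)
    seed = (overrides or {}).get("seed", raw.get("seed", 0))
    return RunConfig(schema_version=SCHEMA_VERSION, seed=int(seed), **sections)


def _plain(value):
    if isinstance(value, np.ndarray):
        return [float(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {f.name: _plain(getattr(value, f.name)) for f in dataclasses.fields(value)}
    return value


def save_resolved_config(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved config as YAML next to the run outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(_plain(cfg), sort_keys=False))
    return path
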