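"""Run configuration: a small versioned YAML schema with aggregated,
human-readable validation errors.

CLI flags override file values; every run writes the resolved configuration
next to its outputs so a result can always be traced back to its parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .coupling import DEFAULT_REFRACTIVE_INDEX
from .ensemble import DEFAULT_TEMPERATURE_K
from .rates import DEFAULT_FWHM_ACCEPTOR_EV, DEFAULT_FWHM_DONOR_EV

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_resolved_config"]

SCHEMA_VERSION = 1

MODES = ("two-step", "one-step", "spectra", "overlap", "diagnostics", "synth")


class ConfigError(ValueError):
    """Aggregated configuration schema violations."""


@dataclass
class RunConfig:
    mode: str
    eta: float = DEFAULT_REFRACTIVE_INDEX
    temperature_k: float = DEFAULT_TEMPERATURE_K
    fwhm_donor_ev: float = DEFAULT_FWHM_DONOR_EV
    fwhm_acceptor_ev: float = DEFAULT_FWHM_ACCEPTOR_EV
    shift_ev: float = 0.0
    azimuth_step_deg: float = 1.0
    seed: int = 0
    r_angstrom: float | None = None
    d_donor_angstrom: float | None = None
    d_acceptor_angstrom: float | None = None
    donor_strength_debye: float | None = None
    donor_tilt_deg: float | None = None
    # per-state two-step inputs: list of {label, strength_debye, tilt_deg, overlap_cm}
    states: list[dict] = field(default_factory=list)
    files: dict = field(default_factory=dict)
    output_dir: str = "."
    schema_version: int = SCHEMA_VERSION

    def resolved_r_angstrom(self) -> float:
        if self.r_angstrom is not None:
            return self.r_angstrom
        if self.d_donor_angstrom is not None and self.d_acceptor_angstrom is not None:
            return self.d_donor_angstrom + self.d_acceptor_angstrom
        raise ConfigError("missing key: r_angstrom (or d_donor_angstrom + d_acceptor_angstrom)")


_REQUIRED_BY_MODE = {
    "two-step": ("eta", "donor_strength_debye", "donor_tilt_deg", "states"),
    "one-step": ("eta", "fwhm_donor_ev", "fwhm_acceptor_ev"),
    "spectra": ("fwhm_donor_ev",),
    "overlap": (),
    "diagnostics": (),
    "synth": ("seed",),
}


def _validate(cfg: RunConfig) -> None:
    errors: list[str] = []
    if cfg.mode not in MODES:
        errors.append(f"mode must be one of {MODES}, got {cfg.mode!r}")
    else:
        for key in _REQUIRED_BY_MODE[cfg.mode]:
            value = getattr(cfg, key)
            if value is None or (key == "states" and not value):
                errors.append(f"mode {cfg.mode!r} requires key {key!r}")
    if cfg.eta is not None and cfg.eta < 1:
        errors.append("eta (refractive index) must be >= 1")
    if cfg.temperature_k <= 0:
        errors.append("temperature_k must be positive")
    if cfg.azimuth_step_deg <= 0:
        errors.append("azimuth_step_deg must be positive")
    for i, s in enumerate(cfg.states):
        for k in ("label", "strength_debye", "tilt_deg"):
            if k not in s:
                errors.append(f"states[{i}] missing key {k!r}")
    if cfg.schema_version != SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {cfg.schema_version}")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))


def load_config(path: str | Path | None, mode: str, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides
    (CLI flags); overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    data["mode"] = mode
    for k, v in (overrides or {}).items():
        if v is not None:
            data[k] = v
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    _validate(cfg)
    return cfg


def dump_resolved_config(cfg: RunConfig, output_dir: str | Path) -> Path:
    out = Path(output_dir) / "resolved_config.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return out
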