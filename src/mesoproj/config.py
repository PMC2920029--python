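"""Run configuration: JSON schema, validation, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .model import default_priors
from .sampler import PriorSpec

__all__ = ["RunConfig", "validate_config", "load_config", "write_manifest"]

_KNOWN_KEYS = {
    "person_years", "deaths", "population_future", "out_dir",
    "H", "L", "diagnostic_trend", "rescale_factor", "fit_window",
    "priors", "n_burn", "n_keep", "seed", "tune_rounds", "tune_sweeps",
    "projection_horizon", "projection_draws", "scenario", "target_deaths", "init",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (JSON on disk)."""

    person_years: str | None = None
    deaths: str | None = None
    population_future: str | None = None
    out_dir: str = "mesoproj-out"
    H: float = 1_000_000.0
    L: int = 10
    diagnostic_trend: bool = False
    rescale_factor: float = 1.0 / 0.99
    fit_window: tuple[int, int] = (1968, 2006)
    priors: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_burn: int = 20_000
    n_keep: int = 35_000
    seed: int = 0
    tune_rounds: int = 12
    tune_sweeps: int = 50
    projection_horizon: tuple[int, int] = (1968, 2050)
    projection_draws: int = 500
    scenario: str = "decline"
    target_deaths: float = 34_000.0
    init: str = "auto"  # "auto": profile-grid initialisation; "midpoint": prior midpoints

    def prior_spec(self) -> PriorSpec:
        base = default_priors(self.diagnostic_trend)
        bounds = dict(base.bounds)
        bounds.update({k: tuple(v) for k, v in self.priors.items()})
        return PriorSpec(bounds=bounds, integer=base.integer)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(raw: dict, data_years: tuple[int, int] | None = None) -> tuple[RunConfig | None, list[str]]:
    """Validate a raw config dict; returns (config, errors) with *all* errors.

    ``data_years`` (first, last) enables the cross-check that the fit
    window lies within the data's coverage.
    """
    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown config key: {key!r}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS})

    if cfg.L < 0:
        errors.append("L: lag must be nonnegative")
    if cfg.H <= 0:
        errors.append("H: clearance half-life must be positive")
    if cfg.rescale_factor < 1.0:
        errors.append("rescale_factor: must be >= 1")
    if not cfg.fit_window[0] < cfg.fit_window[1]:
        errors.append("fit_window: start must precede end")
    if cfg.n_burn < 0 or cfg.n_keep < 0:
        errors.append("n_burn/n_keep: must be nonnegative")
    if cfg.scenario not in ("decline", "levelled"):
        errors.append(f"scenario: unknown scenario {cfg.scenario!r}")
    for name, bound in cfg.priors.items():
        if len(bound) != 2 or not bound[0] < bound[1]:
            errors.append(f"priors[{name}]: lower bound must be below upper bound")
    try:
        spec = cfg.prior_spec()
    except ValueError as e:
        errors.append(str(e))
        spec = None
    if spec is not None and "peakyear" in spec.bounds:
        lo, hi = spec.bounds["peakyear"]
        if lo < 1950 or hi > 2000:
            errors.append("priors[peakyear]: support must lie within 1950-2000")
    if not cfg.projection_horizon[0] < cfg.projection_horizon[1]:
        errors.append("projection_horizon: start must precede end")
    if cfg.init not in ("auto", "midpoint"):
        errors.append(f"init: unknown initialisation {cfg.init!r}")
    if data_years is not None:
        lo, hi = data_years
        if cfg.fit_window[0] < lo or cfg.fit_window[1] > hi:
            errors.append(
                f"fit_window: {cfg.fit_window[0]}-{cfg.fit_window[1]} exceeds data "
                f"coverage {lo}-{hi}"
            )
    return (None, errors) if errors else (cfg, errors)


def load_config(path) -> RunConfig:
    raw = json.loads(Path(path).read_text())
    cfg, errors = validate_config(raw)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, stage: str, cfg: RunConfig, inputs: list[str], extra: dict | None = None) -> Path:
    """Record everything needed to regenerate a stage's outputs."""
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {str(p): _checksum(p) for p in inputs if p and Path(p).exists()},
    }
    if extra:
        manifest.update(extra)
    out = Path(out_dir) / f"{stage}-manifest.json"
    out.write_text(json.dumps(manifest, indent=2, default=str))
    return out
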