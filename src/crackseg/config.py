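"""YAML configuration loading, validation and echoing.

One YAML file configures a whole run.  Keys are grouped to mirror the
pipeline::

    transform: {sigma, gamma, scope}
    window:    {L, alpha, H}
    material:  {youngs_modulus, poisson_ratio, max_principal_stress, fracture_energy}
    load:      {patch_radius, ramp_cap, ramp_step, gap_thickness_frac, gap_max,
                look_radius, max_backtracks, backtrack_window}
    sweep:     {N, m, canny_sigma, low_pct, high_pct}
    driver:    {closure_eps, closure_tol, fit_tail, seed_tail, gap_scan, max_windows}

Every key is optional (defaults apply); unknown keys are rejected so that
typos fail loudly; out-of-range values raise errors naming the key and
the admissible range.
"""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .crack_init import SweepConfig
from .fracture import LoadSpec
from .lcpm import LcpmConfig, LcpmConfigError
from .plate_model import MaterialParams


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "transform": {"sigma", "gamma", "scope"},
    "window": {"L", "alpha", "H"},
    "material": {f.name for f in fields(MaterialParams)},
    "load": {f.name for f in fields(LoadSpec)},
    "sweep": {f.name for f in fields(SweepConfig)},
    "driver": {"closure_eps", "closure_tol", "fit_tail", "seed_tail", "gap_scan", "max_windows"},
}


def _check_keys(section: str, given: dict) -> None:
    unknown = set(given) - _SECTIONS[section]
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"allowed: {sorted(_SECTIONS[section])}"
        )


def config_from_dict(raw: dict) -> LcpmConfig:
    """Build a validated LcpmConfig from a nested dict."""
    raw = raw or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s) {sorted(unknown)}; allowed: {sorted(_SECTIONS)}")
    for sec, val in raw.items():
        if not isinstance(val, dict):
            raise ConfigError(f"section '{sec}' must be a mapping")
        _check_keys(sec, val)

    tr = raw.get("transform", {})
    win = raw.get("window", {})
    drv = raw.get("driver", {})
    kw = {}
    if "sigma" in tr:
        kw["sigma"] = float(tr["sigma"])
    if "gamma" in tr:
        kw["gamma"] = float(tr["gamma"])
    if "scope" in tr:
        kw["transform_scope"] = str(tr["scope"])
    if "L" in win:
        kw["L"] = int(win["L"])
    if "alpha" in win:
        kw["alpha"] = float(win["alpha"])
    if "H" in win:
        kw["H"] = float(win["H"])
    for key in _SECTIONS["driver"]:
        if key in drv:
            kw[key] = drv[key]

    try:
        material = MaterialParams(**raw.get("material", {}))
        load = LoadSpec(**raw.get("load", {}))
        sweep = SweepConfig(**raw.get("sweep", {}))
        cfg = LcpmConfig(material=material, load=load, sweep=sweep, **kw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.H < 2:
        raise ConfigError(f"window.H must be >= 2, got {cfg.H}")
    if cfg.sigma <= 0:
        raise ConfigError(f"transform.sigma must be > 0, got {cfg.sigma}")
    if cfg.gamma <= 0:
        raise ConfigError(f"transform.gamma must be > 0, got {cfg.gamma}")
    return cfg


def load_config(path: str | None) -> LcpmConfig:
    """Load a YAML config file; an empty or missing mapping gives defaults."""
    if path is None:
        return LcpmConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return LcpmConfig()
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    try:
        return config_from_dict(raw)
    except LcpmConfigError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(cfg: LcpmConfig) -> dict:
    """Nested-dict echo of the effective configuration (YAML-ready)."""
    return {
        "transform": {"sigma": cfg.sigma, "gamma": cfg.gamma, "scope": cfg.transform_scope},
        "window": {"L": cfg.L, "alpha": cfg.alpha, "H": cfg.H},
        "material": asdict(cfg.material),
        "load": asdict(cfg.load),
        "sweep": asdict(cfg.sweep),
        "driver": {
            "closure_eps": cfg.closure_eps,
            "closure_tol": cfg.closure_tol,
            "fit_tail": cfg.fit_tail,
            "seed_tail": cfg.seed_tail,
            "gap_scan": cfg.gap_scan,
            "max_windows": cfg.max_windows,
        },
    }


def dump_config(cfg: LcpmConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
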