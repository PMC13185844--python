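"""Run configuration: every algorithm constant in one validated file.

A run config is a plain YAML mapping with one section per module plus
globals (seed, output directory, log level).  Unknown sections or keys are
rejected outright — a typo must fail loudly, not silently fall back to a
default — and every run writes its fully-resolved config beside its outputs
so results are reproducible from the artefacts alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "DEFAULTS", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "output_dir": "dipchar_out",
    "log_level": "INFO",
    "mechtest": {
        "g_const": 9.81,
        "k_sigma": 5.0,
        "m_sustain": 5,
        "strain_window": [0.05, 0.10],
        "sweep_fraction": 0.25,  # density sweep span / container height
        "container_height_m": 0.04,
    },
    "stiffseek": {
        "G_min": 1.0,
        "G_max": 255.0,
        "learn_alpha": 0.5,
        "conf_delta": 0.34,
        "conf_min": 0.5,
        "grad_eps": 1.0,
        "prop_gain_lambda": 30.0,
        "sigma0": 5.0,
        "tau": 3.0,
        "explore": True,
        "k_max": 20,
        "eps_tol": 0.03,
        "n_recent": 3,
        "delta_g_min": 0.5,
        "init_mode": "midpoint",
        "init_g": None,
    },
    "grayfield": {
        "background_G0": 30.0,
        "decay_kind": "gaussian",
        "coarse_factor": 4,
    },
    "photosim": {
        "E_sat_Pa": 40e3,
        "hill_n": 4.0,
        "noise_sd_frac": 0.02,
        "I0_max": 1e-5,
    },
    "lsrecon": {
        "sheet_offset_um": 500.0,
        "layer_height_um": 50.0,
        "ssim_win_size": 11,
        "ssim_sigma": 1.5,
        "max_shift_px": 10,
        "n_replicates": 3,
    },
}


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {where} must be a mapping")
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


class RunConfig:
    """Validated, fully-resolved run configuration."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge_strict(DEFAULTS, overrides or {})
        if self.data["schema_version"] != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.data['schema_version']} "
                f"(expected {SCHEMA_VERSION})"
            )

    def __getitem__(self, key):
        return self.data[key]

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        return cls(raw)

    def dump(self, path) -> None:
        """Write the fully-resolved config (for reproducibility)."""
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    def seek_config(self):
        from .stiffseek import SeekConfig

        s = self.data["stiffseek"]
        return SeekConfig(seed=self.data["seed"], **s)
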