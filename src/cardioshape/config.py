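"""Run configuration: one YAML file with full defaulting and strict key checking."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "shapes": {
        "unit": "mm",
    },
    "model": {
        "modes": 50,              # fixed mode count, clamped to available rank
        "variance_fraction": None,  # set to e.g. 0.98 to use the fraction policy
        "gpa_tol": 1e-7,
        "gpa_max_iter": 100,
    },
    "ga": {
        "population_size": 80,
        "generations": 150,
        "crossover_rate": 0.9,
        "mutation_rate": 0.15,
        "mutation_sigma": 0.08,
        "elitism_count": 1,
        "weights": None,          # per-shape weights for strategy 3
    },
    "spline": {
        "order_u": 3,
        "order_v": 3,
        "closed_u": True,
        "pole_caps": True,
        "n_ctrl_u": None,         # default: one control column per landmark column
        "n_ctrl_v": None,
    },
    "fitting": {
        "profile_half_length": 5,   # k: gradient profile is 2k+1 samples
        "search_half_length": 8,    # m: candidate offsets span +-(m-k) voxels
        "max_iter": 50,
        "tol": None,                # mm; default 0.1 voxel
    },
    "volume": {
        "method": "exact",
        "paper_dialect": False,
        "samples": 100_000,         # Monte-Carlo samples
        "slices": 64,               # Simpson slices
    },
}


def _merge(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {prefix + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, prefix=f"{prefix}{key}.")
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated configuration; sections mirror the pipeline stages."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])


def load_config(path=None) -> RunConfig:
    """Read a YAML config, filling defaults; unknown keys are rejected by name."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(_merge(DEFAULT_CONFIG, user))
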