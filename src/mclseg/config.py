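"""Run configuration: defaults, YAML files, and dotted-key overrides.

A run is described by one nested tree with ``synthetic``, ``model``, ``loss``,
``train`` and ``eval`` sections.  Every field has a default; values from a
YAML file override the defaults and command-line ``section.key=value``
overrides beat the file.  The fully resolved tree is written into the run's
output directory so any run can be reproduced from its artifacts.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .losses import LossWeights
from .model import ModelConfig
from .synthetic import SyntheticConfig
from .training import TrainConfig

__all__ = [
    "default_config",
    "load_config",
    "apply_overrides",
    "resolve_config",
    "write_config",
    "build_synthetic_config",
    "build_model_config",
    "build_loss_weights",
    "build_train_config",
]


def default_config() -> dict:
    return {
        "seed": 0,
        "synthetic": {
            "height": 64,
            "width": 64,
            "n_bands": 16,
            "n_scenes": 80,
            "morphology": "mix",
            "tumor_fraction_lo": 0.15,
            "tumor_fraction_hi": 0.45,
            "sigma_pix": 0.08,
            "sigma_band": 0.04,
            "sigma_spec": 0.02,
            "labeled_fraction": 0.10,
            "test_count": 14,
        },
        "model": {
            "in_channels": 6,
            "n_decoders": 3,
            "depth": 4,
            "base_width": 16,
            "noise": [{"mean": 1.0, "std": 1.2}, {"mean": 1.0, "std": 1.5}],
            "noise_mode": "additive",
        },
        "loss": {
            "lambda": 0.5,
            "temperature": 0.5,
            "beta_amplitude": 0.001,
            "beta_shape": 5.0,
            "consistency_mode": "hard",
        },
        "train": {
            "epochs": 100,
            "lr": 0.01,
            "momentum": 0.9,
            "crop_size": 64,
            "max_iterations": None,
            "deterministic": True,
            "val_every": 1,
        },
        "eval": {
            "tile_size": None,
            "overlap": 0.5,
        },
    }


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in extra.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None) -> dict:
    """Defaults merged with an optional YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def apply_overrides(cfg: dict, overrides: list[str]) -> dict:
    """Apply ``section.key=value`` overrides (values parsed as YAML scalars)."""
    cfg = copy.deepcopy(cfg)
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        dotted, _, raw = item.partition("=")
        node = cfg
        keys = dotted.strip().lstrip("-").split(".")
        for key in keys[:-1]:
            if not isinstance(node.get(key), dict):
                raise KeyError(f"unknown config section {key!r} in {dotted!r}")
            node = node[key]
        if keys[-1] not in node:
            raise KeyError(f"unknown config key {dotted!r}")
        node[keys[-1]] = yaml.safe_load(raw)
    return cfg


def resolve_config(
    config_file: str | Path | None,
    overrides: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    cfg = load_config(config_file)
    cfg = apply_overrides(cfg, overrides or [])
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def write_config(cfg: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path


def build_synthetic_config(cfg: dict) -> SyntheticConfig:
    s = cfg["synthetic"]
    return SyntheticConfig(
        height=s["height"],
        width=s["width"],
        n_bands=s["n_bands"],
        n_scenes=s["n_scenes"],
        morphology=s["morphology"],
        tumor_fraction=(s["tumor_fraction_lo"], s["tumor_fraction_hi"]),
        sigma_pix=s["sigma_pix"],
        sigma_band=s["sigma_band"],
        sigma_spec=s["sigma_spec"],
        seed=cfg["seed"],
    )


def build_model_config(cfg: dict) -> ModelConfig:
    m = cfg["model"]
    return ModelConfig(
        in_channels=m["in_channels"],
        n_decoders=m["n_decoders"],
        depth=m["depth"],
        base_width=m["base_width"],
        noise=tuple((p["mean"], p["std"]) for p in m["noise"])[
            : max(m["n_decoders"] - 1, 0)
        ],
        noise_mode=m["noise_mode"],
        seed=cfg["seed"],
    )


def build_loss_weights(cfg: dict) -> LossWeights:
    l = cfg["loss"]
    return LossWeights(
        lam=l["lambda"],
        temperature=l["temperature"],
        beta_amplitude=l["beta_amplitude"],
        beta_shape=l["beta_shape"],
        consistency_mode=l["consistency_mode"],
    )


def build_train_config(cfg: dict) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(
        epochs=t["epochs"],
        lr=t["lr"],
        momentum=t["momentum"],
        crop_size=t["crop_size"],
        max_iterations=t["max_iterations"],
        seed=cfg["seed"],
        deterministic=t["deterministic"],
        val_every=t["val_every"],
    )
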