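"""YAML configuration loading and dataset presets.

Presets carry the tuned hyperparameter sets for the three crop datasets
this model family targets: cotton (``gossypium``), rapeseed (``brassica``)
and durum wheat (``triticum``).  ``synthetic`` mirrors the flagship preset
and is the default for generated data.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .diffusion import DiffusionConfig
from .objectives import LossConfig
from .training import TrainConfig

__all__ = ["PRESETS", "preset", "load_config", "dump_config"]


def _mk(alpha, beta, d, mask, predictor_layers, **extra):
    return TrainConfig(
        d=d,
        mask=mask,
        predictor_layers=predictor_layers,
        loss=LossConfig(tau=0.05, alpha=alpha, beta=beta),
        **extra,
    )


PRESETS = {
    "gossypium": _mk(alpha=0.8, beta=0.01, d=64, mask=0.4, predictor_layers=2),
    "brassica": _mk(alpha=0.2, beta=0.1, d=32, mask=0.8, predictor_layers=1),
    "triticum": _mk(alpha=0.8, beta=0.01, d=64, mask=0.4, predictor_layers=2),
    # calibrated on the synthetic latent-factor benchmark (dense graphs with
    # informative similarity features favour aggressive masking and a larger
    # step size)
    "synthetic": _mk(alpha=0.8, beta=0.01, d=64, mask=0.8, predictor_layers=2,
                     lr=3e-3),
}


def preset(name: str, **overrides) -> TrainConfig:
    """A named preset, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides) if overrides else PRESETS[name]


_TOP_FIELDS = {
    "epochs", "lr", "weight_decay", "seed", "d", "mask", "split_ratio",
    "ablation", "augmentation_strategy", "predictor_layers",
    "output_normalization", "projection_epochs",
}


def load_config(path) -> TrainConfig:
    """Build a TrainConfig from a YAML file.

    Top-level keys mirror TrainConfig fields; nested ``diffusion`` and
    ``loss`` mappings mirror DiffusionConfig and LossConfig.  An optional
    ``preset`` key supplies defaults that explicit keys override.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = preset(raw.pop("preset")) if "preset" in raw else TrainConfig()
    kwargs = {}
    for key in list(raw):
        if key in _TOP_FIELDS:
            kwargs[key] = raw.pop(key)
    if "diffusion" in raw:
        kwargs["diffusion"] = DiffusionConfig(**raw.pop("diffusion"))
    if "loss" in raw:
        kwargs["loss"] = LossConfig(**raw.pop("loss"))
    if raw:
        raise ValueError(f"unknown configuration keys: {sorted(raw)}")
    return replace(base, **kwargs)


def dump_config(cfg: TrainConfig) -> dict:
    """TrainConfig as a plain mapping (for manifests and YAML round-trips)."""
    out = {k: getattr(cfg, k) for k in _TOP_FIELDS}
    out["diffusion"] = {
        "c": cfg.diffusion.c,
        "beta": cfg.diffusion.beta,
        "gamma": cfg.diffusion.gamma,
        "epsilon": cfg.diffusion.epsilon,
        "max_iter": cfg.diffusion.max_iter,
    }
    out["loss"] = {
        "tau": cfg.loss.tau,
        "alpha": cfg.loss.alpha,
        "beta": cfg.loss.beta,
    }
    return out


def save_config(cfg: TrainConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dump_config(cfg), fh, sort_keys=True)
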