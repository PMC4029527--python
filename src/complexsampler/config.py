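"""Configuration files: key = value text (TOML-compatible).

Recognized keys and their defaults:

    temperature     = 1e-9
    iterations      = 2000000
    max_cluster_size = 100
    beta            = 0.01
    gamma           = 2
    sigma2_scale    = 1000
    sigma2_base     = 1.1
    lambda          = 2000
    sigma3_sq       = 1e6
    g2_enabled      = true
    seed            = 0
    hastings_correction = true
"""

from __future__ import annotations

import tomllib
from typing import IO, Any

from .sampler import SamplerConfig
from .scoring import ScoreParams

__all__ = ["load_config", "config_from_dict", "config_to_dict"]

_SCORE_KEYS = {
    "max_cluster_size": "N",
    "gamma": "gamma",
    "sigma2_scale": "sigma2_scale",
    "sigma2_base": "sigma2_base",
    "lambda": "lam",
    "sigma3_sq": "sigma3_sq",
    "g2_enabled": "g2_enabled",
}
_SAMPLER_KEYS = {
    "temperature": "T",
    "iterations": "L",
    "beta": "beta",
    "seed": "seed",
    "hastings_correction": "hastings_correction",
}


def config_from_dict(data: dict[str, Any]) -> SamplerConfig:
    """Build a SamplerConfig from a flat key = value mapping."""
    unknown = set(data) - set(_SCORE_KEYS) - set(_SAMPLER_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    score_kwargs = {attr: data[key] for key, attr in _SCORE_KEYS.items() if key in data}
    sampler_kwargs = {attr: data[key] for key, attr in _SAMPLER_KEYS.items() if key in data}
    if "N" in score_kwargs:
        score_kwargs["N"] = int(score_kwargs["N"])
    if "L" in sampler_kwargs:
        sampler_kwargs["L"] = int(sampler_kwargs["L"])
    if "seed" in sampler_kwargs:
        sampler_kwargs["seed"] = int(sampler_kwargs["seed"])
    return SamplerConfig(score=ScoreParams(**score_kwargs), **sampler_kwargs)


def load_config(stream: IO[bytes] | IO[str]) -> SamplerConfig:
    """Parse a key = value (TOML) config file into a SamplerConfig."""
    raw = stream.read()
    if isinstance(raw, str):
        raw = raw.encode()
    return config_from_dict(tomllib.loads(raw.decode()))


def config_to_dict(config: SamplerConfig) -> dict[str, Any]:
    """Flat mapping of a SamplerConfig, inverse of :func:`config_from_dict`."""
    out: dict[str, Any] = {}
    for key, attr in _SAMPLER_KEYS.items():
        out[key] = getattr(config, attr)
    for key, attr in _SCORE_KEYS.items():
        out[key] = getattr(config.score, attr)
    return out
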