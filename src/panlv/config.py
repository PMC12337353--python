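"""Flat YAML configuration mirroring the simulation parameter names.

A config file holds the :class:`~panlv.stochastic_dynamics.SimParams`
fields plus the genotype-space keys (``L``, ``g``) and interaction-matrix
keys.  Unknown keys are errors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .genotype_space import build_interaction, build_space
from .stochastic_dynamics import SimParams

SPACE_KEYS = {"L", "g"}
INTERACTION_KEYS = {"interaction_mode", "interaction_density", "interaction_seed"}
PARAM_KEYS = {f.name for f in dataclasses.fields(SimParams)}
KNOWN_KEYS = SPACE_KEYS | INTERACTION_KEYS | PARAM_KEYS


def load_config(path: str | Path) -> dict:
    """Read a YAML config file; reject non-mapping documents and unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def setup_from_config(cfg: dict, **overrides):
    """Build ``(space, params, interaction)`` from a config mapping.

    Keyword overrides (e.g. ``seed=...`` from the CLI) replace config
    values; ``L`` is required, ``g`` defaults to 2.
    """
    cfg = {**cfg, **{k: v for k, v in overrides.items() if v is not None}}
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "L" not in cfg:
        raise ValueError("config must set L (gene pool size)")
    space = build_space(int(cfg["L"]), int(cfg.get("g", 2)))
    M = build_interaction(
        space,
        mode=cfg.get("interaction_mode", "matched"),
        density=float(cfg.get("interaction_density", 1.0)),
        seed=cfg.get("interaction_seed"),
    )
    params_kwargs = {k: v for k, v in cfg.items() if k in PARAM_KEYS}
    params = SimParams(**params_kwargs)
    return space, params, M
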