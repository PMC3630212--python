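"""Configuration schema, validation, and reproducibility plumbing.

A configuration is a nested mapping mirroring :func:`default_config`.  YAML
files supply overrides; unknown keys and invalid ranges are collected and
reported together.  The canonical JSON serialization of the merged tree is
hashed so that every report can name the exact configuration that produced
it.
"""

from __future__ import annotations

import hashlib
import json
import math

import numpy as np
import yaml

__all__ = ["default_config", "load_config", "merge_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    """The standard-scale configuration used throughout."""
    return {
        "arm": {
            "link_lengths": [12.0, 20.0],
            "joint_limits": [[0.0, math.pi / 2], [math.pi / 3, 5 * math.pi / 6]],
            "link_1d": 32.0,
            "joint_limits_1d": [math.pi / 6, 5 * math.pi / 6],
        },
        "populations": {
            "units_per_dim": 30,
            "margin_sd": 4.0,
            "fwhm_fraction": 1.0 / 6.0,
        },
        "gains": {"prop": [12.0, 18.0], "vis": [12.0, 18.0]},
        "stimulus_prior": {
            "kind": "uniform-joint",
            # for gaussian-joint: extreme angles are this many prior sd apart
            "sd_separation": 150.0,
        },
        "network": {"n_hidden": None},  # None -> half the visible layer
        "training": {
            "n_vectors": 40_000,
            "minibatch": 40,
            "epochs_per_stage": 15,
            "n_stages": 6,
            "lr_w": 5e-3,
            "lr_b": 5e-3,
            "anneal_factor": 0.8,
            "weight_sd": 0.01,
            "rate_cap_factor": 3.0,
            "neg_hidden": "mean",
            "pos_hidden": "mean",
            "dtype": "float32",
        },
        "testing": {"n_test": 40_000, "n_hidden_samples": 15, "gain_bins": 3},
        "decoupled": {"p_couple": 0.5},
        "discrepancy": {"direction": [1.0, 0.0], "k_sd_list": [2.5, 5.0, 7.5]},
        "hierarchical": {"gain_prop2": [12.0, 18.0], "hidden_count_cap": 15.0,
                         # feed stage 2 the stage-1 mean activity (x n_samples)
                         # or a sampled spike count per unit
                         "stage1_activity": "means"},
        "coordtrans": {
            "units_per_pop": 60,
            "n_hidden": 160,
            # the raised prop gain triples the visible count scale, so this
            # network gets a proportionally smaller rate and a longer schedule
            "lr_w": 2e-3,
            "lr_b": 2e-3,
            "n_stages": 9,
            # X_r and E are sampled independently; X_b = X_r + E must stay
            # inside the image of the 1D joint range (|X_b| <= 32 cos(pi/6))
            "retinal_range": [-13.5, 13.5],
            "eye_range": [-13.5, 13.5],
            "gain_prop": [36.0, 54.0],
            "gain_vis": [12.0, 18.0],
            "gain_eye": [12.0, 18.0],
        },
        "calibrator": {"hidden_units": 32, "use_hidden": True},
    }


def _walk_validate(defaults, override, path, errors, merged):
    for key, val in override.items():
        if key not in defaults:
            errors.append(f"unknown key {'.'.join(path + (key,))!r}")
            continue
        base = defaults[key]
        if isinstance(base, dict):
            if not isinstance(val, dict):
                errors.append(f"{'.'.join(path + (key,))} must be a mapping")
                continue
            _walk_validate(base, val, path + (key,), errors, merged[key])
        else:
            merged[key] = val


def _check_ranges(cfg: dict, errors: list[str]) -> None:
    for name, iv in cfg["gains"].items():
        if not (0 <= iv[0] <= iv[1]):
            errors.append(f"gains.{name}: invalid interval {iv}")
    for name in ("gain_prop", "gain_vis", "gain_eye"):
        iv = cfg["coordtrans"][name]
        if not (0 <= iv[0] <= iv[1]):
            errors.append(f"coordtrans.{name}: invalid interval {iv}")
    if not (0 <= cfg["decoupled"]["p_couple"] <= 1):
        errors.append("decoupled.p_couple must lie in [0, 1]")
    if cfg["populations"]["units_per_dim"] < 2:
        errors.append("populations.units_per_dim must be >= 2")
    tr = cfg["training"]
    for key in ("n_vectors", "minibatch", "epochs_per_stage", "n_stages"):
        if tr[key] <= 0:
            errors.append(f"training.{key} must be positive")
    if not (0 < tr["anneal_factor"] <= 1):
        errors.append("training.anneal_factor must lie in (0, 1]")
    lims = np.asarray(cfg["arm"]["joint_limits"], dtype=float)
    if lims.shape != (2, 2) or np.any(lims[:, 1] <= lims[:, 0]):
        errors.append("arm.joint_limits must be two non-degenerate intervals")


def merge_config(overrides: dict | None = None) -> dict:
    """Validate ``overrides`` against the schema and merge onto the defaults."""
    merged = default_config()
    errors: list[str] = []
    if overrides:
        if not isinstance(overrides, dict):
            raise ConfigError("configuration must be a mapping")
        _walk_validate(default_config(), overrides, (), errors, merged)
    if not errors:
        _check_ranges(merged, errors)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return merged


def load_config(path: str | None) -> dict:
    """Load a YAML configuration file, validate it, and inject defaults."""
    if path is None:
        return merge_config(None)
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return merge_config(overrides)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration tree (independent of key order)."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
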