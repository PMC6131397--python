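"""Pipeline configuration: defaults, YAML loading, validation, seed fanout.

One master seed fans out deterministically to per-stage seeds so a single
knob reproduces a whole run. Unknown configuration keys are rejected.
"""

from __future__ import annotations

import copy

import yaml

from .errors import ConfigurationError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthesize": {
        "enabled": True,
        "n_train_slides": 4,
        "n_mine_slides": 2,
        "n_test_slides": 2,
        "slide_w": 1024,
        "slide_h": 1024,
        "n_sections": 4,
        "follicles_per_section": [5, 15],
        "follicle_diameter": [18, 30],
        "distractors_per_section": [10, 30],
        "noise_sd": 4.0,
        "allow_pairs": False,
        "section_ax_a": [180, 220],
        "section_ax_b": [130, 160],
    },
    "input": {
        "slides_dir": None,
        "train_slides": [],
        "mine_slides": [],
        "test_slides": [],
    },
    "preprocess": {
        "binarize_method": "otsu",
        "fixed_threshold": None,
        "extra_downsample": 4,
        "min_area_frac": 0.005,
        "margin_frac": 0.02,
        "downsample_factor": 1,
    },
    "dataset": {
        "frame_size": 48,
        "neg_pos_ratio": 1.0,
        "min_dist": None,
        "negatives_per_positive": 12,
        "augment": True,
        "n_translations": 4,
        "max_shift_frac": 0.25,
    },
    "model": {
        "preset": "tiny",
    },
    "training": {
        "batch_size": 32,
        "epochs": 12,
        "rho": 0.95,
        "epsilon": 1.0e-6,
    },
    "hnm": {
        "rounds": 1,
        "epochs": 6,
    },
    "detection": {
        "window": 48,
        "overlap_fraction": 0.5,
        "threshold": 0.15,
        "adjacency_rule": "any_overlap",
        "chunk_size": 256,
    },
    "evaluation": {
        "operator_confirmed": 0,
    },
    "output": {
        "save_crops": False,
        "save_corpus": False,
    },
}

# stage indices for deterministic seed fanout
STAGE_SEEDS = {
    "synthesize": 0,
    "negatives": 1,
    "augment": 2,
    "balance": 3,
    "training": 4,
    "hnm": 5,
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults merged with overrides; unknown keys raise ConfigurationError."""
    return _merge(DEFAULT_CONFIG, overrides or {})


def load_config(path) -> dict:
    """Load a YAML configuration file and merge it over the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration file must hold a mapping")
    return resolve_config(data)


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Per-stage seed derived from the master seed, below 2**31."""
    import numpy as np

    if stage not in STAGE_SEEDS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(STAGE_SEEDS[stage], index)
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))
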