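"""Structured run configuration with strict unknown-key rejection.

Silent typos in a threshold-heavy analysis corrupt results, so a config
file may only set keys that exist in the default schema; anything else
is an error listing every offending key.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "fusion": {
        "width_transform": "raw",      # or "log10"
        "ncr_rule": "above_threshold",
        "tss_halfwidth": 1000,
        "min_samples": 5,
        "linkage": "complete",
        "n_starts": 4,
    },
    "bivalency": {
        "tss_halfwidth": 1000,
        "n_starts": 4,
    },
    "landscape": {
        "max_divergence": 0.05,
        "min_variance_fraction": 0.01,
        "center_percentile": 95.0,
        "dc_percentile": 2.0,
        "perplexity": None,            # None -> round(sqrt(n rows))
    },
    "sc": {
        "min_fragments": 300,
        "frip_sd_mult": 2.0,
        "bin_width": 5000,
        "n_components": 30,
        "depth_corr_cutoff": 0.9,
        "umap_neighbors": 15,
        "flank": 2000,
        "target_sum": 10000.0,
        "knn_k": 15,
        "diffusion_t": 3,
        "dispersion_bins": 20,
    },
    "simulate": {
        "n_genes": 600,
        "chrom_length": 40_000_000,
        "n_chroms": 2,
        "fusion": {"n_peaks": 500, "frac_wide": 0.1, "frac_fusion": 0.05,
                   "nc_fold": 4.0, "depth": 25.0, "dispersion": 40.0},
        "bivalency": {"frac_k4": 0.45, "frac_k27": 0.40, "frac_bivalent": 0.20,
                      "effect_fold": 8.0, "depth": 8.0, "dispersion": 10.0},
        "landscape": {"samples_per_lineage": 4, "n_regions": 1500,
                      "frac_shared": 0.2, "frac_lineage_specific": 0.5,
                      "effect_fold": 8.0},
        "sc": {"n_cells": 500, "n_program_genes": 8, "frac_program_a": 0.15,
               "per_cell_depth": 800.0},
    },
}


def _check_keys(user: dict, schema: dict, prefix: str, errors: list[str]) -> None:
    for key, val in user.items():
        path = f"{prefix}{key}"
        if key not in schema:
            errors.append(path)
        elif isinstance(schema[key], dict) and isinstance(val, dict):
            _check_keys(val, schema[key], path + ".", errors)


def _merge(base: dict, user: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def merge_config(user: dict | None) -> dict:
    """Overlay a user config on the defaults, rejecting unknown keys."""
    if not user:
        return copy.deepcopy(DEFAULTS)
    errors: list[str] = []
    _check_keys(user, DEFAULTS, "", errors)
    if errors:
        raise ConfigError("unknown configuration keys: " + ", ".join(sorted(errors)))
    return _merge(DEFAULTS, user)


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file and merge it over the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return merge_config(user)
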