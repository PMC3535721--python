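"""Pipeline configuration: nested defaults, YAML loading, validation."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .features import FeatureSpec
from .reduction import ReducerSpec

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "features": {
        "max_n": 4,
        "block_weights": None,  # uniform 1/max_n
        "seed_boost": False,
        "seed_range": [2, 8],
    },
    "reducer": {
        "method": "isomap",
        "d": 150,
        "k_neighbors": 10,
        "metric": "cityblock",
    },
    "kmeans": {
        "restarts": 20,
        "max_iter": 300,
        "tol": 1e-6,
        "centroid": "median",
    },
    "sweep": {
        "enabled": True,
        "K_list": None,  # explicit K values override the N..2N sweep
    },
    "evaluation": {
        "min_cluster_size": 5,
        "vote_fraction": 1 / 3,
    },
    "paths": {
        "fasta": None,
        "labels": None,  # two-column TSV
        "mifam": None,  # miFam-style flat file (alternative to labels)
        "out_dir": ".",
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def make_config(overrides: Mapping | None = None) -> dict[str, Any]:
    """Defaults merged with overrides; unknown keys are rejected."""
    return _merge(DEFAULTS, overrides or {})


def load_config(path: str | Path, **extra_overrides) -> dict[str, Any]:
    """Load a YAML config file over the defaults."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    cfg = make_config(data)
    return _merge(cfg, extra_overrides) if extra_overrides else cfg


def feature_spec(cfg: Mapping) -> FeatureSpec:
    f = cfg["features"]
    return FeatureSpec(
        max_n=int(f["max_n"]),
        block_weights=tuple(f["block_weights"]) if f["block_weights"] else None,
        seed_boost=bool(f["seed_boost"]),
        seed_range=tuple(f["seed_range"]),
    )


def reducer_spec(cfg: Mapping) -> ReducerSpec:
    r = cfg["reducer"]
    return ReducerSpec(
        method=r["method"],
        d=int(r["d"]),
        k_neighbors=int(r["k_neighbors"]),
        metric=r["metric"],
        random_seed=int(cfg["seed"]),
    )
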