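"""Configuration files for simulation runs.

A run configuration is a single TOML or JSON file with up to four tables:

    [rates]       # RateConstants fields
    [scenario]    # ScenarioConfig fields (S, delta, dispersal_mode, T, ...)
    [landscape]   # V, N, C, matrix_mode, seed, resource_spec fields
    [design]      # fragment_counts, covers, n_replicates, master_seed

Only the keys you want to override need to be present.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from .landscape import ResourceFieldSpec, make_landscape
from .simulator import RateConstants, ScenarioConfig

__all__ = ["load_config", "rates_from_config", "scenario_from_config",
           "landscape_from_config"]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        return tomllib.loads(path.read_text())
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    raise ValueError(f"unsupported config format: {path.suffix!r} (use .toml/.json)")


def rates_from_config(cfg: dict) -> RateConstants:
    return RateConstants(**cfg.get("rates", {}))


def scenario_from_config(cfg: dict) -> ScenarioConfig:
    sc = dict(cfg.get("scenario", {}))
    if "snapshot_times" in sc:
        sc["snapshot_times"] = tuple(sc["snapshot_times"])
    return ScenarioConfig(**sc)


def landscape_from_config(cfg: dict):
    land = dict(cfg.get("landscape", {}))
    spec_kw = land.pop("resource_spec", {})
    if "phases" in spec_kw and spec_kw["phases"] is not None:
        spec_kw["phases"] = tuple(spec_kw["phases"])
    return make_landscape(
        N=land.get("N", 1),
        C=land.get("C", 0.48),
        V=land.get("V", 100.0),
        seed=land.get("seed", 0),
        matrix_mode=land.get("matrix_mode", "habitable"),
        resource_spec=ResourceFieldSpec(**spec_kw) if spec_kw else None,
        radius_sigma=land.get("radius_sigma", 0.0),
    )
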