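"""YAML configuration loading for scenarios and analysis runs.

A scenario config mirrors :class:`dimerdeer.scenarios.ScenarioConfig`::

    preset: invitro            # optional starting point
    binding: {model: gated, load: 0.39, gate_strength: 0.4615}
    # or: binding: {model: independent, p: 0.195}
    geometry:
      sigma: 0.1               # shared sd, or per-pair entries:
      pairs: {a1-b1: [4.1, 0.15], ...}
    labels: {inversion_efficiency: 0.4, spin_survival: 1.0}
    trace: {t_max: 2.0, dt: 0.008, background_rate: 0.05, snr: 50, seed: 1}
    cw: {free_fraction: 0.09, snr: 100, seed: 7}
    n_dimers: 20000

An analysis config accepts labels, geometry, alpha, n_dimers, n_boot,
seed and the consistency/exclusion score thresholds; flags given on the
command line override config keys.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .deer import LabelingModel
from .errors import InvalidConfigError
from .hypotheses import SCORE_CONSISTENT, SCORE_EXCLUDED, SiteGeometry
from .pipeline import AnalysisConfig
from .scenarios import (
    PRESETS,
    CWSettings,
    GatedBinding,
    IndependentBinding,
    ScenarioConfig,
    TraceSettings,
)


def _load(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path}: expected a mapping at top level")
    return data


def geometry_from_dict(data: dict) -> SiteGeometry:
    if "pairs" in data:
        return SiteGeometry({pair: tuple(map(float, ms)) for pair, ms in data["pairs"].items()})
    if "sigma" in data:
        return SiteGeometry.with_sigma(float(data["sigma"]))
    return SiteGeometry()


def _binding_from_dict(data: dict):
    model = data.get("model", "gated")
    if model == "independent":
        return IndependentBinding(float(data["p"]))
    if model == "gated":
        return GatedBinding(float(data["load"]), float(data["gate_strength"]))
    raise InvalidConfigError(f"unknown binding model {model!r}")


def scenario_config_from_dict(data: dict) -> ScenarioConfig:
    base = PRESETS[data["preset"]]() if "preset" in data else None
    kwargs = {}
    if "binding" in data:
        kwargs["binding"] = _binding_from_dict(data["binding"])
    if "geometry" in data:
        kwargs["geometry"] = geometry_from_dict(data["geometry"])
    if "labels" in data:
        kwargs["labels"] = LabelingModel(**data["labels"])
    if "trace" in data:
        kwargs["trace"] = TraceSettings(**data["trace"])
    if "cw" in data:
        kwargs["cw"] = CWSettings(**data["cw"])
    if "n_dimers" in data:
        kwargs["n_dimers"] = int(data["n_dimers"])
    if "population_seed" in data:
        kwargs["population_seed"] = int(data["population_seed"])
    if base is not None:
        return replace(base, **kwargs)
    if "binding" not in kwargs:
        raise InvalidConfigError("scenario config needs a preset or a binding model")
    return ScenarioConfig(**kwargs)


def load_scenario_config(path) -> ScenarioConfig:
    return scenario_config_from_dict(_load(path))


def analysis_config_from_dict(data: dict) -> AnalysisConfig:
    kwargs = {}
    if "labels" in data:
        kwargs["labels"] = LabelingModel(**data["labels"])
    if "geometry" in data:
        kwargs["geometry"] = geometry_from_dict(data["geometry"])
    for key in ("alpha", "n_dimers", "n_boot", "seed"):
        if key in data:
            kwargs[key] = data[key]
    kwargs["consistent_threshold"] = float(data.get("consistent_threshold", SCORE_CONSISTENT))
    kwargs["excluded_threshold"] = float(data.get("excluded_threshold", SCORE_EXCLUDED))
    return AnalysisConfig(**kwargs)


def load_analysis_config(path) -> AnalysisConfig:
    return analysis_config_from_dict(_load(path))
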