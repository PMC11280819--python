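"""YAML configuration loading.

Every stage reads an editable YAML config; defaults ship inside the package
under ``aquarisk/defaults`` and are returned when no path is given.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .exposure_risk import DistributionSpec, ExposureModel, ToxicityRef
from .trophic_state import TrophicConfig
from .wq_index import StandardLimits, WQIConfig

__all__ = [
    "load_yaml",
    "load_wqi_config",
    "load_class3_limits",
    "load_trophic_config",
    "load_exposure_model",
    "load_toxicity",
    "load_geodetector_config",
]


def _default_path(name: str):
    return resources.files("aquarisk").joinpath("defaults", name)


def load_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is None:
        with _default_path(default_name).open("r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_wqi_config(path: str | Path | None = None) -> WQIConfig:
    raw = load_yaml(path, "wqi_config.yaml")
    return WQIConfig(
        k=float(raw["k"]),
        weights=dict(raw["weights"]),
        curves={p: [list(map(float, node)) for node in nodes] for p, nodes in raw["curves"].items()},
        scheme=[(str(label), float(bound)) for label, bound in raw["scheme"]],
    )


def load_class3_limits(path: str | Path | None = None) -> StandardLimits:
    raw = load_yaml(path, "wqi_config.yaml")
    return StandardLimits(limits=dict(raw["class3_limits"]))


def load_trophic_config(path: str | Path | None = None) -> TrophicConfig:
    raw = load_yaml(path, "trophic_config.yaml")
    return TrophicConfig(
        references=dict(raw["references"]),
        weights=raw.get("weights"),
        x_max=float(raw.get("x_max", 100.0)),
        thresholds=tuple(float(t) for t in raw["thresholds"]),
        grades=tuple(raw["grades"]),
    )


def _dist(raw: dict) -> DistributionSpec:
    trunc = raw.get("truncate", [None, None])
    return DistributionSpec(
        family=raw["family"],
        params={k: float(v) for k, v in raw["params"].items()},
        truncate=(trunc[0], trunc[1]),
    )


def load_exposure_model(path: str | Path | None = None) -> ExposureModel:
    raw = load_yaml(path, "exposure.yaml")
    return ExposureModel(
        populations={
            pop: {f: _dist(s) for f, s in specs.items()}
            for pop, specs in raw["populations"].items()
        },
        at_mode=raw.get("at_mode", "derived"),
        lifetime_years=float(raw.get("lifetime_years", 70.0)),
    )


def load_toxicity(path: str | Path | None = None) -> ToxicityRef:
    raw = load_yaml(path, "toxicity.yaml")
    return ToxicityRef(
        sf={m: float(v) for m, v in raw["sf"].items()},
        rfd={m: float(v) for m, v in raw["rfd"].items()},
    )


def load_geodetector_config(path: str | Path | None = None) -> dict:
    raw = load_yaml(path, "geodetector.yaml")
    return {
        "method": raw.get("method", "natural_breaks"),
        "n_classes": int(raw.get("n_classes", 5)),
        "tolerance": float(raw.get("tolerance", 1e-9)),
    }
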