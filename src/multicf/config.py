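"""Problem-configuration files (JSON or YAML).

Schema::

    diseases: [heart_stroke, diabetes]
    features:
      age: {kind: continuous, default_bounds: [0, 100]}
      work_type: {kind: categorical, categories: [Private, ...]}
      gender: {kind: binary, binary_labels: [female, male]}
    membership:
      heart_stroke: [age, ...]
    constraints:
      fixed: {age: 32, gender: male}
      windows: {avg_glucose_level: [90, 110]}
      anchors: {bmi: 20.10}
    optimizer: {population_size: 500, max_generations: 40, seed: 1}
    penalty: {weights: [1, 1], lambda: 1}
    n_cf: 2
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .engine import PenaltyConfig
from .exceptions import ConfigurationError
from .feature_space import (
    CATEGORICAL,
    CONTINUOUS,
    DiseaseFeatureSet,
    FeatureSpec,
    UserConstraints,
)
from .nsga2 import OptimizerConfig


@dataclass
class ProblemConfig:
    """A fully parsed problem configuration."""

    diseases: list[str]
    registry: dict[str, FeatureSpec]
    feature_sets: list[DiseaseFeatureSet]
    constraints: UserConstraints
    optimizer: OptimizerConfig
    penalty: PenaltyConfig
    n_cf: int = 2
    window_fraction: float = 0.10

    def to_dict(self) -> dict:
        features = {}
        for name, spec in self.registry.items():
            entry: dict = {"kind": spec.kind}
            if spec.kind == CONTINUOUS:
                entry["default_bounds"] = [spec.default_lower, spec.default_upper]
            if spec.kind == CATEGORICAL:
                entry["categories"] = list(spec.categories)
            if spec.kind == "binary":
                entry["binary_labels"] = list(spec.binary_labels)
            features[name] = entry
        return {
            "diseases": self.diseases,
            "features": features,
            "membership": {fs.disease: list(fs.features) for fs in self.feature_sets},
            "constraints": {
                "fixed": dict(self.constraints.fixed),
                "windows": {k: list(v) for k, v in self.constraints.windows.items()},
                "anchors": dict(self.constraints.anchor_values),
            },
            "optimizer": {
                "population_size": self.optimizer.population_size,
                "max_generations": self.optimizer.max_generations,
                "crossover_probability": self.optimizer.crossover_probability,
                "mutation_probability": self.optimizer.mutation_probability,
                "sbx_eta": self.optimizer.sbx_eta,
                "mutation_eta": self.optimizer.mutation_eta,
                "tournament_size": self.optimizer.tournament_size,
                "seed": self.optimizer.seed,
            },
            "penalty": {
                "weights": [float(w) for w in self.penalty.resolved_weights],
                "lambda": float(self.penalty.lambda_),
            },
            "n_cf": self.n_cf,
            "window_fraction": self.window_fraction,
        }


def _parse_feature(name: str, entry: Mapping) -> FeatureSpec:
    kind = entry.get("kind")
    if kind == CONTINUOUS:
        lo, hi = entry.get("default_bounds", (None, None))
        if lo is None or hi is None:
            raise ConfigurationError(
                f"continuous feature {name!r} needs default_bounds [lower, upper]"
            )
        return FeatureSpec(name, CONTINUOUS, float(lo), float(hi))
    if kind == "binary":
        labels = tuple(entry.get("binary_labels", ("no", "yes")))
        return FeatureSpec(name, "binary", binary_labels=labels)  # type: ignore[arg-type]
    if kind == CATEGORICAL:
        return FeatureSpec(name, CATEGORICAL, categories=tuple(entry.get("categories", ())))
    raise ConfigurationError(f"feature {name!r}: unknown kind {kind!r}")


def load_problem(path: str | Path, **overrides) -> ProblemConfig:
    """Parse a problem config file; keyword overrides win over file values.

    Recognised overrides: ``population_size``, ``max_generations``, ``seed``,
    ``n_cf``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)

    diseases = list(raw.get("diseases", []))
    if not diseases:
        raise ConfigurationError("config lists no diseases")
    registry = {
        name: _parse_feature(name, entry)
        for name, entry in raw.get("features", {}).items()
    }
    membership = raw.get("membership", {})
    feature_sets = []
    for disease in diseases:
        if disease not in membership:
            raise ConfigurationError(f"no membership entry for disease {disease!r}")
        feature_sets.append(DiseaseFeatureSet(disease, tuple(membership[disease])))

    cons = raw.get("constraints", {}) or {}
    constraints = UserConstraints(
        fixed=dict(cons.get("fixed", {}) or {}),
        windows={k: tuple(v) for k, v in (cons.get("windows", {}) or {}).items()},
        anchor_values=dict(cons.get("anchors", {}) or {}),
    )

    opt = dict(raw.get("optimizer", {}) or {})
    for key in ("population_size", "max_generations", "seed"):
        if overrides.get(key) is not None:
            opt[key] = overrides[key]
    optimizer = OptimizerConfig(**opt)

    pen = raw.get("penalty", {}) or {}
    weights = pen.get("weights")
    penalty_config = PenaltyConfig(
        disease_order=tuple(diseases),
        weights=tuple(weights) if weights is not None else None,
        lambda_=float(pen.get("lambda", 1.0)),
    )

    n_cf = int(overrides.get("n_cf") or raw.get("n_cf", 2))
    return ProblemConfig(
        diseases=diseases,
        registry=registry,
        feature_sets=feature_sets,
        constraints=constraints,
        optimizer=optimizer,
        penalty=penalty_config,
        n_cf=n_cf,
        window_fraction=float(raw.get("window_fraction", 0.10)),
    )


def dump_problem(config: ProblemConfig, path: str | Path) -> None:
    """Write a config back out (YAML unless the suffix is .json)."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
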