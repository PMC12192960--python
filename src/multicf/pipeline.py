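"""End-to-end glue: tables -> trained models -> ranked recommendations.

Thin orchestration over the real modules so library users, the examples and
the CLI all run the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .engine import (
    CounterfactualResult,
    PenaltyConfig,
    pareto_export,
    penalty,
    report,
    select_counterfactuals,
)
from .feature_space import (
    DiseaseFeatureSet,
    FeatureSpec,
    FeatureUnion,
    UserConstraints,
    union_features,
)
from .nsga2 import OptimizerConfig, RunResult, run
from .risk_models import (
    CandidateBuilder,
    MetricReport,
    RiskModel,
    default_candidates,
    split_train_test,
    train_and_select,
)


def train_disease_models(
    tables: Mapping[str, pd.DataFrame],
    feature_sets: Sequence[DiseaseFeatureSet],
    registry: Mapping[str, FeatureSpec],
    candidates: Sequence[CandidateBuilder] | None = None,
    ratio: float = 0.80,
    seed: int = 0,
    oversample: bool = False,
) -> tuple[dict[str, RiskModel], dict[str, list[MetricReport]]]:
    """Train and select one risk model per disease (80:20 split by default).

    The outcome column of each table is assumed to be named after the
    disease. Returns {disease: RiskModel} plus the full per-disease metric
    report tables.
    """
    candidates = candidates or default_candidates()
    schema = {name: spec.kind for name, spec in registry.items()}
    models: dict[str, RiskModel] = {}
    reports: dict[str, list[MetricReport]] = {}
    for fs in feature_sets:
        table = tables[fs.disease]
        train, test = split_train_test(table, ratio=ratio, seed=seed)
        model, reps = train_and_select(
            train,
            test,
            candidates,
            disease=fs.disease,
            outcome=fs.disease,
            schema=schema,
            feature_order=fs.features,
            oversample=oversample,
            seed=seed,
        )
        models[fs.disease] = model
        reports[fs.disease] = reps
    return models, reports


@dataclass
class RecommendationBundle:
    """Everything one recommendation run produces."""

    results: list[CounterfactualResult]
    run_result: RunResult
    table: pd.DataFrame  # feature x CF recommendation table
    pareto: pd.DataFrame  # objective pairs + penalty + best flag


def recommend(
    models: Mapping[str, RiskModel],
    union: FeatureUnion,
    constraints: UserConstraints | None,
    penalty_config: PenaltyConfig,
    optimizer_config: OptimizerConfig,
    n_cf: int = 2,
    window_fraction: float = 0.10,
) -> RecommendationBundle:
    """Run the optimizer and rank its Pareto front into ``n_cf`` results."""
    ordered_models = [models[d] for d in penalty_config.disease_order]
    result = run(
        ordered_models,
        union,
        constraints,
        optimizer_config,
        window_fraction=window_fraction,
        penalty_fn=lambda p: penalty(p, penalty_config),
    )
    results = select_counterfactuals(result.front, n_cf, penalty_config, union)
    table = report(results, union, constraints)
    pareto = pareto_export(result.front, penalty_config)
    return RecommendationBundle(
        results=results, run_result=result, table=table, pareto=pareto
    )
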