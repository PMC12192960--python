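"""Rank the Pareto front into user-facing counterfactual recommendations.

The optimiser returns mutually non-dominated genomes; the engine scalarises
each one with a penalty

    L(x) = sum_i w_i * P_i(x) + lambda * sum_{i<j} max(0, P_i(x) - P_j(x))

(for two diseases: ``w1*P1 + w2*P2 + lambda*max(0, P1 - P2)``, with the
first-listed disease as P1) and presents the lowest-penalty members first.
The positive-gap term penalises solutions that buy one disease's risk down
by letting the first-listed disease's risk exceed the other's — the
asymmetry is deliberate, so ``disease_order`` is a required, explicit field.
The n>2 pairwise-gap generalisation is this package's extension; it reduces
exactly to the two-disease form.

The penalty ranks the final front post hoc; it is not part of the GA's
fitness (the search minimises the raw probability vector). ``run`` accepts
the penalty as an optional extra objective for experimentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_space import (
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    FeatureUnion,
    ResolvedBound,
    UserConstraints,
    decode_genome,
)
from .nsga2 import Individual, dominates

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PenaltyConfig:
    """Weights, gap multiplier and the (ordered) disease list for L(x)."""

    disease_order: tuple[str, ...]
    weights: tuple[float, ...] | None = None
    lambda_: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.weights is not None and len(self.weights) != len(self.disease_order):
            raise ValueError("weights length must equal the number of diseases")

    @property
    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self.disease_order))
        return np.asarray(self.weights, dtype=float)


def penalty(probabilities: Sequence[float], config: PenaltyConfig) -> float:
    """Scalarise a probability vector; lower is better.

    Probabilities are taken in ``config.disease_order``. For two diseases
    this is ``w1*p1 + w2*p2 + lambda*max(0, p1 - p2)``.
    """
    p = np.asarray(probabilities, dtype=float)
    w = config.resolved_weights
    if p.shape != w.shape:
        raise ValueError(
            f"expected {len(w)} probabilities (one per disease), got {len(p)}"
        )
    total = float(np.dot(w, p))
    n = len(p)
    for i in range(n):
        for j in range(i + 1, n):
            total += config.lambda_ * max(0.0, float(p[i] - p[j]))
    return total


@dataclass(frozen=True)
class CounterfactualResult:
    """One ranked recommendation: probabilities, penalty and feature values."""

    index: int  # 1-based CF number after penalty ranking
    probabilities: dict[str, float]
    penalty: float
    recommended_values: dict[str, object]
    crowding: float = float("inf")


def select_counterfactuals(
    front: Sequence[Individual],
    n_cf: int,
    config: PenaltyConfig,
    union: FeatureUnion,
) -> list[CounterfactualResult]:
    """Penalty-rank the front and keep the best ``n_cf`` members.

    Ties on penalty break by descending crowding distance, then by stable
    position in the front. Warns (and returns fewer) when the front is
    smaller than ``n_cf``.
    """
    if n_cf < 1:
        raise ValueError("n_cf must be >= 1")
    if not front:
        raise ValueError("front is empty")
    scored = []
    for pos, member in enumerate(front):
        if member.objectives is None:
            raise RuntimeError("front member is unevaluated")
        pen = penalty(member.objectives, config)
        crowd = member.crowding if member.crowding is not None else float("inf")
        scored.append((pen, -crowd, pos, member))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    if len(front) < n_cf:
        logger.warning(
            "requested %d counterfactuals but the Pareto front has only %d members",
            n_cf,
            len(front),
        )
    results = []
    for number, (pen, _, pos, member) in enumerate(scored[:n_cf], start=1):
        results.append(
            CounterfactualResult(
                index=number,
                probabilities={
                    d: float(member.objectives[i])
                    for i, d in enumerate(config.disease_order)
                },
                penalty=pen,
                recommended_values=decode_genome(union, member.genome),
                crowding=float(member.crowding)
                if member.crowding is not None
                else float("inf"),
            )
        )
    return results


def report(
    results: Sequence[CounterfactualResult],
    union: FeatureUnion,
    constraints: UserConstraints | None = None,
    precision: int = 3,
) -> pd.DataFrame:
    """Recommendation table: one row per union feature, one column per CF.

    Fixed features show their constants; binary and categorical genes render
    as labels; continuous values render at ``precision`` decimals.
    """
    if not results:
        raise ValueError("no results to report")
    constraints = constraints or UserConstraints()
    columns: dict[str, list[str]] = {}
    for res in results:
        col = []
        for spec in union.features:
            value = (
                constraints.fixed[spec.name]
                if spec.name in constraints.fixed
                else res.recommended_values[spec.name]
            )
            if spec.kind == CONTINUOUS:
                col.append(f"{float(spec.encode(value)):.{precision}f}")
            else:
                col.append(str(spec.decode(spec.encode(value))))
        columns[f"CF {res.index}"] = col
    return pd.DataFrame(columns, index=list(union.names))


def pareto_export(
    front: Sequence[Individual],
    config: PenaltyConfig,
) -> pd.DataFrame:
    """Objective-pair table for Pareto-front plots.

    One row per front member: per-disease probability, penalty, and a flag
    marking the minimum-penalty member (the recommended optimum).
    """
    rows = []
    for member in front:
        if member.objectives is None:
            raise RuntimeError("front member is unevaluated")
        row = {
            f"P_{d}": float(member.objectives[i])
            for i, d in enumerate(config.disease_order)
        }
        row["penalty"] = penalty(member.objectives, config)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["is_best"] = False
    df.loc[df["penalty"].idxmin(), "is_best"] = True
    return df


def check_front_nondominated(front: Sequence[Individual]) -> bool:
    """True iff no front member dominates another (sanity re-check)."""
    for a in front:
        for b in front:
            if a is not b and dominates(a.objectives, b.objectives):
                return False
    return True
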