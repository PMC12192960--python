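"""Synthetic multi-disease problems with a known logistic risk surface.

The generator emulates the structure of the stroke/diabetes pair: two
diseases with partially overlapping feature sets (three shared continuous
features), mixed continuous/binary/categorical columns, and binary outcomes
drawn from known logistic ground truths. Because the truth is logistic —
hence monotone and separable per feature after rescaling to [0, 1] — the
box-constrained risk minimiser and the true Pareto front are analytic,
which turns end-to-end optimizer claims into checkable assertions.

Shared features carry identical values across disease tables for the same
synthetic subject: one master table is sampled first and each disease table
is a column projection of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .feature_space import (
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    DiseaseFeatureSet,
    FeatureSpec,
    FeatureUnion,
    ResolvedBound,
    union_features,
)
from .reference import DIABETES, STROKE, default_feature_sets, default_registry

Effect = float | Mapping[str, float]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class LogisticTruth:
    """Ground-truth risk surface for one disease.

    ``effects`` maps each feature of the disease's set to its coefficient:
    a float for continuous (applied to the feature rescaled to [0, 1] over
    its default bounds) and binary features, or a {label: effect} mapping
    for categorical features. Probability = sigmoid(intercept + sum of
    contributions).
    """

    disease: str
    intercept: float
    effects: Mapping[str, Effect]

    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.effects)

    def _contribution(
        self, name: str, values, registry: Mapping[str, FeatureSpec]
    ) -> np.ndarray:
        spec = registry[name]
        eff = self.effects[name]
        if spec.kind == CATEGORICAL:
            assert isinstance(eff, Mapping)
            return np.asarray([float(eff[v]) for v in values])
        beta = float(eff)  # type: ignore[arg-type]
        x = np.asarray(values, dtype=float)
        if spec.kind == CONTINUOUS:
            span = spec.default_upper - spec.default_lower
            x = (x - spec.default_lower) / span if span > 0 else x * 0.0
        return beta * x

    def logit_frame(
        self, table: pd.DataFrame, registry: Mapping[str, FeatureSpec]
    ) -> np.ndarray:
        z = np.full(len(table), self.intercept)
        for name in self.effects:
            z += self._contribution(name, table[name].to_numpy(), registry)
        return z

    def probability_frame(
        self, table: pd.DataFrame, registry: Mapping[str, FeatureSpec]
    ) -> np.ndarray:
        return _sigmoid(self.logit_frame(table, registry))

    def probability(
        self, assignment: Mapping[str, object], registry: Mapping[str, FeatureSpec]
    ) -> float:
        row = pd.DataFrame({k: [assignment[k]] for k in self.effects})
        return float(self.probability_frame(row, registry)[0])


def default_truths() -> dict[str, LogisticTruth]:
    """Epidemiologically plausible default coefficients.

    Age, glucose and BMI raise both risks (so the two optima are
    compatible); disease-specific features carry the remaining signal.
    Intercepts put prevalence near 5% (stroke) and 35% (diabetes), roughly
    matching the public tables.
    """
    stroke = LogisticTruth(
        STROKE,
        intercept=-6.3,
        effects={
            "age": 2.0,
            "hypertension": 0.7,
            "heart_disease": 0.9,
            "avg_glucose_level": 1.2,
            "bmi": 0.8,
            "gender": 0.2,
            "ever_married": 0.1,
            "work_type": {
                "Private": 0.0,
                "Self-employed": 0.2,
                "Govt_job": 0.1,
                "children": -0.5,
                "Never_worked": -0.3,
            },
            "residence_type": 0.05,
            "smoking_status": {
                "never smoked": 0.0,
                "formerly smoked": 0.3,
                "smokes": 0.6,
                "Unknown": 0.1,
            },
        },
    )
    diabetes = LogisticTruth(
        DIABETES,
        intercept=-4.4,
        effects={
            "pregnancies": 0.6,
            "avg_glucose_level": 2.5,
            "blood_pressure": 0.3,
            "skin_thickness": 0.2,
            "insulin": 0.5,
            "bmi": 1.5,
            "diabetes_pedigree": 1.0,
            "age": 1.0,
        },
    )
    return {STROKE: stroke, DIABETES: diabetes}


@dataclass
class SyntheticProblem:
    """A generated multi-disease dataset plus its ground truth."""

    tables: dict[str, pd.DataFrame]
    truths: dict[str, LogisticTruth]
    registry: dict[str, FeatureSpec]
    feature_sets: list[DiseaseFeatureSet]
    union: FeatureUnion
    seed: int
    master: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def diseases(self) -> list[str]:
        return [fs.disease for fs in self.feature_sets]


def generate(
    n_subjects: int = 5000,
    registry: Mapping[str, FeatureSpec] | None = None,
    feature_sets: Sequence[DiseaseFeatureSet] | None = None,
    truths: Mapping[str, LogisticTruth] | None = None,
    seed: int = 0,
    null_fraction: float = 0.0,
) -> SyntheticProblem:
    """Sample a multi-disease problem under a logistic ground truth.

    Continuous features are uniform within default bounds, discrete features
    uniform over their domain; each disease's binary outcome column (named
    after the disease) is Bernoulli under that disease's truth. Set
    ``null_fraction`` > 0 to blank a fraction of the shared ``bmi`` column
    (or the first continuous feature) for imputation testing.
    """
    if n_subjects < 10:
        raise ConfigurationError("n_subjects must be >= 10")
    registry = dict(registry or default_registry())
    feature_sets = list(feature_sets or default_feature_sets())
    truths = dict(truths or default_truths())
    for fs in feature_sets:
        if not fs.features:
            raise ConfigurationError(f"disease {fs.disease!r} has no features")
        if fs.disease not in truths:
            raise ConfigurationError(f"no ground truth for disease {fs.disease!r}")
    union = union_features(feature_sets, registry)
    rng = np.random.default_rng(seed)

    cols: dict[str, object] = {}
    for spec in union.features:
        if spec.kind == CONTINUOUS:
            cols[spec.name] = rng.uniform(
                spec.default_lower, spec.default_upper, size=n_subjects
            )
        elif spec.kind == BINARY:
            cols[spec.name] = rng.integers(0, 2, size=n_subjects)
        else:
            cols[spec.name] = rng.choice(list(spec.categories), size=n_subjects)
    master = pd.DataFrame(cols)

    tables: dict[str, pd.DataFrame] = {}
    for fs in feature_sets:
        probs = truths[fs.disease].probability_frame(master, registry)
        outcome = (rng.random(n_subjects) < probs).astype(int)
        table = master[list(fs.features)].copy()
        table[fs.disease] = outcome
        if null_fraction > 0:
            target = next(
                (f for f in fs.features if registry[f].kind == CONTINUOUS), None
            )
            if target is not None:
                n_null = int(round(null_fraction * n_subjects))
                idx = rng.choice(n_subjects, size=n_null, replace=False)
                table.loc[table.index[idx], target] = np.nan
        tables[fs.disease] = table

    return SyntheticProblem(
        tables=tables,
        truths=truths,
        registry=registry,
        feature_sets=feature_sets,
        union=union,
        seed=seed,
        master=master,
    )


def random_truths(
    registry: Mapping[str, FeatureSpec],
    feature_sets: Sequence[DiseaseFeatureSet],
    seed: int = 0,
    coefficient_range: tuple[float, float] = (-2.0, 2.0),
) -> dict[str, LogisticTruth]:
    """Draw a random logistic truth per disease (coefficients in the given
    range on the [0, 1]-rescaled features, per-label effects for
    categoricals, intercept uniform in [-2, 0])."""
    rng = np.random.default_rng(seed)
    lo, hi = coefficient_range
    truths: dict[str, LogisticTruth] = {}
    for fs in feature_sets:
        effects: dict[str, Effect] = {}
        for name in fs.features:
            spec = registry[name]
            if spec.kind == CATEGORICAL:
                effects[name] = {
                    c: float(rng.uniform(lo / 2, hi / 2)) for c in spec.categories
                }
            else:
                effects[name] = float(rng.uniform(lo, hi))
        truths[fs.disease] = LogisticTruth(
            fs.disease, intercept=float(rng.uniform(-2.0, 0.0)), effects=effects
        )
    return truths


# ---------------------------------------------------------------------------
# analytic oracles


def _minimising_value(
    spec: FeatureSpec, eff: Effect, bound: ResolvedBound
) -> tuple[object, float]:
    """Raw value inside ``bound`` minimising this feature's contribution."""
    if bound.is_fixed:
        g = bound.fixed_value
        if spec.kind == CONTINUOUS:
            value: object = float(g)
        elif spec.kind == BINARY:
            value = int(round(g))
        else:
            value = spec.categories[int(round(g))]
    elif spec.kind == CONTINUOUS:
        beta = float(eff)  # type: ignore[arg-type]
        value = bound.lower if beta >= 0 else bound.upper
    elif spec.kind == BINARY:
        beta = float(eff)  # type: ignore[arg-type]
        value = 0 if beta >= 0 else 1
    else:
        assert isinstance(eff, Mapping)
        value = min(spec.categories, key=lambda c: (float(eff[c]), spec.categories.index(c)))
    contrib = _contribution_of(spec, eff, value)
    return value, contrib


def _contribution_of(spec: FeatureSpec, eff: Effect, value: object) -> float:
    if spec.kind == CATEGORICAL:
        assert isinstance(eff, Mapping)
        return float(eff[value])  # type: ignore[index]
    beta = float(eff)  # type: ignore[arg-type]
    x = float(value)  # type: ignore[arg-type]
    if spec.kind == CONTINUOUS:
        span = spec.default_upper - spec.default_lower
        x = (x - spec.default_lower) / span if span > 0 else 0.0
    return beta * x


def analytic_optimum(
    truth: LogisticTruth,
    registry: Mapping[str, FeatureSpec],
    bounds: Mapping[str, ResolvedBound],
) -> tuple[dict[str, object], float]:
    """Box-constrained minimiser of one disease's true risk.

    Each free continuous/binary feature sits at the bound opposite its
    coefficient sign; free categorical features take their lowest-effect
    label; fixed features sit at their constants. Returns the minimising
    assignment (over the disease's features) and the minimum probability.
    """
    assignment: dict[str, object] = {}
    logit = truth.intercept
    for name, eff in truth.effects.items():
        value, contrib = _minimising_value(registry[name], eff, bounds[name])
        assignment[name] = value
        logit += contrib
    return assignment, float(_sigmoid(logit))


@dataclass(frozen=True)
class ParetoSample:
    """A sampled true Pareto front: objective points and their assignments."""

    diseases: tuple[str, str]
    points: np.ndarray  # (m, 2) true probabilities
    assignments: tuple[dict, ...]


def analytic_pareto(
    truths: Sequence[LogisticTruth],
    registry: Mapping[str, FeatureSpec],
    bounds: Mapping[str, ResolvedBound],
    grid_resolution: int = 33,
) -> ParetoSample:
    """Sample the true Pareto front of a two-disease logistic problem.

    Because each truth is monotone and separable per feature, any feature
    that affects only one disease — or that both diseases prefer moved the
    same way — must sit at its joint minimiser on every Pareto point; only
    genuinely conflicting features are grid-enumerated (``grid_resolution``
    points per conflicting continuous feature, every level of a conflicting
    discrete feature). The candidate set is then brute-force filtered for
    non-domination.
    """
    if len(truths) != 2:
        raise ValueError("analytic_pareto needs exactly two diseases")
    t1, t2 = truths
    names = list(dict.fromkeys(list(t1.effects) + list(t2.effects)))

    base: dict[str, object] = {}
    grids: list[tuple[str, list[object]]] = []
    for name in names:
        spec = registry[name]
        b = bounds[name]
        in1, in2 = name in t1.effects, name in t2.effects
        if b.is_fixed or not (in1 and in2):
            # fixed, or single-disease: its minimiser is unconditionally optimal
            eff = t1.effects.get(name, t2.effects.get(name))
            base[name], _ = _minimising_value(spec, eff, b)
            continue
        v1, _ = _minimising_value(spec, t1.effects[name], b)
        v2, _ = _minimising_value(spec, t2.effects[name], b)
        if v1 == v2:
            base[name] = v1
        elif spec.kind == CONTINUOUS:
            grids.append(
                (name, list(np.linspace(b.lower, b.upper, grid_resolution)))
            )
        elif spec.kind == BINARY:
            grids.append((name, [0, 1]))
        else:
            grids.append((name, list(spec.categories)))

    n_points = int(np.prod([len(g) for _, g in grids])) if grids else 1
    if n_points > 1_000_000:
        raise ValueError(
            f"grid of {n_points} points is too large; coarsen grid_resolution"
        )

    assignments: list[dict] = []
    for combo in product(*[g for _, g in grids]) if grids else [()]:
        a = dict(base)
        for (name, _), value in zip(grids, combo):
            a[name] = value
        assignments.append(a)
    frame = pd.DataFrame(assignments) if assignments[0] else pd.DataFrame(index=[0])
    p1 = t1.probability_frame(frame, registry)
    p2 = t2.probability_frame(frame, registry)
    points = np.column_stack([p1, p2])

    # brute-force non-domination filter (independent of the optimizer's code)
    keep = []
    for i in range(len(points)):
        dominated = False
        for j in range(len(points)):
            if i == j:
                continue
            if (
                points[j, 0] <= points[i, 0]
                and points[j, 1] <= points[i, 1]
                and (points[j, 0] < points[i, 0] or points[j, 1] < points[i, 1])
            ):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return ParetoSample(
        diseases=(t1.disease, t2.disease),
        points=points[keep],
        assignments=tuple(assignments[i] for i in keep),
    )
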