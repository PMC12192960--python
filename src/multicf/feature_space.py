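"""Feature sets, their union, and box-constraint resolution.

Each disease-risk model is trained on its own feature set ``X_i``; the
counterfactual search runs over the union ``X_union`` of all of them so a
single candidate genome can be scored by every model simultaneously. Features
a user cannot change ("infeasible" features such as age or gender) are pinned
to constants; feasible continuous features carry either an explicit window or
a default window of +/-10% around the user's current value, always clipped to
the feature's physiological default bounds.

The genome encoding is label-based: continuous genes are floats, binary genes
are integers in {0, 1}, categorical genes are integer indices into the ordered
category list. One-hot expansion, where a model's preprocessing needs it,
happens inside the model adapter, never in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, ConstraintError

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, BINARY, CATEGORICAL)


@dataclass(frozen=True)
class FeatureSpec:
    """Definition of a single feature: kind, domain and display labels.

    Parameters
    ----------
    name:
        Column name, shared across all disease tables that use the feature.
    kind:
        ``"continuous"``, ``"binary"`` or ``"categorical"``.
    default_lower, default_upper:
        Physiological default bounds (continuous only).
    categories:
        Ordered category labels (categorical only). The genome stores the
        index into this tuple.
    binary_labels:
        Display labels for 0 and 1, used when rendering recommendations
        (e.g. ``("no", "yes")`` or ``("female", "male")``).
    """

    name: str
    kind: str
    default_lower: float = float("nan")
    default_upper: float = float("nan")
    categories: tuple[str, ...] = ()
    binary_labels: tuple[str, str] = ("no", "yes")

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"feature {self.name!r}: unknown kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.kind == CONTINUOUS:
            if not (np.isfinite(self.default_lower) and np.isfinite(self.default_upper)):
                raise ConfigurationError(
                    f"continuous feature {self.name!r} needs finite default bounds"
                )
            if self.default_lower > self.default_upper:
                raise ConfigurationError(
                    f"feature {self.name!r}: default_lower > default_upper"
                )
        if self.kind == CATEGORICAL:
            if not self.categories:
                raise ConfigurationError(
                    f"categorical feature {self.name!r} needs a non-empty category list"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ConfigurationError(
                    f"categorical feature {self.name!r} has duplicate category labels"
                )

    @property
    def n_choices(self) -> int:
        """Size of the discrete domain (2 for binary, |categories| for categorical)."""
        if self.kind == BINARY:
            return 2
        if self.kind == CATEGORICAL:
            return len(self.categories)
        raise TypeError(f"continuous feature {self.name!r} has no discrete domain")

    def encode(self, value) -> float:
        """Map a user-facing value onto its gene value (index for discrete kinds)."""
        if self.kind == CONTINUOUS:
            return float(value)
        if self.kind == BINARY:
            if value in (0, 1, 0.0, 1.0, False, True):
                return float(int(value))
            if value in self.binary_labels:
                return float(self.binary_labels.index(value))
            raise ConstraintError(
                f"feature {self.name!r}: {value!r} is not a valid binary value "
                f"(expected 0/1 or one of {self.binary_labels})"
            )
        if value in self.categories:
            return float(self.categories.index(value))
        if isinstance(value, (int, np.integer)) and 0 <= value < len(self.categories):
            return float(value)
        raise ConstraintError(
            f"feature {self.name!r}: {value!r} is not among categories {self.categories}"
        )

    def decode(self, gene: float):
        """Map a gene value back to the user-facing value (label for discrete kinds)."""
        if self.kind == CONTINUOUS:
            return float(gene)
        idx = int(round(gene))
        if self.kind == BINARY:
            return self.binary_labels[idx]
        return self.categories[idx]


@dataclass(frozen=True)
class DiseaseFeatureSet:
    """Ordered feature names backing one disease's risk model (its ``X_i``)."""

    disease: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ConfigurationError(
                f"disease {self.disease!r}: duplicate feature names in its feature set"
            )


@dataclass(frozen=True)
class FeatureUnion:
    """The unioned search space: every feature any configured disease uses.

    ``features`` preserves first-appearance order across the configured
    disease list, which fixes the genome layout deterministically.
    ``membership`` maps each disease to the indices of its own features, in
    that disease's declared (training column) order.
    """

    features: tuple[FeatureSpec, ...]
    membership: Mapping[str, tuple[int, ...]]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def k(self) -> int:
        return len(self.features)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in the union") from None

    def spec(self, name: str) -> FeatureSpec:
        return self.features[self.index(name)]

    def disease_features(self, disease: str) -> tuple[str, ...]:
        return tuple(self.features[i].name for i in self.membership[disease])


@dataclass(frozen=True)
class UserConstraints:
    """User-provided immutability constraints and value windows.

    ``fixed`` pins infeasible features to constants (degenerate bounds);
    ``windows`` narrows feasible continuous features to an explicit range;
    ``anchor_values`` seeds the default +/-10% window for continuous
    features the user did not bound explicitly.
    """

    fixed: Mapping[str, object] = field(default_factory=dict)
    windows: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    anchor_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.fixed) & set(self.windows)
        if overlap:
            raise ConstraintError(
                f"features {sorted(overlap)} are both fixed and windowed; pick one"
            )


@dataclass(frozen=True)
class ResolvedBound:
    """Per-feature outcome of constraint resolution.

    For continuous features ``lower``/``upper`` delimit the search interval
    (equal when fixed). For discrete features a free gene ranges over
    ``0 .. n_choices-1``; a fixed gene has ``lower == upper`` at the pinned
    index.
    """

    kind: str
    lower: float
    upper: float
    n_choices: int = 0
    is_fixed: bool = False

    @property
    def fixed_value(self) -> float:
        if not self.is_fixed:
            raise ValueError("bound is not fixed")
        return self.lower


def union_features(
    sets: Sequence[DiseaseFeatureSet],
    registry: Mapping[str, FeatureSpec],
) -> FeatureUnion:
    """Build the de-duplicated union of all disease feature sets.

    Union order is first appearance across ``sets``; membership maps every
    disease to exactly its declared features (in its own order).

    Raises
    ------
    ConfigurationError
        If any feature name is missing from ``registry``.
    """
    order: list[str] = []
    for fs in sets:
        for name in fs.features:
            if name not in registry:
                raise ConfigurationError(
                    f"disease {fs.disease!r} references unknown feature {name!r}"
                )
            if name not in order:
                order.append(name)
    features = tuple(registry[name] for name in order)
    index = {name: i for i, name in enumerate(order)}
    membership = {
        fs.disease: tuple(index[name] for name in fs.features) for fs in sets
    }
    return FeatureUnion(features=features, membership=membership)


def intersect_features(sets: Sequence[DiseaseFeatureSet]) -> list[str]:
    """Feature names common to every set, in the first set's order."""
    if len(sets) < 2:
        raise ValueError("intersection needs at least two disease feature sets")
    common = set(sets[0].features)
    for fs in sets[1:]:
        common &= set(fs.features)
    return [name for name in sets[0].features if name in common]


def resolve_bounds(
    union: FeatureUnion,
    constraints: UserConstraints | None = None,
    window_fraction: float = 0.10,
) -> dict[str, ResolvedBound]:
    """Resolve every feature of the union to its search bounds.

    Priority per feature: fixed constant > explicit window (clipped to
    defaults) > anchor-derived +/-``window_fraction`` window (clipped) >
    default bounds. Discrete features without a fixed value keep their full
    domain.

    Raises
    ------
    ConstraintError
        Window entirely outside the default bounds, or a fixed value outside
        the feature domain.
    TypeError
        Anchor or window supplied for a non-continuous feature.
    """
    constraints = constraints or UserConstraints()
    out: dict[str, ResolvedBound] = {}
    for spec in union.features:
        name = spec.name
        if name in constraints.fixed:
            gene = spec.encode(constraints.fixed[name])
            if spec.kind == CONTINUOUS and not (
                spec.default_lower <= gene <= spec.default_upper
            ):
                raise ConstraintError(
                    f"fixed value {gene} for {name!r} lies outside default bounds "
                    f"[{spec.default_lower}, {spec.default_upper}]"
                )
            n = spec.n_choices if spec.kind != CONTINUOUS else 0
            out[name] = ResolvedBound(spec.kind, gene, gene, n, is_fixed=True)
            continue
        if spec.kind != CONTINUOUS:
            if name in constraints.anchor_values:
                raise TypeError(
                    f"anchor value given for non-continuous feature {name!r}"
                )
            if name in constraints.windows:
                raise TypeError(f"window given for non-continuous feature {name!r}")
            out[name] = ResolvedBound(spec.kind, 0.0, float(spec.n_choices - 1), spec.n_choices)
            continue
        lo, hi = spec.default_lower, spec.default_upper
        if name in constraints.windows:
            wlo, whi = constraints.windows[name]
            if wlo > whi:
                raise ConstraintError(f"window for {name!r} has lower > upper")
            if whi < lo or wlo > hi:
                raise ConstraintError(
                    f"window [{wlo}, {whi}] for {name!r} lies entirely outside "
                    f"default bounds [{lo}, {hi}]"
                )
            lo, hi = max(lo, float(wlo)), min(hi, float(whi))
        elif name in constraints.anchor_values:
            v = float(constraints.anchor_values[name])
            a, b = v * (1.0 - window_fraction), v * (1.0 + window_fraction)
            wlo, whi = min(a, b), max(a, b)  # negative anchors swap the endpoints
            lo, hi = max(lo, wlo), min(hi, whi)
            if lo > hi:
                raise ConstraintError(
                    f"anchor window for {name!r} does not intersect default bounds"
                )
        out[name] = ResolvedBound(CONTINUOUS, lo, hi)
    return out


def project(
    assignment: Mapping[str, object],
    union: FeatureUnion,
    disease: str,
) -> list:
    """Project a full assignment over the union onto one disease's ``X_i``.

    Returns values in that disease's training column order; features outside
    its set have no effect on the result.
    """
    if disease not in union.membership:
        raise KeyError(f"unknown disease {disease!r}")
    missing = [
        union.features[i].name
        for i in union.membership[disease]
        if union.features[i].name not in assignment
    ]
    if missing:
        raise ConfigurationError(
            f"assignment is missing features {missing} required by {disease!r}"
        )
    return [assignment[union.features[i].name] for i in union.membership[disease]]


def decode_genome(union: FeatureUnion, genome: np.ndarray) -> dict[str, object]:
    """Turn a raw gene vector into a user-facing {feature: value} mapping."""
    return {
        spec.name: spec.decode(genome[i]) for i, spec in enumerate(union.features)
    }


def encode_assignment(union: FeatureUnion, assignment: Mapping[str, object]) -> np.ndarray:
    """Inverse of :func:`decode_genome` for a complete assignment."""
    genome = np.empty(union.k, dtype=float)
    for i, spec in enumerate(union.features):
        genome[i] = spec.encode(assignment[spec.name])
    return genome


def genome_to_frame(union: FeatureUnion, genomes: np.ndarray):
    """Decode a (n, k) gene matrix into a table in model-input convention.

    Continuous genes stay floats, binary genes stay 0/1 integers (tables
    store binaries numerically; ``binary_labels`` are display-only), and
    categorical genes become their category labels.
    """
    import pandas as pd

    genomes = np.atleast_2d(genomes)
    cols: dict[str, object] = {}
    for i, spec in enumerate(union.features):
        g = genomes[:, i]
        if spec.kind == CONTINUOUS:
            cols[spec.name] = g.astype(float)
        elif spec.kind == BINARY:
            cols[spec.name] = np.round(g).astype(int)
        else:
            idx = np.round(g).astype(int)
            cols[spec.name] = [spec.categories[j] for j in idx]
    return pd.DataFrame(cols)


def validate_genome(
    union: FeatureUnion,
    bounds: Mapping[str, ResolvedBound],
    genome: np.ndarray,
    atol: float = 1e-9,
) -> bool:
    """True iff every gene lies inside its resolved bounds (fixed genes exact)."""
    for i, spec in enumerate(union.features):
        b = bounds[spec.name]
        g = genome[i]
        if b.is_fixed:
            if abs(g - b.fixed_value) > atol:
                return False
        elif not (b.lower - atol <= g <= b.upper + atol):
            return False
        if spec.kind != CONTINUOUS and abs(g - round(g)) > atol:
            return False
    return True
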