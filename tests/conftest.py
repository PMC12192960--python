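import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import multicf as mc
from multicf.reference import DIABETES, STROKE

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def problem():
    """Moderate-size default synthetic two-disease problem."""
    return mc.generate(2000, seed=7)


@pytest.fixture(scope="session")
def trained(problem):
    """Logistic models per disease, trained once for the whole session."""
    models, reports = mc.train_disease_models(
        problem.tables,
        problem.feature_sets,
        problem.registry,
        candidates=mc.logistic_candidates(),
        seed=7,
    )
    return models, reports


@pytest.fixture(scope="session")
def penalty_config():
    return mc.PenaltyConfig(disease_order=(STROKE, DIABETES))


@pytest.fixture()
def toy_registry():
    return {
        "a": mc.FeatureSpec("a", "continuous", 0.0, 1.0),
        "b": mc.FeatureSpec("b", "continuous", 0.0, 10.0),
        "c": mc.FeatureSpec("c", "binary"),
        "d": mc.FeatureSpec("d", "categorical", categories=("x", "y", "z")),
    }


@pytest.fixture()
def toy_union(toy_registry):
    sets = [
        mc.DiseaseFeatureSet("d1", ("a", "b")),
        mc.DiseaseFeatureSet("d2", ("b", "c", "d")),
    ]
    return mc.union_features(sets, toy_registry), sets
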