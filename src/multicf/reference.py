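"""Reference schema of the public stroke and diabetes (Pima) tables.

The two datasets overlap in exactly three continuous features — age, average
glucose level and BMI — which is what makes single-disease counterfactuals
hazardous (lowering one risk can raise the other) and motivates searching
the 15-feature union instead. These specs mirror the public tables' column
layout and plausible physiological default bounds; the synthetic generator
reuses them as its default problem structure.
"""

from __future__ import annotations

from .feature_space import (
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    DiseaseFeatureSet,
    FeatureSpec,
)

STROKE = "heart_stroke"
DIABETES = "diabetes"

WORK_TYPES = ("Private", "Self-employed", "Govt_job", "children", "Never_worked")
SMOKING_STATUS = ("never smoked", "formerly smoked", "smokes", "Unknown")


def default_registry() -> dict[str, FeatureSpec]:
    """Feature registry for the stroke/diabetes union (15 features)."""
    specs = [
        FeatureSpec("age", CONTINUOUS, 0.0, 100.0),
        FeatureSpec("hypertension", BINARY),
        FeatureSpec("heart_disease", BINARY),
        FeatureSpec("avg_glucose_level", CONTINUOUS, 50.0, 300.0),
        FeatureSpec("bmi", CONTINUOUS, 10.0, 60.0),
        FeatureSpec("gender", BINARY, binary_labels=("female", "male")),
        FeatureSpec("ever_married", BINARY),
        FeatureSpec("work_type", CATEGORICAL, categories=WORK_TYPES),
        FeatureSpec("residence_type", BINARY, binary_labels=("rural", "urban")),
        FeatureSpec("smoking_status", CATEGORICAL, categories=SMOKING_STATUS),
        FeatureSpec("pregnancies", CONTINUOUS, 0.0, 17.0),
        FeatureSpec("blood_pressure", CONTINUOUS, 40.0, 120.0),
        FeatureSpec("skin_thickness", CONTINUOUS, 0.0, 99.0),
        FeatureSpec("insulin", CONTINUOUS, 0.0, 846.0),
        FeatureSpec("diabetes_pedigree", CONTINUOUS, 0.08, 2.5),
    ]
    return {s.name: s for s in specs}


def default_feature_sets() -> list[DiseaseFeatureSet]:
    """Per-disease feature sets: stroke uses 10 features, diabetes 8; the
    shared triple is {age, avg_glucose_level, bmi}."""
    stroke = DiseaseFeatureSet(
        STROKE,
        (
            "age",
            "hypertension",
            "heart_disease",
            "avg_glucose_level",
            "bmi",
            "gender",
            "ever_married",
            "work_type",
            "residence_type",
            "smoking_status",
        ),
    )
    diabetes = DiseaseFeatureSet(
        DIABETES,
        (
            "pregnancies",
            "avg_glucose_level",
            "blood_pressure",
            "skin_thickness",
            "insulin",
            "bmi",
            "diabetes_pedigree",
            "age",
        ),
    )
    return [stroke, diabetes]
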