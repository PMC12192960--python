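"""Build the unioned search space of two overlapping disease feature sets
and resolve user constraints into per-feature search bounds."""

import multicf as mc
from multicf.reference import default_feature_sets, default_registry

registry = default_registry()
sets = default_feature_sets()

union = mc.union_features(sets, registry)
common = mc.intersect_features(sets)
print(f"union size: {union.k} features")
print(f"shared features ({len(common)}): {common}")

# A 32-year-old man who cannot change age/gender/marital status/work type,
# anchors BMI at 20.10 (default +/-10% window) and glucose at 100.
constraints = mc.UserConstraints(
    fixed={"age": 32.0, "gender": "male", "ever_married": "no", "work_type": "Private"},
    anchor_values={"bmi": 20.10, "avg_glucose_level": 100.0},
)
bounds = mc.resolve_bounds(union, constraints)
for name in ("age", "bmi", "avg_glucose_level", "insulin"):
    b = bounds[name]
    tag = "fixed" if b.is_fixed else "free"
    print(f"{name:>18s}: [{b.lower:8.2f}, {b.upper:8.2f}]  ({tag})")

# The search optimises over the union; each model only ever sees its own
# columns, so features outside a disease's set cannot move its probability.
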