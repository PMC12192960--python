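"""The synthetic generator's analytic oracles: the box-constrained risk
minimiser per disease and the sampled true Pareto front of a conflicting
two-disease toy."""

import numpy as np

import multicf as mc
from multicf.reference import DIABETES, STROKE
from multicf.synthetic import LogisticTruth

# 1) default problem: both diseases prefer the same corner, so the true
#    Pareto front degenerates toward a single point
problem = mc.generate(n_subjects=1000, seed=0)
bounds = mc.resolve_bounds(problem.union)
for d in (STROKE, DIABETES):
    assignment, p_min = mc.analytic_optimum(problem.truths[d], problem.registry, bounds)
    print(f"{d}: minimum achievable true risk = {p_min:.6f}")

# 2) a deliberately conflicting toy: one shared feature helps one disease
#    and hurts the other, so the true front is a curve
registry = {"s": mc.FeatureSpec("s", "continuous", 0.0, 1.0)}
union = mc.union_features(
    [mc.DiseaseFeatureSet("d1", ("s",)), mc.DiseaseFeatureSet("d2", ("s",))], registry
)
t1 = LogisticTruth("d1", -1.0, {"s": 3.0})
t2 = LogisticTruth("d2", -1.0, {"s": -3.0})
sample = mc.analytic_pareto([t1, t2], registry, mc.resolve_bounds(union),
                            grid_resolution=11)
print("\nconflicting toy, sampled true Pareto front (P_d1, P_d2):")
for p in sample.points:
    print(f"  ({p[0]:.4f}, {p[1]:.4f})")
# Every point is non-dominated: improving d1 (moving s down) necessarily
# worsens d2, which is exactly the trade-off the multi-objective search
# must expose instead of collapsing to one disease's optimum.
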