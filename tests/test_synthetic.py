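import numpy as np
import pandas as pd
import pytest

import multicf as mc
from multicf.exceptions import ConfigurationError
from multicf.reference import DIABETES, STROKE
from multicf.synthetic import LogisticTruth, _sigmoid


class TestGenerate:
    def test_zero_truth_gives_half_prevalence(self):
        registry = {"x": mc.FeatureSpec("x", "continuous", 0.0, 1.0)}
        sets = [mc.DiseaseFeatureSet("d", ("x",))]
        truths = {"d": LogisticTruth("d", intercept=0.0, effects={"x": 0.0})}
        prob = mc.generate(10_000, registry, sets, truths, seed=0)
        prevalence = prob.tables["d"]["d"].mean()
        assert prevalence == pytest.approx(0.5, abs=0.02)  # ~4 binomial sigma

    def test_same_seed_identical_tables(self):
        p1 = mc.generate(200, seed=11)
        p2 = mc.generate(200, seed=11)
        for d in p1.tables:
            pd.testing.assert_frame_equal(p1.tables[d], p2.tables[d])

    def test_shared_features_consistent_across_tables(self, problem):
        stroke, diabetes = problem.tables[STROKE], problem.tables[DIABETES]
        for shared in ("age", "avg_glucose_level", "bmi"):
            assert np.array_equal(stroke[shared].to_numpy(), diabetes[shared].to_numpy())

    def test_positive_coefficient_raises_rate_across_quartiles(self):
        registry = {"x": mc.FeatureSpec("x", "continuous", 0.0, 1.0)}
        sets = [mc.DiseaseFeatureSet("d", ("x",))]
        truths = {"d": LogisticTruth("d", intercept=-2.0, effects={"x": 4.0})}
        prob = mc.generate(20_000, registry, sets, truths, seed=1)
        t = prob.tables["d"]
        rates = t.groupby(pd.qcut(t["x"], 4, labels=False), observed=True)["d"].mean()
        assert rates.is_monotonic_increasing

    def test_null_injection_for_imputation_testing(self):
        prob = mc.generate(500, seed=2, null_fraction=0.1)
        n_null = prob.tables[STROKE].isna().sum().sum()
        assert n_null == 50

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            mc.generate(5)

    def test_default_mirrors_reference_structure(self, problem):
        assert problem.union.k == 15
        assert len(problem.union.disease_features(STROKE)) == 10
        assert len(problem.union.disease_features(DIABETES)) == 8


class TestAnalyticOptimum:
    def test_positive_coefficient_pushes_to_lower_bound(self):
        registry = {"x": mc.FeatureSpec("x", "continuous", 0.0, 1.0)}
        union = mc.union_features([mc.DiseaseFeatureSet("d", ("x",))], registry)
        truth = LogisticTruth("d", intercept=-1.0, effects={"x": 2.0})
        bounds = mc.resolve_bounds(union)
        a, p = mc.analytic_optimum(truth, registry, bounds)
        assert a["x"] == 0.0
        assert p == pytest.approx(float(_sigmoid(-1.0)))

    def test_all_fixed_returns_fixed_point(self, problem):
        truth = problem.truths[DIABETES]
        fixed = {name: problem.master.iloc[0][name] for name in truth.effects}
        bounds = mc.resolve_bounds(
            problem.union, mc.UserConstraints(fixed=fixed)
        )
        a, p = mc.analytic_optimum(truth, problem.registry, bounds)
        for name, v in fixed.items():
            if problem.registry[name].kind == "continuous":
                assert a[name] == pytest.approx(float(v))
        assert p == pytest.approx(
            truth.probability(fixed, problem.registry), abs=1e-12
        )

    def test_matches_random_search_oracle(self):
        rng = np.random.default_rng(8)
        registry = {
            f"f{i}": mc.FeatureSpec(f"f{i}", "continuous", 0.0, 1.0) for i in range(5)
        }
        union = mc.union_features(
            [mc.DiseaseFeatureSet("d", tuple(registry))], registry
        )
        truth = LogisticTruth(
            "d",
            intercept=float(rng.uniform(-1, 1)),
            effects={k: float(rng.uniform(-2, 2)) for k in registry},
        )
        bounds = mc.resolve_bounds(union)
        _, p_opt = mc.analytic_optimum(truth, registry, bounds)
        # exhaustive 3^5 grid (includes every box corner) as an independent
        # search oracle, plus random interior samples as an upper bound
        from itertools import product

        grid = pd.DataFrame(
            list(product([0.0, 0.5, 1.0], repeat=5)), columns=list(registry)
        )
        p_grid = truth.probability_frame(grid, registry).min()
        samples = pd.DataFrame(rng.random((100_000, 5)), columns=list(registry))
        p_search = truth.probability_frame(samples, registry).min()
        assert p_opt == pytest.approx(p_grid, abs=1e-12)
        assert p_opt <= p_search + 1e-12


class TestAnalyticPareto:
    def _conflict_setup(self):
        registry = {
            "s": mc.FeatureSpec("s", "continuous", 0.0, 1.0),
            "t": mc.FeatureSpec("t", "continuous", 0.0, 1.0),
        }
        union = mc.union_features(
            [
                mc.DiseaseFeatureSet("d1", ("s", "t")),
                mc.DiseaseFeatureSet("d2", ("s", "t")),
            ],
            registry,
        )
        t1 = LogisticTruth("d1", -1.0, {"s": 3.0, "t": 1.0})
        t2 = LogisticTruth("d2", -1.0, {"s": -3.0, "t": 2.0})
        return registry, union, t1, t2

    def test_identical_truths_collapse_to_point(self):
        registry = {"s": mc.FeatureSpec("s", "continuous", 0.0, 1.0)}
        union = mc.union_features(
            [mc.DiseaseFeatureSet("d1", ("s",)), mc.DiseaseFeatureSet("d2", ("s",))],
            registry,
        )
        t = LogisticTruth("d1", -1.0, {"s": 2.0})
        t2 = LogisticTruth("d2", -1.0, {"s": 2.0})
        ps = mc.analytic_pareto([t, t2], registry, mc.resolve_bounds(union))
        assert len(ps.points) == 1
        assert ps.points[0, 0] == pytest.approx(ps.points[0, 1])

    def test_conflicting_feature_traces_curve(self):
        registry, union, t1, t2 = self._conflict_setup()
        bounds = mc.resolve_bounds(union)
        ps = mc.analytic_pareto([t1, t2], registry, bounds, grid_resolution=101)
        # the front is the 1-D sweep of the conflicting feature s with t at 0
        xs = np.linspace(0, 1, 101)
        sweep = np.column_stack([_sigmoid(-1 + 3 * xs), _sigmoid(-1 - 3 * xs)])
        assert ps.points.shape == sweep.shape
        assert np.allclose(np.sort(ps.points[:, 0]), np.sort(sweep[:, 0]))

    def test_matches_full_grid_bruteforce(self):
        registry, union, t1, t2 = self._conflict_setup()
        bounds = mc.resolve_bounds(union)
        ps = mc.analytic_pareto([t1, t2], registry, bounds, grid_resolution=21)
        # independent full 2-D grid over BOTH features
        grid = np.linspace(0, 1, 21)
        s, t = np.meshgrid(grid, grid)
        frame = pd.DataFrame({"s": s.ravel(), "t": t.ravel()})
        pts = np.column_stack(
            [t1.probability_frame(frame, registry), t2.probability_frame(frame, registry)]
        )
        keep = []
        for i in range(len(pts)):
            if not any(
                np.all(pts[j] <= pts[i]) and np.any(pts[j] < pts[i])
                for j in range(len(pts))
            ):
                keep.append(i)
        full = pts[keep]
        assert len(full) == len(ps.points)
        assert np.allclose(
            np.sort(full, axis=0), np.sort(ps.points, axis=0), atol=1e-12
        )

    def test_front_mutually_nondominated(self, problem):
        bounds = mc.resolve_bounds(problem.union)
        ps = mc.analytic_pareto(
            [problem.truths[STROKE], problem.truths[DIABETES]],
            problem.registry,
            bounds,
        )
        pts = ps.points
        for i in range(len(pts)):
            for j in range(len(pts)):
                if i != j:
                    assert not (np.all(pts[j] <= pts[i]) and np.any(pts[j] < pts[i]))

    def test_oversized_grid_rejected(self):
        registry = {
            f"f{i}": mc.FeatureSpec(f"f{i}", "continuous", 0.0, 1.0) for i in range(4)
        }
        union = mc.union_features(
            [
                mc.DiseaseFeatureSet("d1", tuple(registry)),
                mc.DiseaseFeatureSet("d2", tuple(registry)),
            ],
            registry,
        )
        t1 = LogisticTruth("d1", 0.0, {k: 1.0 for k in registry})
        t2 = LogisticTruth("d2", 0.0, {k: -1.0 for k in registry})
        with pytest.raises(ValueError, match="too large"):
            mc.analytic_pareto(
                [t1, t2], registry, mc.resolve_bounds(union), grid_resolution=100
            )
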