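import numpy as np
import pandas as pd
import pytest

import multicf as mc
from multicf.exceptions import ConfigurationError
from multicf.feature_space import validate_genome
from multicf.nsga2 import (
    GenomeSpace,
    Individual,
    Population,
    _polynomial_mutation,
    _sbx_pair,
    sort_population,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class ToyModel:
    """Duck-typed risk model: logistic in raw feature values."""

    def __init__(self, disease, feature_order, coefs, intercept=0.0):
        self.disease = disease
        self.feature_order = tuple(feature_order)
        self.coefs = dict(coefs)
        self.intercept = intercept

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        z = np.full(len(frame), self.intercept)
        for name, beta in self.coefs.items():
            z += beta * frame[name].to_numpy(dtype=float)
        return sigmoid(z)


def make_population(objectives):
    pop = Population(
        [Individual(np.zeros(1), objectives=np.asarray(o, dtype=float)) for o in objectives]
    )
    return pop


# independent O(n^2) oracles live in tests_oracles.py
from tests_oracles import oracle_crowding, oracle_fronts, oracle_select


# --- dominance and sorting -------------------------------------------------


class TestDominance:
    def test_definition(self):
        assert mc.dominates((0.1, 0.2), (0.2, 0.2))
        assert not mc.dominates((0.1, 0.3), (0.2, 0.2))
        assert not mc.dominates((0.2, 0.2), (0.1, 0.3))
        assert not mc.dominates((0.1, 0.2), (0.1, 0.2))  # irreflexive

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mc.dominates((0.1,), (0.1, 0.2))


class TestSorting:
    def test_frozen_example(self):
        pop = make_population([(1, 2), (2, 1), (2, 2), (3, 3)])
        fronts = mc.fast_non_dominated_sort(pop)
        assert fronts == [[0, 1], [2], [3]]
        assert [m.rank for m in pop.members] == [0, 0, 1, 2]

    def test_identical_objectives_single_front(self):
        pop = make_population([(0.5, 0.5)] * 6)
        assert mc.fast_non_dominated_sort(pop) == [list(range(6))]

    @pytest.mark.parametrize("n_obj", [2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, n_obj, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((200, n_obj))
        pop = make_population(F)
        assert mc.fast_non_dominated_sort(pop) == oracle_fronts(F.tolist())


class TestCrowding:
    def test_small_fronts_are_infinite(self):
        assert np.all(np.isinf(mc.crowding_distance(np.array([[0.1, 0.2]]))))
        assert np.all(np.isinf(mc.crowding_distance(np.array([[0.1, 0.2], [0.2, 0.1]]))))

    def test_collinear_middle_point(self):
        F = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        d = mc.crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        F = rng.random((20, 2))
        d = mc.crowding_distance(F)
        perm = rng.permutation(20)
        d_perm = mc.crowding_distance(F[perm])
        assert np.allclose(d[perm], d_perm)

    def test_matches_oracle(self):
        rng = np.random.default_rng(9)
        F = rng.random((50, 3))
        assert np.allclose(mc.crowding_distance(F), oracle_crowding(F))


# --- variation operators ----------------------------------------------------


def toy_space(fixed=None, windows=None):
    registry = {
        "u": mc.FeatureSpec("u", "continuous", 0.0, 1.0),
        "v": mc.FeatureSpec("v", "continuous", 0.0, 1.0),
        "w": mc.FeatureSpec("w", "binary"),
    }
    union = mc.union_features([mc.DiseaseFeatureSet("d", ("u", "v", "w"))], registry)
    cons = mc.UserConstraints(fixed=fixed or {}, windows=windows or {})
    return union, GenomeSpace(union, mc.resolve_bounds(union, cons))


class TestVariation:
    def test_identical_parents_zero_mutation_reproduce(self):
        union, space = toy_space()
        genome = np.array([0.3, 0.7, 1.0])
        members = [Individual(genome.copy(), np.array([0.1]), rank=0, crowding=np.inf)
                   for _ in range(4)]
        pop = Population(members)
        cfg = mc.OptimizerConfig(population_size=4, mutation_probability=0.0, seed=0)
        off = mc.make_offspring(pop, cfg, space, np.random.default_rng(0))
        for child in off.members:
            assert np.allclose(child.genome, genome)

    def test_fixed_gene_survives_certain_mutation(self):
        union, space = toy_space(fixed={"u": 0.42})
        rng = np.random.default_rng(1)
        pop = mc.initialize_population(space, 8, rng)
        for m in pop.members:
            m.objectives, m.rank, m.crowding = np.array([0.5]), 0, np.inf
        cfg = mc.OptimizerConfig(population_size=8, mutation_probability=1.0, seed=1)
        off = mc.make_offspring(pop, cfg, space, rng)
        for child in off.members:
            assert child.genome[0] == pytest.approx(0.42)

    def test_sbx_offspring_mean_is_parent_midpoint(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(10_000):
            c1, c2 = _sbx_pair(0.2, 0.8, 0.0, 1.0, eta=15.0, rng=rng)
            vals.extend([c1, c2])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)

    def test_offspring_respect_bounds(self):
        union, space = toy_space(windows={"u": (0.4, 0.6)})
        rng = np.random.default_rng(2)
        pop = mc.initialize_population(space, 20, rng)
        for m in pop.members:
            m.objectives, m.rank, m.crowding = np.array([0.5]), 0, np.inf
        cfg = mc.OptimizerConfig(population_size=20, mutation_probability=0.5, seed=2)
        bounds = mc.resolve_bounds(union, mc.UserConstraints(windows={"u": (0.4, 0.6)}))
        off = mc.make_offspring(pop, cfg, space, rng)
        for child in off.members:
            assert validate_genome(union, bounds, child.genome)

    def test_polynomial_mutation_stays_in_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            x = _polynomial_mutation(rng.random(), 0.0, 1.0, 20.0, rng)
            assert 0.0 <= x <= 1.0


class TestEnvironmentalSelect:
    def test_front_zero_kept_wholesale(self):
        # two clearly layered fronts of size N each (base is a diagonal front)
        base = np.column_stack([np.linspace(0, 1, 10), np.linspace(1, 0, 10)])
        F = np.vstack([base, base + 1.0])
        pop = make_population(F)
        sort_population(pop)
        selected = mc.environmental_select(pop, 10)
        assert all(m.rank == 0 for m in selected.members)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((60, 2))
        pop = make_population(F)
        selected = mc.environmental_select(pop, 30)
        got = sorted(
            int(np.flatnonzero((F == m.objectives).all(axis=1))[0])
            for m in selected.members
        )
        assert got == oracle_select(F.tolist(), 30)

    def test_overdraw_rejected(self):
        pop = make_population([(0.1, 0.1)] * 4)
        with pytest.raises(ValueError):
            mc.environmental_select(pop, 8)


# --- the full loop ----------------------------------------------------------


def one_gene_setup(coef):
    registry = {"x": mc.FeatureSpec("x", "continuous", 0.0, 1.0)}
    union = mc.union_features([mc.DiseaseFeatureSet("d", ("x",))], registry)
    model = ToyModel("d", ("x",), {"x": coef}, intercept=0.0)
    return union, model


class TestRun:
    def test_monotone_objective_reaches_box_optimum(self):
        union, model = one_gene_setup(coef=-6.0)  # decreasing: optimum at x = 1
        cfg = mc.OptimizerConfig(population_size=100, max_generations=40, seed=0)
        res = mc.run([model], union, None, cfg)
        best = min(res.front, key=lambda m: m.objectives[0])
        assert best.genome[0] == pytest.approx(1.0, abs=1e-2)
        assert best.objectives[0] == pytest.approx(sigmoid(-6.0), abs=1e-2)

    def test_elitism_minimum_never_increases(self, problem, trained):
        models, _ = trained
        cfg = mc.OptimizerConfig(population_size=40, max_generations=15, seed=1)
        res = mc.run(list(models.values()), problem.union, None, cfg)
        for name in res.objective_names:
            col = res.trace[f"min_{name}"].to_numpy()
            assert np.all(np.diff(col) <= 1e-15)

    def test_fixed_seed_reproduces_bit_identical_trace(self, problem, trained):
        models, _ = trained
        cfg = mc.OptimizerConfig(population_size=20, max_generations=8, seed=9)
        r1 = mc.run(list(models.values()), problem.union, None, cfg)
        r2 = mc.run(list(models.values()), problem.union, None, cfg)
        pd.testing.assert_frame_equal(r1.trace, r2.trace)
        g1 = np.vstack([m.genome for m in r1.front])
        g2 = np.vstack([m.genome for m in r2.front])
        assert np.array_equal(g1, g2)

    def test_all_fixed_trace_constant(self):
        registry = {"x": mc.FeatureSpec("x", "continuous", 0.0, 1.0)}
        union = mc.union_features([mc.DiseaseFeatureSet("d", ("x",))], registry)
        model = ToyModel("d", ("x",), {"x": 2.0}, intercept=-1.0)
        cfg = mc.OptimizerConfig(population_size=8, max_generations=5, seed=0)
        res = mc.run([model], union, mc.UserConstraints(fixed={"x": 0.5}), cfg)
        assert res.trace["min_d"].nunique() == 1
        assert res.trace["min_d"].iloc[0] == pytest.approx(sigmoid(-1.0 + 1.0))

    def test_final_front_mutually_nondominated(self, problem, trained):
        models, _ = trained
        cfg = mc.OptimizerConfig(population_size=30, max_generations=10, seed=2)
        res = mc.run(list(models.values()), problem.union, None, cfg)
        from multicf.engine import check_front_nondominated

        assert check_front_nondominated(res.front)

    def test_conflicting_objectives_trace_analytic_tradeoff(self):
        registry = {"x": mc.FeatureSpec("x", "continuous", 0.0, 1.0)}
        union = mc.union_features(
            [mc.DiseaseFeatureSet("d1", ("x",)), mc.DiseaseFeatureSet("d2", ("x",))],
            registry,
        )
        m1 = ToyModel("d1", ("x",), {"x": 4.0}, intercept=-2.0)
        m2 = ToyModel("d2", ("x",), {"x": -4.0}, intercept=2.0)
        cfg = mc.OptimizerConfig(population_size=60, max_generations=40, seed=3)
        res = mc.run([m1, m2], union, None, cfg)
        # analytic trade-off curve sampled on a 10^4 grid
        xs = np.linspace(0, 1, 10_000)
        curve = np.column_stack([sigmoid(-2 + 4 * xs), sigmoid(2 - 4 * xs)])
        front = np.vstack([m.objectives for m in res.front])
        dists = np.sqrt(((front[:, None, :] - curve[None, :, :]) ** 2).sum(-1)).min(1)
        assert dists.max() < 0.02

    def test_bounds_and_fixed_hold_every_generation(self, problem, trained):
        models, _ = trained
        cons = mc.UserConstraints(
            fixed={"age": 32.0, "gender": "male"},
            anchor_values={"bmi": 20.10},
        )
        bounds = mc.resolve_bounds(problem.union, cons)
        seen = []

        def watch(gen, population):
            ok = all(
                validate_genome(problem.union, bounds, m.genome)
                for m in population.members
            )
            seen.append(ok)

        cfg = mc.OptimizerConfig(population_size=20, max_generations=10, seed=4)
        mc.run(list(models.values()), problem.union, cons, cfg, callback=watch)
        assert seen and all(seen)


class TestConfigValidation:
    def test_odd_population_rejected(self):
        with pytest.raises(ConfigurationError):
            mc.OptimizerConfig(population_size=7)

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            mc.OptimizerConfig(crossover_probability=1.5)
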