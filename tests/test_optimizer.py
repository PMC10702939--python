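import numpy as np
import pytest

from chaoswolf.chaotic_maps import ChaoticMapSpec, sequence
from chaoswolf.optimizer import (
    Bounds,
    OptimizerConfig,
    coefficient_A,
    coefficient_C,
    dlh_candidate,
    gwo_candidate,
    initialize_population,
    neighbor_indices,
    normalize_variant,
    run,
    schedule_a,
    schedule_r1,
    select_and_update,
)

ALL_VARIANTS = ["ni-gwo", "cni-gwo1", "cni-gwo2", "cni-gwo3", "cni-gwo4"]


def toy_objective(x):
    """Separable objective with known optimum at x = 0.7 everywhere."""
    return 1.0 - float(np.mean(np.abs(np.asarray(x) - 0.7)))


def make_config(variant, **kwargs):
    map_spec = None if variant == "ni-gwo" else ChaoticMapSpec("logistic")
    return OptimizerConfig(variant=variant, map_spec=map_spec, **kwargs)


class TestSchedulesAndCoefficients:
    @pytest.mark.parametrize("t,expected", [(0, 2.0), (50, 1.0), (100, 0.0)])
    def test_schedule_a(self, t, expected):
        assert schedule_a(t, 100) == pytest.approx(expected)

    @pytest.mark.parametrize("t,expected", [(0, 2.0), (25, 1.5), (100, 0.0)])
    def test_schedule_r1(self, t, expected):
        assert schedule_r1(t, 100, 2.0) == pytest.approx(expected)

    def test_schedule_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            schedule_a(101, 100)
        with pytest.raises(ValueError):
            schedule_r1(-1, 100)

    @pytest.mark.parametrize(
        "a,r1,expected", [(2.0, 0.5, 0.0), (2.0, 1.0, 2.0), (1.5, 0.2, -0.9)]
    )
    def test_coefficient_A(self, a, r1, expected):
        assert coefficient_A(a, r1) == pytest.approx(expected)

    @pytest.mark.parametrize("r2,expected", [(0.0, 0.0), (1.0, 2.0), (0.84, 1.68)])
    def test_coefficient_C(self, r2, expected):
        assert coefficient_C(r2) == pytest.approx(expected)


class TestInitialization:
    def test_zero_width_bounds(self):
        cfg = make_config("ni-gwo", population_size=4, bounds=Bounds.uniform(0.3, 0.3, 2))
        pop = initialize_population(cfg, 2, source="uniform")
        assert np.allclose(pop, 0.3)

    def test_chaotic_rowmajor_consumption(self):
        cfg = OptimizerConfig(
            variant="cni-gwo1",
            map_spec=ChaoticMapSpec("logistic", z1=0.7),
            population_size=3,
        )
        pop = initialize_population(cfg, 2, source="chaotic")
        expected = np.array(sequence(cfg.map_spec, 6)).reshape(3, 2)
        assert np.array_equal(pop, expected)
        assert pop[0, 0] == pytest.approx(0.84)
        assert pop[0, 1] == pytest.approx(0.5376)

    def test_uniform_is_seed_deterministic(self):
        cfg = make_config("ni-gwo", population_size=5, seed=9)
        a = initialize_population(cfg, 4, source="uniform")
        b = initialize_population(cfg, 4, source="uniform")
        assert np.array_equal(a, b)

    def test_rejects_bad_dim(self):
        with pytest.raises(ValueError):
            initialize_population(make_config("ni-gwo"), 0)


class TestGwoCandidate:
    def test_coincident_population_is_fixed(self):
        x = np.array([0.4, 0.6])
        leaders = np.tile(x, (3, 1))
        cand = gwo_candidate(x, leaders, A=[0.7, -0.3, 1.2], C=[1, 1, 1], bounds=Bounds.unit(2))
        assert np.allclose(cand, x)

    def test_zero_A_averages_leaders(self):
        leaders = np.array([[0.9, 0.0], [0.6, 0.3], [0.3, 0.6]])
        cand = gwo_candidate(
            np.array([0.1, 0.1]), leaders, A=[0, 0, 0], C=[1, 1, 1], bounds=Bounds.unit(2)
        )
        assert np.allclose(cand, leaders.mean(axis=0))

    def test_one_dimensional_hand_trace(self):
        # X=0.2, leaders (0.8, 0.6, 0.4), C=1, A=0.5:
        # X1' = 0.8 - 0.5*0.6 = 0.5, X2' = 0.6 - 0.5*0.4 = 0.4,
        # X3' = 0.4 - 0.5*0.2 = 0.3 -> mean 0.4
        cand = gwo_candidate(
            np.array([0.2]),
            np.array([[0.8], [0.6], [0.4]]),
            A=[0.5] * 3,
            C=[1.0] * 3,
            bounds=Bounds.unit(1),
        )
        assert cand[0] == pytest.approx(0.4)

    def test_clamped_to_bounds(self):
        cand = gwo_candidate(
            np.array([0.0]),
            np.array([[1.0], [1.0], [1.0]]),
            A=[-5.0] * 3,
            C=[1.0] * 3,
            bounds=Bounds.unit(1),
        )
        assert 0.0 <= cand[0] <= 1.0


class _ScriptedRng:
    """Replays queued draws so the DLH hand trace can pin its randomness."""

    def __init__(self, integer_queues, random_queues):
        self._ints = list(integer_queues)
        self._rands = list(random_queues)

    def integers(self, low, high, size):
        return np.asarray(self._ints.pop(0))

    def random(self, size):
        return np.asarray(self._rands.pop(0))


class TestDlhCandidate:
    def test_neighbors_match_brute_force(self, rng):
        for _ in range(20):
            positions = rng.random((10, 4))
            i = int(rng.integers(0, 10))
            radius = float(rng.random())
            expected = [
                j
                for j in range(10)
                if np.linalg.norm(positions[j] - positions[i]) <= radius + 1e-15
            ]
            assert neighbor_indices(positions, i, radius).tolist() == expected

    def test_self_always_neighbor(self, rng):
        positions = rng.random((6, 3))
        assert 2 in neighbor_indices(positions, 2, 0.0).tolist()

    def test_collapsed_population_is_fixed(self, rng):
        positions = np.tile([0.5, 0.5], (5, 1))
        cand = dlh_candidate(0, positions, positions[0], rng, Bounds.unit(2))
        assert np.allclose(cand, positions[0])

    def test_hand_trace_with_pinned_draws(self):
        # 1-D wolves at (0.0, 0.5, 1.0), X_i = 0.0, gwo candidate 0.6:
        # radius 0.6 -> neighbors {0.0, 0.5}; pinned draws pick neighbor 0.5,
        # population member 1.0, multiplier 0.5:
        # 0.0 + 0.5 * (0.5 - 1.0) = -0.25 -> clamped to 0.0
        positions = np.array([[0.0], [0.5], [1.0]])
        rng = _ScriptedRng(integer_queues=[[1], [2]], random_queues=[[0.5]])
        cand = dlh_candidate(0, positions, np.array([0.6]), rng, Bounds.unit(1))
        assert cand[0] == 0.0

    def test_zero_radius_uses_self(self, rng):
        positions = np.array([[0.2, 0.2], [0.9, 0.9]])
        nbrs = neighbor_indices(positions, 0, 0.0)
        assert nbrs.tolist() == [0]


class TestSelectAndUpdate:
    def test_exhaustive_orderings(self):
        x = np.array([0.0])
        g, d = np.array([1.0]), np.array([2.0])
        # (f_wolf, f_gwo, f_dlh) -> expected winner position
        cases = [
            ((0.7, 0.9, 0.8), g),  # gwo improves
            ((0.7, 0.8, 0.9), d),  # dlh improves
            ((0.6, 0.5, 0.5), x),  # no improvement
            ((0.4, 0.5, 0.5), g),  # candidate tie above incumbent -> gwo
            ((0.5, 0.5, 0.5), x),  # exact tie with incumbent -> keep wolf
            ((0.9, 0.1, 0.2), x),
        ]
        for (fw, fg, fd), expected in cases:
            pos, fit = select_and_update(x, fw, g, fg, d, fd)
            assert np.array_equal(pos, expected)
            assert fit == max(fw, fg, fd)


class TestRun:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_history_monotone_and_eval_count(self, variant):
        cfg = make_config(variant, population_size=8, max_iter=15, seed=3)
        res = run(cfg, 4, toy_objective)
        hist = np.array(res.history)
        assert len(hist) == cfg.max_iter + 1
        assert np.all(np.diff(hist) >= 0)
        assert res.best_fitness == hist[-1]
        assert res.evaluations == 8 + 2 * 8 * 15

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_bit_identical_reruns(self, variant):
        cfg = make_config(variant, population_size=6, max_iter=10, seed=11)
        r1, r2 = run(cfg, 3, toy_objective), run(cfg, 3, toy_objective)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.best_fitness == r2.best_fitness
        assert r1.history == r2.history

    def test_zero_iterations_returns_initial_best(self):
        cfg = make_config("ni-gwo", population_size=5, max_iter=0, seed=2)
        res = run(cfg, 3, toy_objective)
        assert res.evaluations == 5
        assert len(res.history) == 1
        assert res.best_fitness == toy_objective(res.best_position)

    def test_positions_respect_bounds(self):
        seen = []

        def recording(x):
            seen.append(np.array(x))
            return toy_objective(x)

        cfg = make_config("cni-gwo2", population_size=6, max_iter=10, seed=5)
        run(cfg, 4, recording)
        stacked = np.vstack(seen)
        assert stacked.min() >= 0.0 and stacked.max() <= 1.0

    def test_nonfinite_fitness_aborts_with_context(self):
        cfg = make_config("ni-gwo", population_size=4, max_iter=3, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            run(cfg, 2, lambda x: float("nan"))

    def test_toy_objective_convergence_all_variants(self):
        # known optimum at x = 0.7 (fitness 1); each variant should land
        # within 0.05 of it in at least 4 of 5 seeds
        for variant in ALL_VARIANTS:
            hits = 0
            for seed in range(5):
                cfg = make_config(variant, population_size=30, max_iter=100, seed=seed)
                res = run(cfg, 5, toy_objective)
                assert res.best_fitness >= res.history[0]
                if res.best_fitness >= 0.95:
                    hits += 1
            assert hits >= 4, f"{variant} converged in only {hits}/5 seeds"

    def test_chaotic_injection_smoke_equivalence(self, monkeypatch):
        # with the chaotic stream replaced by a uniform source, the chaotic
        # C-injection variants should behave like the base algorithm
        import chaoswolf.optimizer as opt

        class UniformStream:
            def __init__(self, spec):
                self._rng = np.random.default_rng(424242)

            def next_unit(self):
                return float(self._rng.random())

        def mean_best(variant):
            vals = []
            for seed in range(5):
                cfg = make_config(variant, population_size=15, max_iter=40, seed=seed)
                vals.append(run(cfg, 5, toy_objective).best_fitness)
            return float(np.mean(vals))

        base = mean_best("ni-gwo")
        monkeypatch.setattr(opt, "ChaoticStream", UniformStream)
        for variant in ("cni-gwo2", "cni-gwo3", "cni-gwo4"):
            assert abs(mean_best(variant) - base) < 0.05


class TestConfigValidation:
    def test_variant_aliases(self):
        assert normalize_variant("NIGWO") == "ni-gwo"
        assert normalize_variant("cni1") == "cni-gwo1"
        with pytest.raises(ValueError):
            normalize_variant("pso")

    def test_chaotic_variant_requires_map(self):
        with pytest.raises(ValueError):
            OptimizerConfig(variant="cni-gwo1")

    def test_population_floor(self):
        with pytest.raises(ValueError):
            OptimizerConfig(variant="ni-gwo", population_size=2)
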