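"""Grey wolf optimizer family with dimension-learning-based hunting.

The engine maximizes a fitness function over a box-bounded continuous search
space with a population of N "wolves".  Each iteration the three best wolves
(alpha, beta, delta) guide a canonical leader-following move, and every wolf
additionally builds a second, neighborhood-based candidate (dimension
learning-based hunting, DLH); the better of the two candidates replaces the
wolf only if it strictly improves on it, so the best-so-far trace is
monotone.

Five variants are provided:

``ni-gwo``
    The base algorithm: the r1 coefficient that usually is a fresh uniform
    draw is replaced by a deterministic schedule decreasing linearly from 2
    to 0 over the iterations.
``cni-gwo1``
    As ni-gwo, but the initial population is laid out with a chaotic map
    orbit instead of uniform draws.
``cni-gwo2`` / ``cni-gwo3`` / ``cni-gwo4``
    As ni-gwo, but the C coefficient of the alpha / beta / delta leader
    respectively is drawn from the chaotic map (C = 2 z) instead of the
    uniform source.

Draw accounting is fixed so a run is a pure function of (config, seed): the
chaotic stream is consumed row-major during initialization (cni-gwo1) or
once per wolf per iteration (cni-gwo2/3/4); all remaining randomness comes
from one seeded numpy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chaotic_maps import ChaoticMapSpec, ChaoticStream

__all__ = [
    "Bounds",
    "OptimizerConfig",
    "RunResult",
    "VARIANTS",
    "normalize_variant",
    "initialize_population",
    "schedule_a",
    "schedule_r1",
    "coefficient_A",
    "coefficient_C",
    "gwo_candidate",
    "neighbor_indices",
    "dlh_candidate",
    "select_and_update",
    "run",
]

VARIANTS = ("ni-gwo", "cni-gwo1", "cni-gwo2", "cni-gwo3", "cni-gwo4")

_ALIASES = {
    "nigwo": "ni-gwo",
    "ni_gwo": "ni-gwo",
    "cni1": "cni-gwo1",
    "cni2": "cni-gwo2",
    "cni3": "cni-gwo3",
    "cni4": "cni-gwo4",
    "cni_gwo1": "cni-gwo1",
    "cni_gwo2": "cni-gwo2",
    "cni_gwo3": "cni-gwo3",
    "cni_gwo4": "cni-gwo4",
}

# which leader's C coefficient is chaotic, per variant (None: no injection)
_CHAOTIC_C_LEADER = {"cni-gwo2": 0, "cni-gwo3": 1, "cni-gwo4": 2}


def normalize_variant(name: str) -> str:
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")
    return key


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box constraints l_j <= x_j <= u_j."""

    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def unit(cls, dim: int) -> "Bounds":
        return cls(np.zeros(dim), np.ones(dim))

    @classmethod
    def uniform(cls, low: float, high: float, dim: int) -> "Bounds":
        return cls(np.full(dim, float(low)), np.full(dim, float(high)))

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("lower and upper bound vectors must have equal shape")
        if np.any(lo > hi):
            raise ValueError("every lower bound must not exceed its upper bound")

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class OptimizerConfig:
    """Run settings; the defaults (population 30, 100 iterations) are the
    standard protocol for this optimizer family."""

    variant: str = "ni-gwo"
    map_spec: ChaoticMapSpec | None = None
    population_size: int = 30
    max_iter: int = 100
    seed: int = 0
    bounds: Bounds | None = None
    alpha_const: float = 2.0
    #: reproduce the leader distance |C - X_leader - X| exactly as some
    #: descriptions typeset it, instead of the canonical |C * X_leader - X|.
    literal_distance: bool = False

    def __post_init__(self) -> None:
        self.variant = normalize_variant(self.variant)
        if self.population_size < 3:
            raise ValueError("population_size must be at least 3 (three leaders)")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.variant != "ni-gwo" and self.map_spec is None:
            raise ValueError(f"variant {self.variant!r} requires a chaotic map_spec")


@dataclass
class RunResult:
    """Outcome of one optimizer run.

    ``history[i]`` is the best-so-far fitness after iteration ``i`` (entry 0
    is the best of the initial population), so it is non-decreasing and its
    last entry equals ``best_fitness``.
    """

    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    evaluations: int
    seed: int
    variant: str = "ni-gwo"
    extras: dict = field(default_factory=dict)


def schedule_a(t: int, max_iter: int) -> float:
    """Encircling coefficient a(t), linear from 2 at t=0 to 0 at t=max_iter."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration index {t} outside [0, {max_iter}]")
    return 2.0 * (1.0 - t / max_iter)


def schedule_r1(t: int, max_iter: int, alpha_const: float = 2.0) -> float:
    """Deterministic replacement for the uniform r1 draw: linear alpha_const -> 0."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration index {t} outside [0, {max_iter}]")
    return alpha_const - t * (alpha_const / max_iter)


def coefficient_A(a: float, r1: float) -> float:
    return 2.0 * a * r1 - a


def coefficient_C(r2: float) -> float:
    return 2.0 * r2


def initialize_population(
    config: OptimizerConfig,
    dim: int,
    source: str = "uniform",
    rng: np.random.Generator | None = None,
    stream: ChaoticStream | None = None,
) -> np.ndarray:
    """Lay out the initial N x dim positions X_ij = l_j + s * (u_j - l_j).

    ``s`` is a fresh uniform draw per entry, or — for ``source='chaotic'`` —
    the next chaotic unit value, consumed in row-major order.
    """
    if dim < 1:
        raise ValueError("dim must be positive")
    n = config.population_size
    bounds = config.bounds if config.bounds is not None else Bounds.unit(dim)
    if source == "uniform":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        s = rng.random((n, dim))
    elif source == "chaotic":
        if stream is None:
            if config.map_spec is None:
                raise ValueError("chaotic initialization requires a map_spec")
            stream = ChaoticStream(config.map_spec)
        s = np.array([stream.next_unit() for _ in range(n * dim)]).reshape(n, dim)
    else:
        raise ValueError(f"unknown initialization source {source!r}")
    return bounds.lower + s * (bounds.upper - bounds.lower)


def gwo_candidate(
    position: np.ndarray,
    leader_positions: np.ndarray,
    A: Sequence[float],
    C: Sequence[float],
    bounds: Bounds,
    literal_distance: bool = False,
) -> np.ndarray:
    """Canonical leader-following move.

    For each leader k: D_k = |C_k * X_k - X| and X_k' = X_k - A_k * D_k; the
    candidate is the mean of the three X_k', clamped to the bounds.
    """
    A = np.asarray(A, dtype=float).reshape(3, 1)
    C = np.asarray(C, dtype=float).reshape(3, 1)
    leaders = np.asarray(leader_positions, dtype=float)
    if literal_distance:
        D = np.abs(C - leaders - position)
    else:
        D = np.abs(C * leaders - position)
    moved = leaders - A * D
    return bounds.clamp(moved.mean(axis=0))


def neighbor_indices(positions: np.ndarray, i: int, radius: float) -> np.ndarray:
    """Indices of wolves within Euclidean distance ``radius`` of wolf ``i``.

    Wolf ``i`` itself always qualifies (distance 0), so the set is never
    empty even when the radius is 0.
    """
    d = np.linalg.norm(positions - positions[i], axis=1)
    return np.flatnonzero(d <= radius + 1e-15)


def dlh_candidate(
    i: int,
    positions: np.ndarray,
    gwo_cand: np.ndarray,
    rng: np.random.Generator,
    bounds: Bounds,
) -> np.ndarray:
    """Dimension-learning-based hunting candidate for wolf ``i``.

    The neighborhood radius is the distance from X_i to its canonical
    candidate; per dimension a fresh neighbor, a fresh population member and
    a fresh uniform multiplier are drawn:
    cand_d = X_{i,d} + rand * (X_{n,d} - X_{r,d}).
    """
    x_i = positions[i]
    radius = float(np.linalg.norm(x_i - gwo_cand))
    nbrs = neighbor_indices(positions, i, radius)
    dim = positions.shape[1]
    n_sel = nbrs[rng.integers(0, len(nbrs), size=dim)]
    r_sel = rng.integers(0, positions.shape[0], size=dim)
    mult = rng.random(dim)
    cand = x_i + mult * (positions[n_sel, np.arange(dim)] - positions[r_sel, np.arange(dim)])
    return bounds.clamp(cand)


def select_and_update(
    position: np.ndarray,
    fitness: float,
    cand_gwo: np.ndarray,
    fit_gwo: float,
    cand_dlh: np.ndarray,
    fit_dlh: float,
) -> tuple[np.ndarray, float]:
    """Greedy acceptance between the two candidates and the incumbent.

    The better candidate wins (ties go to the canonical GWO candidate); the
    wolf is replaced only on strict fitness improvement.
    """
    if fit_gwo >= fit_dlh:
        cand, fit = cand_gwo, fit_gwo
    else:
        cand, fit = cand_dlh, fit_dlh
    if fit > fitness:
        return cand, fit
    return position, fitness


def _evaluate(fitness_fn: Callable[[np.ndarray], float], x: np.ndarray, where: str) -> float:
    value = float(fitness_fn(x))
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite fitness {value!r} at {where}")
    return value


def run(config: OptimizerConfig, dim: int, fitness_fn: Callable[[np.ndarray], float]) -> RunResult:
    """Execute one optimizer run, maximizing ``fitness_fn``.

    Total fitness evaluations: N (initialization) + 2*N*max_iter (both
    candidates of every wolf every iteration).
    """
    bounds = config.bounds if config.bounds is not None else Bounds.unit(dim)
    cfg = OptimizerConfig(
        variant=config.variant,
        map_spec=config.map_spec,
        population_size=config.population_size,
        max_iter=config.max_iter,
        seed=config.seed,
        bounds=bounds,
        alpha_const=config.alpha_const,
        literal_distance=config.literal_distance,
    )
    rng = np.random.default_rng(cfg.seed)
    stream = ChaoticStream(cfg.map_spec) if cfg.map_spec is not None else None

    source = "chaotic" if cfg.variant == "cni-gwo1" else "uniform"
    positions = initialize_population(cfg, dim, source=source, rng=rng, stream=stream)
    n = cfg.population_size
    fitness = np.array(
        [_evaluate(fitness_fn, positions[i], f"initialization, wolf {i}") for i in range(n)]
    )
    evaluations = n

    best_idx = int(np.argmax(fitness))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitness[best_idx])
    history = [best_fit]

    chaotic_leader = _CHAOTIC_C_LEADER.get(cfg.variant)

    for t in range(cfg.max_iter):
        a = schedule_a(t, cfg.max_iter)
        r1 = schedule_r1(t, cfg.max_iter, cfg.alpha_const)
        A_val = coefficient_A(a, r1)  # r1 schedule applies to all three leaders
        order = np.argsort(-fitness, kind="stable")
        leaders = positions[order[:3]].copy()

        new_positions = positions.copy()
        new_fitness = fitness.copy()
        for i in range(n):
            C = np.empty(3)
            for k in range(3):
                if k == chaotic_leader:
                    C[k] = coefficient_C(stream.next_unit())
                else:
                    C[k] = coefficient_C(rng.random())
            cand_gwo = gwo_candidate(
                positions[i], leaders, (A_val, A_val, A_val), C, bounds,
                literal_distance=cfg.literal_distance,
            )
            cand_dlh = dlh_candidate(i, positions, cand_gwo, rng, bounds)
            where = f"iteration {t}, wolf {i}"
            fit_gwo = _evaluate(fitness_fn, cand_gwo, where + " (gwo candidate)")
            fit_dlh = _evaluate(fitness_fn, cand_dlh, where + " (dlh candidate)")
            evaluations += 2
            new_positions[i], new_fitness[i] = select_and_update(
                positions[i], float(fitness[i]), cand_gwo, fit_gwo, cand_dlh, fit_dlh
            )
        positions, fitness = new_positions, new_fitness

        it_best = int(np.argmax(fitness))
        if fitness[it_best] > best_fit:
            best_fit = float(fitness[it_best])
            best_pos = positions[it_best].copy()
        history.append(best_fit)

    return RunResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=history,
        evaluations=evaluations,
        seed=cfg.seed,
        variant=cfg.variant,
    )
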