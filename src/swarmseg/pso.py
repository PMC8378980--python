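"""Global-best particle swarm optimizers for bounded maximization.

Two variants are provided:

* :func:`optimize` — PSO with a *shrinkage factor* (a constriction-style
  multiplier on the whole velocity update) scheduled to decrease linearly
  from ``p_max`` to ``p_min`` over the run, layered on top of a classic
  inertia-weight rule.  The shrinkage factor damps particle velocities more
  and more as the search progresses, shifting the swarm from exploration to
  local refinement.
* :func:`optimize_standard` — the same dynamics with the shrinkage factor
  pinned at 1, i.e. plain inertia-weight PSO, kept as a comparison baseline.

Both maximize; minimize by negating the objective.  Objective values of
``-inf`` are accepted and treated as "infeasible candidate" markers (they
can never become a personal or global best while any feasible candidate
exists); ``NaN`` and ``+inf`` raise :class:`EvaluationError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PSOConfig",
    "SearchBounds",
    "Particle",
    "SwarmState",
    "OptimizationResult",
    "EvaluationError",
    "shrinkage_factor",
    "initialize_swarm",
    "velocity_update",
    "position_update",
    "swarm_step",
    "optimize",
    "optimize_standard",
    "compare_optimizers",
]

Objective = Callable[[np.ndarray], float]

#: Default velocity clamp, as a fraction of each dimension's search range,
#: used when ``PSOConfig.v_max`` is left unset.
DEFAULT_V_MAX_FRACTION = 0.2


class EvaluationError(RuntimeError):
    """The objective returned NaN or +inf at some evaluated position."""


@dataclass(frozen=True)
class PSOConfig:
    """Optimizer parameters.

    Parameters
    ----------
    swarm_size:
        Number of particles (>= 2).
    n_max:
        Maximum iteration count (>= 1).
    p_max, p_min:
        Upper and lower bounds of the linearly decreasing shrinkage factor,
        with ``p_max >= p_min > 0``.
    inertia_weight:
        Coefficient on the previous velocity (w).
    c1, c2:
        Cognitive (personal-best) and social (global-best) acceleration
        coefficients; ``c1 + c2 > 0``.
    v_max:
        Per-dimension velocity clamp.  ``None`` means "20% of each
        dimension's range", resolved against the search bounds at run time.
    seed:
        Seed for the swarm's random number generator.
    stall_tolerance, stall_window:
        Early stop when the global best improves by less than
        ``stall_tolerance`` over ``stall_window`` consecutive iterations;
        ``stall_window = 0`` disables early stopping (the default).
    """

    swarm_size: int = 30
    n_max: int = 100
    p_max: float = 0.9
    p_min: float = 0.4
    inertia_weight: float = 1.0
    c1: float = 2.0
    c2: float = 2.0
    v_max: float | None = None
    seed: int = 0
    stall_tolerance: float = 0.0
    stall_window: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError(f"swarm_size must be >= 2, got {self.swarm_size}")
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if not (self.p_max >= self.p_min > 0):
            raise ValueError(
                f"need p_max >= p_min > 0, got p_max={self.p_max}, p_min={self.p_min}"
            )
        if self.inertia_weight < 0:
            raise ValueError("inertia_weight must be nonnegative")
        if self.c1 < 0 or self.c2 < 0 or self.c1 + self.c2 <= 0:
            raise ValueError("need c1, c2 >= 0 and c1 + c2 > 0")
        if self.v_max is not None and self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.stall_tolerance < 0 or self.stall_window < 0:
            raise ValueError("stall_tolerance and stall_window must be nonnegative")


@dataclass(frozen=True)
class SearchBounds:
    """Axis-aligned box constraint, one (lower, upper) pair per dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1 or lower.size < 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length >= 1")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, position: np.ndarray) -> bool:
        return bool(np.all(position >= self.lower) and np.all(position <= self.upper))


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int
    rng: np.random.Generator = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray
    iterations_run: int
    converged_early: bool


def shrinkage_factor(n: int, config: PSOConfig) -> float:
    """Linearly decreasing shrinkage factor at iteration ``n``.

    Returns ``p_max - (p_max - p_min) * n / n_max``, which equals ``p_max``
    at n = 0 and ``p_min`` at n = n_max.
    """
    if n < 0 or n > config.n_max:
        raise ValueError(f"iteration n={n} outside [0, n_max={config.n_max}]")
    return config.p_max - (config.p_max - config.p_min) * n / config.n_max


def resolve_v_max(config: PSOConfig, bounds: SearchBounds) -> np.ndarray:
    """Per-dimension velocity clamp; defaults to 20% of each range."""
    if config.v_max is not None:
        return np.full(bounds.dim, float(config.v_max))
    return DEFAULT_V_MAX_FRACTION * bounds.range


def _checked_fitness(value: float, position: np.ndarray) -> float:
    value = float(value)
    if math.isnan(value) or value == math.inf:
        raise EvaluationError(
            f"objective returned non-finite value {value!r} at position {position!r}"
        )
    return value


def initialize_swarm(
    config: PSOConfig,
    bounds: SearchBounds,
    objective: Objective,
    rng: np.random.Generator | None = None,
) -> SwarmState:
    """Seeded uniform initialization of positions, velocities and bests."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    v_max = resolve_v_max(config, bounds)
    particles: list[Particle] = []
    for _ in range(config.swarm_size):
        position = rng.uniform(bounds.lower, bounds.upper)
        velocity = rng.uniform(-v_max, v_max)
        fitness = _checked_fitness(objective(position), position)
        particles.append(
            Particle(
                position=position,
                velocity=velocity,
                pbest_position=position.copy(),
                pbest_fitness=fitness,
            )
        )
    best = max(range(len(particles)), key=lambda i: particles[i].pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=particles[best].pbest_position.copy(),
        gbest_fitness=particles[best].pbest_fitness,
        iteration=0,
        rng=rng,
    )


def velocity_update(
    particle: Particle,
    gbest_position: np.ndarray,
    factor: float,
    config: PSOConfig,
    random_draws: tuple[np.ndarray, np.ndarray],
    v_max: np.ndarray | float | None = None,
) -> np.ndarray:
    """One velocity update with the shrinkage factor applied to the whole rule.

    ``v' = factor * (w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x))``, then
    clamped componentwise to ``[-v_max, v_max]``.  ``r1, r2`` are injected
    per-dimension uniform draws in [0, 1].
    """
    r1, r2 = (np.asarray(r, dtype=float) for r in random_draws)
    gbest_position = np.asarray(gbest_position, dtype=float)
    dim = particle.position.size
    for name, vec in (("r1", r1), ("r2", r2), ("gbest_position", gbest_position)):
        if vec.size != dim:
            raise ValueError(f"dimension mismatch: {name} has size {vec.size}, expected {dim}")
    new_velocity = factor * (
        config.inertia_weight * particle.velocity
        + config.c1 * r1 * (particle.pbest_position - particle.position)
        + config.c2 * r2 * (gbest_position - particle.position)
    )
    if v_max is None:
        v_max = config.v_max
    if v_max is None:
        raise ValueError("v_max must be resolvable (set PSOConfig.v_max or pass v_max)")
    return np.clip(new_velocity, -np.asarray(v_max, dtype=float), np.asarray(v_max, dtype=float))


def position_update(
    particle: Particle,
    new_velocity: np.ndarray,
    bounds: SearchBounds,
) -> tuple[np.ndarray, np.ndarray]:
    """Move by ``new_velocity``, clamping into bounds.

    Returns ``(position, velocity)`` where the velocity component is zeroed
    wherever the position had to be clamped, so particles do not keep
    pushing into a wall.
    """
    raw = particle.position + np.asarray(new_velocity, dtype=float)
    clamped = np.clip(raw, bounds.lower, bounds.upper)
    velocity = np.where(raw == clamped, new_velocity, 0.0)
    return clamped, velocity


def swarm_step(
    state: SwarmState,
    config: PSOConfig,
    bounds: SearchBounds,
    objective: Objective,
    factor: float | None = None,
) -> SwarmState:
    """Advance the swarm one iteration in place and return it.

    ``factor=None`` uses the linear shrinkage schedule at the current
    iteration; a fixed value (e.g. 1.0) gives the standard-PSO baseline.
    """
    if state.iteration >= config.n_max:
        raise ValueError(f"iteration {state.iteration} already at n_max={config.n_max}")
    if factor is None:
        factor = shrinkage_factor(state.iteration, config)
    v_max = resolve_v_max(config, bounds)
    rng = state.rng
    for particle in state.particles:
        r1 = rng.random(bounds.dim)
        r2 = rng.random(bounds.dim)
        velocity = velocity_update(
            particle, state.gbest_position, factor, config, (r1, r2), v_max=v_max
        )
        position, velocity = position_update(particle, velocity, bounds)
        particle.position = position
        particle.velocity = velocity
        fitness = _checked_fitness(objective(position), position)
        if fitness > particle.pbest_fitness:
            particle.pbest_fitness = fitness
            particle.pbest_position = position.copy()
            if fitness > state.gbest_fitness:
                state.gbest_fitness = fitness
                state.gbest_position = position.copy()
    state.iteration += 1
    return state


def _run(
    objective: Objective,
    bounds: SearchBounds,
    config: PSOConfig,
    factor: float | None,
    on_step: Callable[[SwarmState], None] | None = None,
) -> OptimizationResult:
    state = initialize_swarm(config, bounds, objective)
    trace: list[float] = []
    converged_early = False
    for _ in range(config.n_max):
        swarm_step(state, config, bounds, objective, factor=factor)
        trace.append(state.gbest_fitness)
        if on_step is not None:
            on_step(state)
        if (
            config.stall_window > 0
            and len(trace) > config.stall_window
            and trace[-1] - trace[-1 - config.stall_window] < config.stall_tolerance
        ):
            converged_early = True
            break
    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_fitness=state.gbest_fitness,
        fitness_trace=np.asarray(trace, dtype=float),
        iterations_run=len(trace),
        converged_early=converged_early,
    )


def optimize(
    objective: Objective,
    bounds: SearchBounds,
    config: PSOConfig,
    on_step: Callable[[SwarmState], None] | None = None,
) -> OptimizationResult:
    """Maximize ``objective`` with the shrinkage-factor (improved) PSO."""
    return _run(objective, bounds, config, factor=None, on_step=on_step)


def optimize_standard(
    objective: Objective,
    bounds: SearchBounds,
    config: PSOConfig,
    on_step: Callable[[SwarmState], None] | None = None,
) -> OptimizationResult:
    """Maximize ``objective`` with plain inertia-weight PSO (factor = 1)."""
    return _run(objective, bounds, config, factor=1.0, on_step=on_step)


def compare_optimizers(
    objective: Objective,
    bounds: SearchBounds,
    config: PSOConfig,
) -> dict[str, OptimizationResult]:
    """Run the improved and standard optimizers under identical settings.

    Both runs use ``config.n_max`` iterations with stall detection disabled
    so the two fitness traces have equal length and are directly comparable.
    """
    fair = replace(config, stall_window=0)
    return {
        "improved": optimize(objective, bounds, fair),
        "standard": optimize_standard(objective, bounds, fair),
    }
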