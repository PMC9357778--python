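"""Particle swarm optimization and the PSO/ELM coupling.

Two update rules are provided: the classical inertia rule (velocity memory
scaled by an inertia schedule plus attraction to the global and personal
bests) and an accelerated rule that replaces the velocity with a direct
pull toward the global best plus annealed random exploration.  Both accept
an injected randomness source so single steps are exactly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .elm import ELMModel, hidden_matrix, init_elm, one_hot, predict, train_elm

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "init_swarm",
    "step_inertia",
    "step_accelerated",
    "optimize",
    "pso_elm_train",
    "linear_inertia",
]

#: per-step decay of the accelerated rule's exploration noise
NOISE_ANNEAL = 0.97


def linear_inertia(max_iter: int) -> Callable[[int], float]:
    """Default schedule 0.9 - 0.5 * n / max_iter, staying inside (0, 1)."""
    def phi(n: int) -> float:
        return 0.9 - 0.5 * n / max_iter
    return phi


@dataclass
class SwarmConfig:
    n_particles: int
    dim: int
    bounds: tuple[float, float] | Sequence[tuple[float, float]] = (-1.0, 1.0)
    beta: float = 2.0
    gamma: float = 2.0
    inertia: float | Callable[[int], float] | None = None
    max_iter: int = 100
    seed: int = 0
    update_rule: str = "inertia"

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim == 1:
            lo = np.full(self.dim, b[0])
            hi = np.full(self.dim, b[1])
        else:
            lo, hi = b[:, 0], b[:, 1]
        if np.any(lo >= hi):
            raise ValueError("each bound must satisfy lo < hi")
        return lo, hi

    def inertia_at(self, n: int) -> float:
        if self.inertia is None:
            return linear_inertia(self.max_iter)(n)
        if callable(self.inertia):
            return float(self.inertia(n))
        if not (0.0 < self.inertia < 1.0):
            raise ValueError("constant inertia must lie in (0, 1)")
        return float(self.inertia)

    def validate(self) -> None:
        if self.n_particles < 1 or self.dim < 1:
            raise ValueError("n_particles and dim must be >= 1")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be >= 0")
        if self.update_rule not in ("inertia", "accelerated"):
            raise ValueError("update_rule must be 'inertia' or 'accelerated'")
        self.bounds_arrays()


@dataclass
class SwarmState:
    positions: np.ndarray          # (n_particles, dim)
    velocities: np.ndarray         # (n_particles, dim)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray      # (n_particles,)
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    fitness_history: list[float] = field(default_factory=list)
    rng: np.random.Generator | None = None


def _evaluate(fitness, positions: np.ndarray) -> np.ndarray:
    return np.array([float(fitness(p)) for p in positions])


def init_swarm(config: SwarmConfig, fitness: Callable) -> SwarmState:
    """Seeded uniform positions in the box, velocities in +/-(hi-lo)/2."""
    config.validate()
    lo, hi = config.bounds_arrays()
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(lo, hi, size=(config.n_particles, config.dim))
    span = (hi - lo) / 2.0
    velocities = rng.uniform(-span, span, size=(config.n_particles, config.dim))
    fit = _evaluate(fitness, positions)
    if not np.all(np.isfinite(fit)):
        bad = positions[int(np.argmax(~np.isfinite(fit)))]
        raise ValueError(f"non-finite fitness at initial point {bad}")
    best = int(np.argmin(fit))
    state = SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fit,
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fit[best]),
        rng=rng,
    )
    state.fitness_history.append(state.gbest_fitness)
    return state


def _update_bests(state: SwarmState, fitness) -> None:
    fit = _evaluate(fitness, state.positions)
    improved = fit < state.pbest_fitness
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_fitness[improved] = fit[improved]
    best = int(np.argmin(state.pbest_fitness))
    if state.pbest_fitness[best] < state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[best])
        state.gbest_position = state.pbest_positions[best].copy()
    state.fitness_history.append(state.gbest_fitness)


def _clamp(state: SwarmState, lo: np.ndarray, hi: np.ndarray) -> None:
    below = state.positions < lo
    above = state.positions > hi
    state.velocities[below | above] = 0.0
    np.clip(state.positions, lo, hi, out=state.positions)


def step_inertia(
    state: SwarmState,
    config: SwarmConfig,
    fitness: Callable,
    deltas: tuple[np.ndarray, np.ndarray] | None = None,
) -> SwarmState:
    """One velocity/position update of the inertia rule.

    v' = phi(n) v + beta d1 (g* - p) + gamma d2 (p* - p);  p' = p + v'.
    ``deltas`` injects the two uniform random vectors for exact testing;
    otherwise they are drawn from the state's generator.
    """
    lo, hi = config.bounds_arrays()
    shape = state.positions.shape
    if deltas is None:
        d1 = state.rng.uniform(size=shape)
        d2 = state.rng.uniform(size=shape)
    else:
        d1 = np.broadcast_to(np.asarray(deltas[0], float), shape)
        d2 = np.broadcast_to(np.asarray(deltas[1], float), shape)
    phi = config.inertia_at(state.iteration)
    state.velocities = (
        phi * state.velocities
        + config.beta * d1 * (state.gbest_position - state.positions)
        + config.gamma * d2 * (state.pbest_positions - state.positions)
    )
    state.positions = state.positions + state.velocities
    _clamp(state, lo, hi)
    state.iteration += 1
    _update_bests(state, fitness)
    return state


def step_accelerated(
    state: SwarmState,
    config: SwarmConfig,
    fitness: Callable,
    deltas: np.ndarray | None = None,
) -> SwarmState:
    """One position update of the accelerated rule.

    p' = (1 - gamma) p + gamma g* + beta d.  When ``deltas`` is injected it
    is used as-is; otherwise d ~ U(0,1) scaled by (hi-lo) * 0.97^n so the
    exploration noise anneals geometrically.
    """
    lo, hi = config.bounds_arrays()
    shape = state.positions.shape
    if deltas is None:
        d = state.rng.uniform(size=shape) * (hi - lo) \
            * NOISE_ANNEAL ** state.iteration
    else:
        d = np.broadcast_to(np.asarray(deltas, float), shape)
    state.positions = (
        (1.0 - config.gamma) * state.positions
        + config.gamma * state.gbest_position
        + config.beta * d
    )
    _clamp(state, lo, hi)
    state.iteration += 1
    _update_bests(state, fitness)
    return state


def optimize(
    config: SwarmConfig, fitness: Callable
) -> tuple[np.ndarray, float, list[float]]:
    """Run ``max_iter`` steps of the configured rule; returns the best
    position, its fitness, and the (non-increasing) best-fitness history."""
    state = init_swarm(config, fitness)
    step = step_inertia if config.update_rule == "inertia" else step_accelerated
    for _ in range(config.max_iter):
        step(state, config, fitness)
    return state.gbest_position, state.gbest_fitness, state.fitness_history


def _model_from_particle(
    particle: np.ndarray, n_inputs: int, n_hidden: int, activation: str
) -> ELMModel:
    W = particle[: n_hidden * n_inputs].reshape(n_hidden, n_inputs)
    k = particle[n_hidden * n_inputs:]
    return ELMModel(W=W.copy(), k=k.copy(), activation=activation)


def pso_elm_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_hidden: int = 50,
    config: SwarmConfig | None = None,
    activation: str = "sigmoid",
    n_classes: int | None = None,
) -> tuple[ELMModel, list[float]]:
    """Optimize ELM input weights/biases against validation error.

    Each particle flattens W (row-major) followed by k; its fitness is the
    validation misclassification rate of the ELM whose output weights are
    solved on the training set, with a small validation-MSE term breaking
    ties between equal error rates.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if X_val.shape[0] == 0:
        raise ValueError("validation set is empty")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    n_inputs = X_train.shape[1]
    if n_classes is None:
        n_classes = int(max(np.max(y_train), np.max(y_val))) + 1
    d_train = one_hot(y_train, n_classes)
    d_val = one_hot(y_val, n_classes)
    y_val = np.asarray(y_val, dtype=int)

    dim = n_hidden * n_inputs + n_hidden
    if config is None:
        config = SwarmConfig(n_particles=20, dim=dim, seed=0)
    if config.dim != dim:
        raise ValueError(f"config.dim must be {dim} (H*J + H)")

    def fitness(particle: np.ndarray) -> float:
        model = _model_from_particle(particle, n_inputs, n_hidden, activation)
        train_elm(model, X_train, d_train)
        Y, labels = predict(model, X_val)
        err = float(np.mean(labels != y_val))
        mse = float(np.mean((Y - d_val) ** 2))
        # lexicographic tie-break on validation MSE, kept below the error
        # quantum 1/n_val
        return err + 1e-3 / X_val.shape[0] * mse / (1.0 + mse)

    best, _, history = optimize(config, fitness)
    model = _model_from_particle(best, n_inputs, n_hidden, activation)
    model.seed = config.seed
    train_elm(model, X_train, d_train)
    return model, history
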