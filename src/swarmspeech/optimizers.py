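"""Continuous-space Dragonfly, Firefly and Moth-Flame optimizers.

All three minimize a scalar objective over a box, share one SwarmState
layout, draw every random number from a single per-run generator, and track
an incumbent whose fitness is non-increasing by construction.

Update rules:

* Dragonfly: each agent proposes ``x + alpha * r + beta * (x_a - x_b)`` with
  ``r`` per-dimension uniform(-1, 1) and ``x_a``/``x_b`` two distinct other
  agents ordered so the difference points from the worse toward the better
  one; the proposal is accepted only if it improves the agent's fitness.
  ``alpha`` decays linearly across iterations.
* Firefly: asynchronous sweep; each agent moves toward every brighter agent
  by ``beta0 * exp(-gamma * r^2)`` of the separation plus a uniform random
  kick scaled by ``alpha``; the brightest agent only random-walks.
* Moth-Flame: flames are the best positions from the union of previous
  flames and current moths; each moth spirals about its flame with
  ``D * exp(b*t) * cos(2*pi*t) + F`` per dimension, ``t`` uniform(-1, 1);
  the flame count shrinks from the population size down to 1.

Positions are clipped to the bounds after every update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "DAConfig",
    "FAConfig",
    "MFOConfig",
    "SwarmState",
    "OptimizationResult",
    "alpha_schedule",
    "da_proposal",
    "da_step",
    "attractiveness",
    "fa_step",
    "flame_count",
    "spiral_update",
    "mfo_step",
    "optimize",
    "OPTIMIZER_KINDS",
]

OPTIMIZER_KINDS = ("dragonfly", "firefly", "mothflame")


@dataclass(frozen=True)
class DAConfig:
    pop_size: int = 50
    n_iter: int = 200
    alpha_start: float = 1.0
    alpha_end: float = 0.1
    beta: float = 0.5

    def __post_init__(self):
        _check_common(self.pop_size, self.n_iter)
        if self.pop_size < 3:
            raise ConfigurationError(
                "dragonfly needs pop_size >= 3 (difference vector needs two distinct others)"
            )


@dataclass(frozen=True)
class FAConfig:
    pop_size: int = 50
    n_iter: int = 200
    alpha: float = 0.2
    beta0: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        _check_common(self.pop_size, self.n_iter)


@dataclass(frozen=True)
class MFOConfig:
    pop_size: int = 50
    n_iter: int = 200
    b: float = 1.0

    def __post_init__(self):
        _check_common(self.pop_size, self.n_iter)


def _check_common(pop_size: int, n_iter: int):
    if pop_size < 2:
        raise ConfigurationError("pop_size must be >= 2")
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")


@dataclass
class SwarmState:
    """Population positions + fitnesses, incumbent, iteration counter and RNG."""

    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    bounds: np.ndarray  # (D, 2)
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    rng_seed: int
    rng: np.random.Generator
    # MFO flame memory (sorted best-so-far positions); unused by DA/FA
    flame_positions: np.ndarray | None = None
    flame_fitness: np.ndarray | None = None

    def update_incumbent(self):
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # per-iteration incumbent fitness, length n_iter
    evaluations: int
    final_positions: np.ndarray | None = None  # (N, D) population at exit


def alpha_schedule(iteration: int, n_iter: int, alpha_start: float, alpha_end: float) -> float:
    """Linear decay from alpha_start (iteration 0) to alpha_end (iteration n_iter-1)."""
    if not 0 <= iteration < n_iter:
        raise InvalidInputError(f"iteration {iteration} out of range [0, {n_iter})")
    if n_iter == 1:
        return alpha_start
    return alpha_start - (alpha_start - alpha_end) * iteration / (n_iter - 1)


def _clip(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(x, bounds[:, 0], bounds[:, 1])


def da_proposal(x, r, alpha: float, beta: float, delta) -> np.ndarray:
    """The dragonfly position-update equation: x + alpha * r + beta * delta."""
    return np.asarray(x, float) + alpha * np.asarray(r, float) + beta * np.asarray(delta, float)


def da_step(state: SwarmState, cfg: DAConfig, objective) -> SwarmState:
    """One dragonfly iteration (greedy acceptance of the proposal)."""
    n, d = state.positions.shape
    if n < 3:
        raise ConfigurationError("dragonfly step requires at least 3 agents")
    alpha = alpha_schedule(state.iteration, cfg.n_iter, cfg.alpha_start, cfg.alpha_end)
    snapshot = state.positions.copy()
    snapshot_fit = state.fitness.copy()
    for i in range(n):
        others = [j for j in range(n) if j != i]
        a, b = state.rng.choice(others, size=2, replace=False)
        # difference vector points from the worse of the pair toward the better
        if snapshot_fit[a] <= snapshot_fit[b]:
            delta = snapshot[a] - snapshot[b]
        else:
            delta = snapshot[b] - snapshot[a]
        r = state.rng.uniform(-1.0, 1.0, size=d)
        proposal = _clip(da_proposal(snapshot[i], r, alpha, cfg.beta, delta), state.bounds)
        f = float(objective(proposal))
        if f < state.fitness[i]:
            state.positions[i] = proposal
            state.fitness[i] = f
    state.update_incumbent()
    state.iteration += 1
    return state


def attractiveness(beta0: float, gamma: float, distance: float) -> float:
    """Firefly attractiveness beta0 * exp(-gamma * r^2); constant when gamma = 0."""
    if distance < 0:
        raise InvalidInputError("distance must be non-negative")
    return beta0 * math.exp(-gamma * distance * distance)


def fa_step(state: SwarmState, cfg: FAConfig, objective) -> SwarmState:
    """One firefly iteration: asynchronous index-order sweep.

    Distances entering the attractiveness kernel are measured in units of the
    mean box side so gamma stays meaningful across search-space scales.
    """
    n, d = state.positions.shape
    if n < 2:
        raise ConfigurationError("firefly step requires at least 2 agents")
    scale = float(np.mean(state.bounds[:, 1] - state.bounds[:, 0]))
    if scale <= 0:
        scale = 1.0
    for i in range(n):
        moved = False
        xi = state.positions[i]
        for j in range(n):
            if j == i or state.fitness[j] >= state.fitness[i]:
                continue
            moved = True
            diff = state.positions[j] - xi
            beta = attractiveness(cfg.beta0, cfg.gamma, float(np.linalg.norm(diff)) / scale)
            rho = state.rng.uniform(0.0, 1.0, size=d)
            xi = xi + beta * diff + cfg.alpha * (rho - 0.5)
        if not moved and i == int(np.argmin(state.fitness)):
            # brightest firefly: pure random walk
            rho = state.rng.uniform(0.0, 1.0, size=d)
            xi = xi + cfg.alpha * (rho - 0.5)
        # one evaluation per agent per iteration, moved or not
        state.positions[i] = _clip(xi, state.bounds)
        state.fitness[i] = float(objective(state.positions[i]))
    state.update_incumbent()
    state.iteration += 1
    return state


def flame_count(iteration: int, n_iter: int, pop_size: int) -> int:
    """Number of surviving flames, shrinking from pop_size toward 1 (half-up rounding)."""
    if not 0 <= iteration < n_iter:
        raise InvalidInputError(f"iteration {iteration} out of range [0, {n_iter})")
    count = int(math.floor(pop_size - iteration * (pop_size - 1) / n_iter + 0.5))
    return max(1, min(pop_size, count))


def spiral_update(distance, b: float, t, flame) -> np.ndarray:
    """Logarithmic spiral: D * exp(b*t) * cos(2*pi*t) + F, elementwise."""
    distance = np.asarray(distance, float)
    t = np.asarray(t, float)
    return distance * np.exp(b * t) * np.cos(2.0 * np.pi * t) + np.asarray(flame, float)


def mfo_step(state: SwarmState, cfg: MFOConfig, iteration: int, objective) -> SwarmState:
    """One moth-flame iteration with shrinking elitist flame memory."""
    n, d = state.positions.shape
    if state.flame_positions is None:
        pool_pos = state.positions.copy()
        pool_fit = state.fitness.copy()
    else:
        pool_pos = np.vstack([state.flame_positions, state.positions])
        pool_fit = np.concatenate([state.flame_fitness, state.fitness])
    order = np.argsort(pool_fit, kind="stable")
    n_flames = flame_count(iteration, cfg.n_iter, n)
    state.flame_positions = pool_pos[order[:n_flames]].copy()
    state.flame_fitness = pool_fit[order[:n_flames]].copy()
    for i in range(n):
        flame = state.flame_positions[min(i, n_flames - 1)]
        dist = np.abs(flame - state.positions[i])
        t = state.rng.uniform(-1.0, 1.0, size=d)
        state.positions[i] = _clip(spiral_update(dist, cfg.b, t, flame), state.bounds)
        state.fitness[i] = float(objective(state.positions[i]))
    state.update_incumbent()
    state.iteration += 1
    return state


def _init_state(objective, bounds: np.ndarray, pop_size: int, seed: int) -> SwarmState:
    rng = np.random.default_rng(seed)
    d = bounds.shape[0]
    positions = rng.uniform(bounds[:, 0], bounds[:, 1], size=(pop_size, d))
    fitness = np.array([float(objective(p)) for p in positions])
    i = int(np.argmin(fitness))
    return SwarmState(
        positions=positions,
        fitness=fitness,
        bounds=bounds,
        best_position=positions[i].copy(),
        best_fitness=float(fitness[i]),
        iteration=0,
        rng_seed=seed,
        rng=rng,
    )


def optimize(objective, bounds, optimizer_kind: str, config=None, seed: int = 0) -> OptimizationResult:
    """Run a full swarm optimization; pop_size * (n_iter + 1) objective evaluations.

    Parameters
    ----------
    objective : callable
        Maps a length-D position vector to a scalar; must be pure.
    bounds : array-like, shape (D, 2)
        Finite per-dimension (low, high) box.
    optimizer_kind : {"dragonfly", "firefly", "mothflame"}
    config : optional DAConfig / FAConfig / MFOConfig matching the kind.
    seed : int
        Seeds every stochastic draw of the run.
    """
    bounds = np.asarray(bounds, dtype=np.float64)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ConfigurationError("bounds must have shape (D, 2)")
    if not np.isfinite(bounds).all() or (bounds[:, 0] > bounds[:, 1]).any():
        raise ConfigurationError("bounds must be finite with low <= high")
    defaults = {"dragonfly": DAConfig, "firefly": FAConfig, "mothflame": MFOConfig}
    if optimizer_kind not in defaults:
        raise ConfigurationError(
            f"unknown optimizer_kind {optimizer_kind!r}; expected one of {OPTIMIZER_KINDS}"
        )
    cfg = config if config is not None else defaults[optimizer_kind]()
    if not isinstance(cfg, defaults[optimizer_kind]):
        raise ConfigurationError(
            f"config type {type(cfg).__name__} does not match optimizer {optimizer_kind!r}"
        )
    state = _init_state(objective, bounds, cfg.pop_size, seed)
    history = np.empty(cfg.n_iter)
    for it in range(cfg.n_iter):
        if optimizer_kind == "dragonfly":
            da_step(state, cfg, objective)
        elif optimizer_kind == "firefly":
            fa_step(state, cfg, objective)
        else:
            mfo_step(state, cfg, it, objective)
        history[it] = state.best_fitness
    return OptimizationResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=history,
        evaluations=cfg.pop_size * (cfg.n_iter + 1),
        final_positions=state.positions.copy(),
    )
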