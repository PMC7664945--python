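"""Particle swarm optimization (PSO) over a bounded box.

Each particle carries a position ``X`` and velocity ``V`` and is pulled
toward its own best-seen position (pbest) and the swarm's best (gbest):

    V <- w V + c1 r1 (pbest - X) + c2 r2 (gbest - X)
    X <- X + V

with ``r1, r2 ~ Uniform(0, 1)`` drawn per particle per dimension per
iteration, velocities clamped to ``±vmax`` and positions clipped to the
bounds.  The inertia weight ``w`` decreases linearly from ``inertia_start``
to ``inertia_end`` over the run, trading exploration for exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import EvaluationError

__all__ = ["PSOConfig", "SwarmState", "step_particle", "pso_minimize"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters.

    ``bounds`` may be a scalar pair applied to every dimension or a pair of
    arrays of per-dimension lows/highs.  ``vmax_fraction`` sets the velocity
    clamp as a fraction of the box width.
    """

    n_particles: int = 50
    max_iter: int = 30
    cognitive: float = 2.0
    social: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.2
    bounds: tuple = (-5.0, 5.0)
    vmax_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError(f"n_particles must be >= 2, got {self.n_particles}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.cognitive < 0 or self.social < 0:
            raise ValueError("cognitive and social coefficients must be >= 0")
        for name, v in (("inertia_start", self.inertia_start),
                        ("inertia_end", self.inertia_end)):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 < self.vmax_fraction <= 1.0:
            raise ValueError(
                f"vmax_fraction must lie in (0, 1], got {self.vmax_fraction}"
            )
        low, high = self.bounds
        if np.any(np.asarray(low) >= np.asarray(high)):
            raise ValueError(f"bounds must satisfy low < high, got {self.bounds}")

    def box(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        low = np.broadcast_to(np.asarray(self.bounds[0], dtype=float), (dim,))
        high = np.broadcast_to(np.asarray(self.bounds[1], dtype=float), (dim,))
        return low.copy(), high.copy()


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping of the swarm."""

    positions: np.ndarray  # (n_particles, dim)
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_costs: np.ndarray
    gbest_position: np.ndarray
    gbest_cost: float
    iteration: int = 0


def _evaluate(cost, positions: np.ndarray) -> np.ndarray:
    vals = np.empty(positions.shape[0])
    for i, p in enumerate(positions):
        v = float(cost(p))
        if np.isnan(v):
            raise EvaluationError(f"cost returned NaN at position {p!r}")
        vals[i] = v
    return vals


def init_swarm(
    cost,
    dim: int,
    cfg: PSOConfig,
    rng: np.random.Generator,
    seed_positions: np.ndarray | None = None,
) -> SwarmState:
    """Uniform random positions (optionally overriding the first particles
    with user-supplied seed positions), zero velocities, bests evaluated."""
    low, high = cfg.box(dim)
    pos = rng.uniform(low, high, size=(cfg.n_particles, dim))
    if seed_positions is not None:
        seeds = np.atleast_2d(np.asarray(seed_positions, dtype=float))
        k = min(len(seeds), cfg.n_particles)
        pos[:k] = np.clip(seeds[:k], low, high)
    vel = np.zeros_like(pos)
    costs = _evaluate(cost, pos)
    g = int(np.argmin(costs))
    return SwarmState(
        positions=pos,
        velocities=vel,
        pbest_positions=pos.copy(),
        pbest_costs=costs.copy(),
        gbest_position=pos[g].copy(),
        gbest_cost=float(costs[g]),
        iteration=0,
    )


def step_particle(
    state: SwarmState,
    cfg: PSOConfig,
    inertia: float,
    rng: np.random.Generator,
    cost,
) -> SwarmState:
    """One full swarm iteration: velocity/position updates, clamping,
    bounds clipping, and pbest/gbest refresh.  Mutates and returns state."""
    n, dim = state.positions.shape
    low, high = cfg.box(dim)
    vmax = cfg.vmax_fraction * (high - low)

    r1 = rng.random((n, dim))
    r2 = rng.random((n, dim))
    state.velocities = (
        inertia * state.velocities
        + cfg.cognitive * r1 * (state.pbest_positions - state.positions)
        + cfg.social * r2 * (state.gbest_position - state.positions)
    )
    np.clip(state.velocities, -vmax, vmax, out=state.velocities)
    state.positions = np.clip(state.positions + state.velocities, low, high)

    costs = _evaluate(cost, state.positions)
    improved = costs < state.pbest_costs
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_costs[improved] = costs[improved]
    g = int(np.argmin(state.pbest_costs))
    if state.pbest_costs[g] < state.gbest_cost:
        state.gbest_cost = float(state.pbest_costs[g])
        state.gbest_position = state.pbest_positions[g].copy()
    state.iteration += 1
    return state


def _inertia_schedule(cfg: PSOConfig, k: int) -> float:
    """Linear interpolation from inertia_start to inertia_end; k is 0-based."""
    if cfg.max_iter == 1:
        return cfg.inertia_start
    frac = k / (cfg.max_iter - 1)
    return cfg.inertia_start + (cfg.inertia_end - cfg.inertia_start) * frac


def pso_minimize(
    cost,
    dim: int,
    cfg: PSOConfig,
    seed_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``cost`` over the bounded box.

    Returns ``(gbest_position, gbest_cost, history)`` where ``history[k]`` is
    the best cost after k iterations (entry 0 is the initial swarm's best);
    it is non-increasing by construction.  Identical configs (including the
    seed) give bitwise-identical results.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(cost, dim, cfg, rng, seed_positions)
    history = [state.gbest_cost]
    for k in range(cfg.max_iter):
        step_particle(state, cfg, _inertia_schedule(cfg, k), rng, cost)
        history.append(state.gbest_cost)
    return state.gbest_position.copy(), state.gbest_cost, np.asarray(history)
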