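"""Constriction particle swarm optimization over the unit hypercube.

Thirty particles move under Clerc-constriction constants (w = 0.729,
c1 = c2 = 1.49445), seeded at the best quasi-Monte Carlo samples with zero
initial velocity.  Velocities follow the canonical attraction form

    v <- w v + c1 Z1 (xp - x) + c2 Z2 (xg - x),    x <- x + v

with Z1, Z2 elementwise standard-uniform, xp the particle's personal best
and xg the swarm best.  Positions leaving [0, 1]^d score +infinity (they
can never become bests), which is the only bound handling.  A particle has
converged when its dimensionless energy

    E_k = |v|^2 + |x - xp|^2 + |x - xg|^2

falls below a threshold (default 0.1); the run stops when all particles
have converged simultaneously or an iteration cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .qmc import sobol_points

Objective = Callable[[np.ndarray], float]


@dataclass
class PSOConfig:
    pop: int = 30
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    energy_tol: float = 0.1
    max_iter: int = 1000


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    xp: np.ndarray
    fp: float


@dataclass
class SwarmState:
    particles: list[Particle]
    xg: np.ndarray
    fg: float
    iteration: int = 0
    config: PSOConfig = field(default_factory=PSOConfig)

    @property
    def d(self) -> int:
        return self.particles[0].x.size


def _in_bounds(x: np.ndarray) -> bool:
    return bool(np.all((x >= 0.0) & (x <= 1.0)))


def init_swarm(seed_points: np.ndarray, seed_errors: Sequence[float],
               objective: Objective, config: PSOConfig | None = None) -> SwarmState:
    """Swarm at the ``pop`` lowest-error seeds, zero velocity, xp = x.

    When fewer than ``pop`` finite-error seeds exist, the deficit is padded
    with Sobol points (evaluated through the objective).  Raises when no
    finite-error seed is available at all.
    """
    config = config or PSOConfig()
    seed_points = np.atleast_2d(np.asarray(seed_points, dtype=float))
    seed_errors = np.asarray(seed_errors, dtype=float)
    finite = np.flatnonzero(np.isfinite(seed_errors))
    if finite.size == 0:
        raise ValueError("no finite-error seed points to initialize the swarm")
    order = finite[np.argsort(seed_errors[finite], kind="stable")][: config.pop]
    xs = [seed_points[i].copy() for i in order]
    fs = [float(seed_errors[i]) for i in order]
    if len(xs) < config.pop:
        d = seed_points.shape[1]
        for p in sobol_points(config.pop - len(xs), d):
            xs.append(p.copy())
            fs.append(float(objective(p)))
    particles = [Particle(x=x, v=np.zeros_like(x), xp=x.copy(), fp=f)
                 for x, f in zip(xs, fs)]
    g = int(np.argmin(fs))
    return SwarmState(particles=particles, xg=particles[g].xp.copy(),
                      fg=particles[g].fp, config=config)


def step(state: SwarmState, objective: Objective, rng: np.random.Generator) -> SwarmState:
    """One synchronous swarm update (in place); returns the state."""
    cfg = state.config
    for p in state.particles:
        z1 = rng.random(p.x.size)
        z2 = rng.random(p.x.size)
        p.v = cfg.w * p.v + cfg.c1 * z1 * (p.xp - p.x) + cfg.c2 * z2 * (state.xg - p.x)
        p.x = p.x + p.v
        f = float(objective(p.x)) if _in_bounds(p.x) else float("inf")
        # ties update the personal best too (keeps the swarm collapsing on
        # flat objectives); infinite scores never become bests
        if f < p.fp or (f == p.fp and np.isfinite(f)):
            p.fp = f
            p.xp = p.x.copy()
    g = int(np.argmin([p.fp for p in state.particles]))
    if state.particles[g].fp < state.fg:
        state.fg = state.particles[g].fp
        state.xg = state.particles[g].xp.copy()
    state.iteration += 1
    return state


def energy(particle: Particle, xg: np.ndarray) -> float:
    """E_k = |v|^2 + |x - xp|^2 + |x - xg|^2 (dimensionless)."""
    return float(np.sum(particle.v ** 2)
                 + np.sum((particle.x - particle.xp) ** 2)
                 + np.sum((particle.x - xg) ** 2))


def run(state: SwarmState, objective: Objective, rng: np.random.Generator,
        max_iter: int | None = None, energy_tol: float | None = None):
    """Iterate until every particle's energy is below tolerance or the cap.

    Returns ``(best_point, best_error, trace)`` where ``trace`` is a list of
    per-iteration dicts (iteration, best_error, max_energy); the best-error
    sequence is non-increasing by construction.
    """
    cfg = state.config
    max_iter = cfg.max_iter if max_iter is None else max_iter
    energy_tol = cfg.energy_tol if energy_tol is None else energy_tol
    trace: list[dict] = []
    for _ in range(max_iter):
        step(state, objective, rng)
        e_max = max(energy(p, state.xg) for p in state.particles)
        trace.append({"iteration": state.iteration, "best_error": state.fg,
                      "max_energy": e_max})
        if e_max < energy_tol:
            break
    return state.xg.copy(), state.fg, trace


def fit(objective: Objective, seed_points: np.ndarray, seed_errors: Sequence[float],
        rng: np.random.Generator, config: PSOConfig | None = None):
    """Convenience wrapper: initialize from seeds and run to convergence."""
    state = init_swarm(seed_points, seed_errors, objective, config)
    return run(state, objective, rng)
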