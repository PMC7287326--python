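"""Morris elementary-effects screening on a z-level grid.

One-at-a-time trajectories over the normalized parameter hypercube give,
for each parameter i and model output j, elementary effects

    E_ij = (Y_j(x + e_i * delta) - Y_j(x)) / delta

with the signed step actually taken.  The screening statistic is the mean
absolute elementary effect mu*_ij over trajectories, a proxy for the total
sensitivity index.  A parameter is *unimportant* — and dropped from the
subset — when its mu* falls strictly below the column mean for every
output.  Screening repeats on the reduced subset until no parameter can be
dropped.

The grid has z levels {0, 1/(z-1), ..., 1} and step delta = z / (2(z-1));
for the default z = 8, delta = 4/7, which maps grid levels onto grid levels
and makes every grid point equally likely to be visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .param_space import ParameterSpace, SubsetMask
from .strain_metrics import indices_vector
from .toy_model import ToyModel


def grid_step(z: int) -> float:
    """Morris step size delta for a z-level grid.

    ``z`` must be even: delta spans z/2 grid cells, so only an even level
    count keeps every step on the grid (and leaves every level one feasible
    direction).
    """
    if z < 2:
        raise ValueError("need at least two grid levels")
    if z % 2:
        raise ValueError("z must be even so that delta maps grid levels onto grid levels")
    return z / (2.0 * (z - 1))


@dataclass(frozen=True)
class Trajectory:
    """D+1 points changing each parameter exactly once by +-delta."""

    points: np.ndarray   # (d+1, d), every coordinate on the grid
    order: np.ndarray    # order[m] = index of the parameter changed at step m
    deltas: np.ndarray   # signed step actually taken, per parameter

    @property
    def d(self) -> int:
        return self.points.shape[1]


def generate_trajectory(d: int, z: int, rng: np.random.Generator) -> Trajectory:
    """Random Morris trajectory in d dimensions on the z-level grid.

    The base point is drawn uniformly over grid levels per coordinate; the
    step direction is the feasible one (or a fair coin when both +delta and
    -delta stay inside [0, 1]).
    """
    delta = grid_step(z)
    levels = np.arange(z) / (z - 1)
    base = levels[rng.integers(0, z, size=d)]
    deltas = np.empty(d)
    for i in range(d):
        up = base[i] + delta <= 1.0 + 1e-12
        down = base[i] - delta >= -1e-12
        if up and down:
            deltas[i] = delta if rng.random() < 0.5 else -delta
        elif up:
            deltas[i] = delta
        elif down:
            deltas[i] = -delta
        else:  # unreachable for any z >= 2: delta <= 1 by construction
            raise RuntimeError("no feasible step direction")
    order = rng.permutation(d)
    points = np.empty((d + 1, d))
    points[0] = base
    for m, i in enumerate(order):
        points[m + 1] = points[m]
        points[m + 1, i] = points[m, i] + deltas[i]
    return Trajectory(points=points, order=order, deltas=deltas)


def elementary_effects(traj: Trajectory, outputs: np.ndarray) -> np.ndarray:
    """Per-parameter elementary effects, shape (d, J).

    ``outputs`` holds the J model outputs evaluated at each of the d+1
    trajectory points (shape (d+1, J)).  The signed step actually taken
    divides the difference, so effects are orientation-free.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    d = traj.d
    if outputs.shape[0] != d + 1:
        raise ValueError(f"need outputs at all {d + 1} trajectory points, got {outputs.shape[0]}")
    effects = np.empty((d, outputs.shape[1]))
    for m, i in enumerate(traj.order):
        effects[i] = (outputs[m + 1] - outputs[m]) / traj.deltas[i]
    return effects


def mu_star(per_trajectory_effects: np.ndarray) -> np.ndarray:
    """mu*_ij: mean over trajectories of |E_ij|.  Input shape (N_r, d, J)."""
    eff = np.asarray(per_trajectory_effects, dtype=float)
    if eff.ndim != 3 or eff.shape[0] < 1:
        raise ValueError("need at least one successful trajectory (shape (N_r, d, J))")
    return np.mean(np.abs(eff), axis=0)


def important_mask(mu: np.ndarray) -> np.ndarray:
    """Boolean mask of retained parameters.

    Parameter i is dropped iff mu*_ij is strictly below the column mean
    (1/D) sum_k mu*_kj for *every* output j; ties retain the parameter.
    Outputs that respond to no parameter at all (identically zero mu*
    column) carry no importance information and are skipped — otherwise the
    strict inequality could never hold and a single constant output would
    veto all exclusion.  When every output is uninformative, everything is
    retained.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    col_mean = mu.mean(axis=0)
    informative = col_mean > 0.0
    if not informative.any():
        return np.ones(mu.shape[0], dtype=bool)
    unimportant = np.all(mu[:, informative] < col_mean[informative], axis=1)
    return ~unimportant


def select_important(mu: np.ndarray, names: list[str]) -> set[str]:
    """Names of parameters retained by the all-outputs unimportance criterion."""
    mask = important_mask(mu)
    return {n for n, keep in zip(names, mask) if keep}


def loo_convergence(per_trajectory_effects: np.ndarray) -> bool:
    """Leave-one-out stability of the retained set.

    True iff dropping any single trajectory leaves the selected parameter
    set unchanged from the full-sample selection.
    """
    eff = np.asarray(per_trajectory_effects, dtype=float)
    n = eff.shape[0]
    if n < 2:
        raise ValueError("leave-one-out needs at least two trajectories")
    full = important_mask(mu_star(eff))
    for r in range(n):
        loo = important_mask(mu_star(np.delete(eff, r, axis=0)))
        if not np.array_equal(loo, full):
            return False
    return True


@dataclass
class MorrisResult:
    """One screening round: effects, mu*, and the retained/excluded split."""

    names: list[str]                    # active parameters this round
    mu_star: np.ndarray                 # (d, J)
    per_trajectory_effects: np.ndarray  # (N_r, d, J)
    n_trajectories: int                 # successful
    n_attempted: int
    important: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    loo_converged: bool | None = None

    def to_record(self, round_no: int) -> dict:
        return {
            "round": round_no,
            "n_attempted": self.n_attempted,
            "n_successful": self.n_trajectories,
            "loo_converged": self.loo_converged,
            "excluded": list(self.excluded),
            "retained": list(self.important),
        }


def collect_effects(model: ToyModel, mask: SubsetMask, n_successful: int, z: int,
                    rng: np.random.Generator, max_attempts: int | None = None):
    """Sample trajectories on the active subspace until the success budget is met.

    A trajectory containing any crashed evaluation is discarded whole and
    counted as unsuccessful.  Returns (effects array (N_r, d, J), attempts).
    """
    if max_attempts is None:
        max_attempts = 10 * n_successful
    d = mask.d
    effects, attempts = [], 0
    while len(effects) < n_successful and attempts < max_attempts:
        attempts += 1
        traj = generate_trajectory(d, z, rng)
        outputs = []
        for sub_point in traj.points:
            res = model.evaluate(mask.restrict(sub_point))
            if not res.ok:
                break
            outputs.append(indices_vector(res.trace))
        else:
            effects.append(elementary_effects(traj, np.asarray(outputs)))
    if not effects:
        raise RuntimeError(f"all {attempts} trajectories crashed; cannot screen")
    return np.asarray(effects), attempts


def run_screening(model: ToyModel, mask: SubsetMask | None = None, *,
                  z: int = 8, trajectory_budget: int = 200, max_rounds: int = 10,
                  rng: np.random.Generator | None = None,
                  check_loo: bool = True) -> list[MorrisResult]:
    """Iterative Morris screening on the toy model's 35 strain indices.

    Each round screens the currently active subset (excluded parameters held
    at their normalized reference), drops every parameter unimportant for
    all 7 indices x 5 segments, and repeats until a round drops nothing.
    The excluded set grows monotonically across rounds.
    """
    rng = np.random.default_rng() if rng is None else rng
    space: ParameterSpace = model.space
    mask = SubsetMask.full(space) if mask is None else mask
    rounds: list[MorrisResult] = []
    for _ in range(max_rounds):
        effects, attempts = collect_effects(model, mask, trajectory_budget, z, rng)
        mu = mu_star(effects)
        important = select_important(mu, mask.active)
        excluded = [n for n in mask.active if n not in important]
        result = MorrisResult(
            names=list(mask.active), mu_star=mu, per_trajectory_effects=effects,
            n_trajectories=effects.shape[0], n_attempted=attempts,
            important=[n for n in mask.active if n in important], excluded=excluded,
            loo_converged=loo_convergence(effects) if (check_loo and effects.shape[0] >= 2) else None,
        )
        rounds.append(result)
        if not excluded:
            break
        mask = mask.without(excluded)
    return rounds
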