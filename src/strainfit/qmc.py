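"""Sobol quasi-Monte Carlo exploration and diaphony-based identifiability.

A low-discrepancy Sobol point set samples the active parameter subspace;
every point is one forward-model run, whose fit error against each cohort
subject is recorded (crashed runs score +infinity).  For each subject, the
N_b best-fitting points are kept and, per parameter, their coordinates are
condensed into the diaphony

    d_i = | (1/N_b) sum_b exp(2 pi sqrt(-1) x_i^(b)) |

the modulus of the mean unit phasor: 0 for a homogeneously spread set (the
parameter does not constrain the fit), 1 when all best fits agree on one
value (the parameter is sharply identifiable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc as scipy_qmc

from .param_space import SubsetMask
from .strain_metrics import FitWindow, ObjectiveWeights, fit_window, total_error
from .toy_model import StrainTrace, ToyModel


def sobol_points(n: int, d: int) -> np.ndarray:
    """First n points of the unscrambled d-dimensional Sobol sequence.

    The all-zeros initial point is skipped, so the first returned point is
    (0.5, ..., 0.5).  Deterministic: no seed enters.
    """
    if n < 1 or d < 1:
        raise ValueError("need n >= 1 and d >= 1")
    sampler = scipy_qmc.Sobol(d=d, scramble=False)
    sampler.fast_forward(1)
    with warnings.catch_warnings():
        # balance warning for n not a power of two is expected here
        warnings.simplefilter("ignore", UserWarning)
        return sampler.random(n)


def diaphony(coords) -> float:
    """Modulus of the mean unit phasor of a coordinate sample (in [0, 1])."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("diaphony of an empty sample is undefined")
    return float(np.abs(np.mean(np.exp(2j * np.pi * coords))))


class CohortObjective:
    """Per-subject fit errors of one model evaluation, with cached fit windows.

    Callable with a point of the *active* subspace; returns the vector of
    E_SS values over the cohort (+infinity for crashed runs and for points
    outside the unit hypercube).
    """

    def __init__(self, model: ToyModel, mask: SubsetMask, subjects: list[StrainTrace],
                 weights: ObjectiveWeights = ObjectiveWeights()):
        if not subjects:
            raise ValueError("need at least one subject")
        self.model = model
        self.mask = mask
        self.subjects = subjects
        self.weights = weights
        self.windows: list[FitWindow] = [fit_window(s) for s in subjects]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def __call__(self, sub_point) -> np.ndarray:
        sub_point = np.asarray(sub_point, dtype=float)
        if np.any((sub_point < 0.0) | (sub_point > 1.0)):
            return np.full(self.n_subjects, np.inf)
        res = self.model.evaluate(self.mask.restrict(sub_point))
        if not res.ok:
            return np.full(self.n_subjects, np.inf)
        return np.array([
            total_error(res.trace, subj, self.weights, window=w)
            for subj, w in zip(self.subjects, self.windows)
        ])

    def single(self, subject_index: int):
        """Scalar objective for one subject (used to drive the optimizer)."""
        subj = self.subjects[subject_index]
        w = self.windows[subject_index]

        def objective(sub_point) -> float:
            sub_point = np.asarray(sub_point, dtype=float)
            if np.any((sub_point < 0.0) | (sub_point > 1.0)):
                return float("inf")
            res = self.model.evaluate(self.mask.restrict(sub_point))
            return total_error(res, subj, self.weights, window=w)

        return objective


@dataclass
class QmcResult:
    points: np.ndarray          # (N, d) normalized samples of the active subspace
    errors: np.ndarray          # (n_subjects, N) E_SS, +inf for crashes
    best_idx: list[np.ndarray]  # per subject, indices of the N_b lowest finite errors, ascending
    diaphony: pd.DataFrame      # parameters x subjects
    success_rate: float
    active: list[str]

    def best_points(self, subject_index: int) -> np.ndarray:
        return self.points[self.best_idx[subject_index]]

    def best_errors(self, subject_index: int) -> np.ndarray:
        return self.errors[subject_index, self.best_idx[subject_index]]

    def max_diaphony(self) -> pd.Series:
        """Per-parameter maximum diaphony over subjects (the reduction signal)."""
        return self.diaphony.max(axis=1)


def evaluate_cohort(points: np.ndarray, objective: CohortObjective,
                    n_best: int = 100) -> QmcResult:
    """Evaluate the model once per point and score it against every subject.

    The model run is shared across subjects (the cycle time is itself a
    sampled parameter, so one sweep serves all subjects); each subject then
    gets its own best-``n_best`` set and per-parameter diaphony.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    errors = np.empty((objective.n_subjects, n))
    ok = np.zeros(n, dtype=bool)
    for i, p in enumerate(points):
        e = objective(p)
        errors[:, i] = e
        ok[i] = np.isfinite(e).all()
    success_rate = float(ok.mean())
    if success_rate == 0.0:
        warnings.warn("no successful model evaluations; all fit errors are infinite")

    names = list(objective.mask.active)
    best_idx: list[np.ndarray] = []
    dia = np.full((len(names), objective.n_subjects), np.nan)
    for s in range(objective.n_subjects):
        finite = np.flatnonzero(np.isfinite(errors[s]))
        order = finite[np.argsort(errors[s, finite], kind="stable")]
        idx = order[: min(n_best, order.size)]
        best_idx.append(idx)
        if idx.size:
            for j in range(len(names)):
                dia[j, s] = diaphony(points[idx, j])
    table = pd.DataFrame(dia, index=names,
                         columns=[f"subject_{s:02d}" for s in range(objective.n_subjects)])
    return QmcResult(points=points, errors=errors, best_idx=best_idx,
                     diaphony=table, success_rate=success_rate, active=names)


def run_qmc(model: ToyModel, mask: SubsetMask, subjects: list[StrainTrace], *,
            n: int = 2 ** 14, n_best: int = 100,
            weights: ObjectiveWeights = ObjectiveWeights()) -> QmcResult:
    """Sobol sweep of the active subspace scored against a cohort."""
    objective = CohortObjective(model, mask, subjects, weights)
    return evaluate_cohort(sobol_points(n, mask.d), objective, n_best=n_best)
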