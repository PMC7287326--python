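"""Iterative subset reduction: qMC -> diaphony ranking -> omission -> PSO validation.

Each round samples the current subset with a Sobol sweep, ranks the active
parameters by their maximum diaphony over subjects (low diaphony = the best
fits do not constrain the parameter), proposes dropping the least
identifiable ones, and validates the proposal by re-fitting every subject
with PSO on both the old and the new subset.  A proposal is accepted when
the mean cohort fit error does not grow by more than a configured relative
tolerance; on rejection the omission batch is halved and retried.  The loop
stops when no reduction is accepted or the subset reaches a floor, and
returns a full audit trail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .param_space import SubsetMask
from .pso import PSOConfig, fit as pso_fit
from .qmc import CohortObjective, QmcResult, run_qmc
from .strain_metrics import ObjectiveWeights
from .toy_model import StrainTrace, ToyModel


@dataclass
class ReductionConfig:
    qmc_n: int = 2 ** 14
    n_best: int = 100
    omit_quantile: float = 0.25   # drop parameters below this quantile of max-diaphony
    tol: float = 0.5              # accepted when mean error grows by at most this factor
    tol_total: float = 1.0        # ... and by at most this factor over the whole run
    floor: int = 1                # minimum subset size
    max_rounds: int = 10
    pso: PSOConfig = field(default_factory=PSOConfig)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    groups: Mapping[str, str] | None = None  # optional all-or-none omission units


def rank_parameters(diaphony_table: pd.DataFrame, registry_order: Sequence[str]) -> list[str]:
    """Active parameters ordered ascending by max-over-subjects diaphony.

    Ties are broken by registry order.  Raises on missing entries.
    """
    if diaphony_table.isna().any().any():
        bad = diaphony_table.index[diaphony_table.isna().any(axis=1)].tolist()
        raise ValueError(f"diaphony table has missing entries for: {bad}")
    pos = {n: i for i, n in enumerate(registry_order)}
    maxd = diaphony_table.max(axis=1)
    return sorted(diaphony_table.index, key=lambda n: (maxd[n], pos[n]))


def propose_reduction(mask: SubsetMask, ranked: Sequence[str], k_omit: int,
                      groups: Mapping[str, str] | None = None) -> SubsetMask:
    """Mask omitting the k_omit least identifiable parameters (fixed at reference).

    With ``groups``, parameters sharing a group label are omitted all or
    none: the omission set is the union of the k_omit lowest-ranked whole
    units (a unit ranks by its least identifiable member).
    """
    if not 1 <= k_omit < mask.d:
        raise ValueError(f"k_omit must be in [1, {mask.d - 1}], got {k_omit}")
    if groups is None:
        omit = list(ranked[:k_omit])
    else:
        units: list[list[str]] = []
        seen: dict[str, int] = {}
        for name in ranked:  # units ordered by their lowest-ranked member
            label = groups.get(name)
            if label is None:
                units.append([name])
            elif label in seen:
                units[seen[label]].append(name)
            else:
                seen[label] = len(units)
                units.append([name])
        omit = []
        for unit in units[:k_omit]:
            omit.extend(unit)
        omit = omit[: mask.d - 1]  # never empty the subset
    return mask.without(omit)


def rv_stem_groups(names: Sequence[str]) -> dict[str, str]:
    """Group tissue parameters of the three RV free-wall segments by stem,
    so that e.g. the wall volumes of all three patches are omitted together."""
    out = {}
    for n in names:
        for seg in ("RV_apex", "RV_mid", "RV_base"):
            if n.endswith(f"_{seg}"):
                out[n] = f"rvfw:{n[: -len(seg) - 1]}"
    return out


def _pso_cohort_errors(model: ToyModel, mask: SubsetMask, subjects: list[StrainTrace],
                       seeds: list[np.ndarray], seed_errors: list[np.ndarray],
                       config: ReductionConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subject PSO best errors on one subset.

    The candidate seeds are ranked by their qMC errors, but the selected
    swarm seeds are re-evaluated under this subset's objective (the qMC
    errors may belong to a different embedding of the subspace).
    """
    objective = CohortObjective(model, mask, subjects, config.weights)
    errors = np.empty(len(subjects))
    for s in range(len(subjects)):
        obj = objective.single(s)
        order = np.argsort(seed_errors[s], kind="stable")[: config.pso.pop]
        pts = np.atleast_2d(seeds[s])[order]
        errs = [obj(p) for p in pts]
        _, fg, _ = pso_fit(obj, pts, errs, rng, config.pso)
        errors[s] = fg
    return errors


def validate_reduction(model: ToyModel, mask_before: SubsetMask, mask_after: SubsetMask,
                       subjects: list[StrainTrace], qmc_result: QmcResult,
                       config: ReductionConfig, rng: np.random.Generator,
                       errors_before: np.ndarray | None = None,
                       baseline_error: float | None = None):
    """PSO re-fit of every subject on both subsets; accept if errors stay similar.

    Swarms are seeded from the round's qMC best points (projected onto the
    reduced subset for ``mask_after``).  Returns
    ``(accepted, errors_before, errors_after)`` with acceptance iff
    mean(after) <= (1 + tol) * mean(before) and, when a ``baseline_error``
    from the start of the run is given, also
    mean(after) <= (1 + tol_total) * baseline_error — successive rounds may
    not quietly compound into a large total degradation.
    """
    seeds_b = [qmc_result.best_points(s) for s in range(len(subjects))]
    errs_b = [qmc_result.best_errors(s) for s in range(len(subjects))]
    if errors_before is None:
        errors_before = _pso_cohort_errors(model, mask_before, subjects, seeds_b, errs_b, config, rng)
    drop_cols = [mask_before.active.index(n) for n in mask_before.active
                 if n not in set(mask_after.active)]
    seeds_a = [np.delete(p, drop_cols, axis=1) for p in seeds_b]
    try:
        errors_after = _pso_cohort_errors(model, mask_after, subjects, seeds_a, errs_b, config, rng)
    except ValueError:  # no finite-error seeds on some subject: round failed
        errors_after = np.full(len(subjects), np.inf)
    accepted = bool(np.mean(errors_after) <= (1.0 + config.tol) * np.mean(errors_before))
    if baseline_error is not None:
        accepted = accepted and bool(
            np.mean(errors_after) <= (1.0 + config.tol_total) * baseline_error)
    return accepted, errors_before, errors_after


@dataclass
class RoundRecord:
    round: int
    subset_before: list[str]
    diaphony: pd.DataFrame
    success_rate: float
    omitted: list[str]
    subset_after: list[str]
    pso_errors_before: np.ndarray
    pso_errors_after: np.ndarray
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "subset_before": self.subset_before,
            "subset_after": self.subset_after,
            "omitted": self.omitted,
            "accepted": self.accepted,
            "qmc_success_rate": self.success_rate,
            "max_diaphony": self.diaphony.max(axis=1).to_dict(),
            "pso_errors_before": [float(e) for e in self.pso_errors_before],
            "pso_errors_after": [float(e) for e in self.pso_errors_after],
        }


@dataclass
class ReductionRecord:
    rounds: list[RoundRecord]
    final_mask: SubsetMask
    final_errors: np.ndarray | None = None

    @property
    def final_active(self) -> list[str]:
        return list(self.final_mask.active)

    def to_json(self, path) -> None:
        payload = {
            "final_subset": self.final_active,
            "final_errors": None if self.final_errors is None
            else [float(e) for e in self.final_errors],
            "rounds": [r.to_dict() for r in self.rounds],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_reduction(model: ToyModel, mask: SubsetMask, subjects: list[StrainTrace],
                  config: ReductionConfig | None = None,
                  rng: np.random.Generator | None = None) -> ReductionRecord:
    """The full reduction loop on an initial subset.

    Per round: Sobol qMC on the active subset, diaphony ranking, proposal of
    the below-quantile batch, PSO validation; rejected proposals retry with
    the batch halved.  Accepted subsets shrink strictly; the loop ends when
    nothing further is accepted, the floor is reached, or ``max_rounds``.
    """
    config = config or ReductionConfig()
    rng = np.random.default_rng() if rng is None else rng
    if mask.d == 0:
        raise ValueError("initial subset is empty")
    rounds: list[RoundRecord] = []
    errors_current: np.ndarray | None = None  # PSO errors on the current subset
    baseline: float | None = None             # mean PSO error of the initial subset

    for round_no in range(1, config.max_rounds + 1):
        if mask.d <= config.floor:
            break
        qr = run_qmc(model, mask, subjects, n=config.qmc_n, n_best=config.n_best,
                     weights=config.weights)
        ranked = rank_parameters(qr.diaphony, mask.space.names)
        maxd = qr.max_diaphony()
        threshold = float(np.quantile(maxd.values, config.omit_quantile))
        k = int((maxd.values <= threshold).sum())
        k = max(1, min(k, mask.d - config.floor, mask.d - 1))

        accepted_round = None
        while k >= 1:
            proposal = propose_reduction(mask, ranked, k, groups=config.groups)
            if proposal.d < config.floor:
                break
            accepted, errors_before, errors_after = validate_reduction(
                model, mask, proposal, subjects, qr, config, rng,
                errors_before=errors_current, baseline_error=baseline)
            errors_current = errors_before
            if baseline is None:
                baseline = float(np.mean(errors_before))
            record = RoundRecord(
                round=round_no, subset_before=list(mask.active), diaphony=qr.diaphony,
                success_rate=qr.success_rate, omitted=[n for n in mask.active
                                                      if n not in set(proposal.active)],
                subset_after=list(proposal.active), pso_errors_before=errors_before,
                pso_errors_after=errors_after, accepted=accepted)
            rounds.append(record)
            if accepted:
                accepted_round = record
                mask = proposal
                errors_current = errors_after
                break
            k //= 2
        if accepted_round is None:
            break
    return ReductionRecord(rounds=rounds, final_mask=mask, final_errors=errors_current)
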