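"""Virtual subjects: ground-truth parameters plus echo-like strain measurements.

Each subject is one draw of a ground-truth parameter point, pushed through
the forward model and degraded the way speckle-tracking longitudinal strain
measurements are: resampled to the echo frame rate (~60 Hz), additive
Gaussian noise, a slow linear baseline drift over the cycle, and re-zeroing
at QRS onset.  Three regional-abnormality archetypes mirror disease stages
of an RV cardiomyopathy cohort:

* ``concealed``   — near-reference tissue with mild basal heterogeneity;
* ``electrical``  — delayed activation of the RV basal segment;
* ``structural``  — reduced contractility and increased stiffness of the
                    RV basal and mid segments.

Ground truths are recorded so estimation pipelines can be scored against
them.  Draws landing in the model's non-physiological crash region are
rejected and redrawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .toy_model import ModelResult, StrainTrace, ToyModel

Stage = Literal["concealed", "electrical", "structural"]
STAGES: tuple[Stage, ...] = ("concealed", "electrical", "structural")

#: stage frequencies of the emulated cohort (6 concealed : 4 electrical : 5 structural)
DEFAULT_STAGE_MIX: dict[str, float] = {"concealed": 6 / 15, "electrical": 4 / 15, "structural": 5 / 15}


@dataclass
class NoiseConfig:
    frame_rate: float = 60.0        # Hz, echo sampling
    noise_sd: float = 0.5           # % strain, i.i.d. Gaussian per sample
    drift_per_cycle: float = 1.0    # % strain; slope drawn uniform in +-this, per cycle


@dataclass
class VirtualSubject:
    subject_id: str
    stage: Stage
    truth: np.ndarray               # full-space normalized ground truth
    measured: StrainTrace

    def truth_of(self, model: ToyModel, name: str) -> float:
        return float(self.truth[model.space.index(name)])


def _stage_sequence(n: int, mix: dict[str, float]) -> list[Stage]:
    """Deterministic largest-remainder allocation of stages to n subjects."""
    total = sum(mix.values())
    quotas = {s: n * mix.get(s, 0.0) / total for s in STAGES}
    counts = {s: int(np.floor(q)) for s, q in quotas.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(STAGES, key=lambda s: quotas[s] - counts[s], reverse=True)
    for s in by_frac[:remainder]:
        counts[s] += 1
    seq: list[Stage] = []
    for s in STAGES:
        seq.extend([s] * counts[s])
    return seq[:n]


def _draw_truth(model: ToyModel, stage: Stage, rng: np.random.Generator,
                jitter_sd: float = 0.05) -> np.ndarray:
    """One normalized ground-truth point for a stage archetype."""
    space = model.space
    x = space.reference_normalized.copy()
    influential = [space.index(n) for n in model.influential_names]
    x[influential] += rng.normal(0.0, jitter_sd, size=len(influential))

    def shift(name: str, lo: float, hi: float) -> None:
        if name in space:
            x[space.index(name)] += rng.uniform(lo, hi)

    if stage == "concealed":
        # mild basal heterogeneity only
        shift("SfAct_RV_base", -0.12, -0.04)
    elif stage == "electrical":
        shift("dT_RV_base", 0.35, 0.55)  # basal activation delayed ~40-65 ms
    elif stage == "structural":
        # disease staging is progressive: structural disease also carries the
        # electrical phenotype (delayed basal activation) on top of reduced
        # contractility and increased passive stiffness
        for seg in ("RV_base", "RV_mid"):
            shift(f"SfAct_{seg}", -0.45, -0.30)
            shift(f"k_lin_{seg}", 0.08, 0.18)
        shift("dT_RV_base", 0.40, 0.60)  # delayed ~45-70 ms
    return np.clip(x, 0.02, 0.98)


def measure(result: ModelResult, noise: NoiseConfig, rng: np.random.Generator) -> StrainTrace:
    """Degrade a model trace into an echo-like measurement.

    Resamples to the frame interval, adds Gaussian noise and a linear drift,
    and re-references so strain is exactly zero at QRS onset.
    """
    if not result.ok:
        raise ValueError("cannot measure a crashed simulation")
    trace = result.trace
    dt = 1.0 / noise.frame_rate
    n = int(np.floor(trace.T / dt + 1e-9))
    t = np.arange(n + 1) * dt
    i_qrs = int(np.argmin(np.abs(t - trace.t_qrs)))
    strain: dict[str, np.ndarray] = {}
    for seg, y in trace.strain.items():
        ym = np.interp(t, trace.t, y)
        if noise.noise_sd > 0:
            eps = rng.normal(0.0, noise.noise_sd, size=ym.shape)
            eps[i_qrs] = 0.0  # the reference frame is exactly zero by construction
            ym = ym + eps
        if noise.drift_per_cycle > 0:
            slope = rng.uniform(-noise.drift_per_cycle, noise.drift_per_cycle)
            ym = ym + slope * (t - trace.t_qrs) / trace.T
        ym = ym - ym[i_qrs]
        strain[seg] = ym
    return StrainTrace(t=t, strain=strain, t_qrs=trace.t_qrs, t_pvc=trace.t_pvc, T=trace.T)


def make_cohort(model: ToyModel, n_subjects: int, *,
                stage_mix: dict[str, float] | None = None,
                noise: NoiseConfig | None = None,
                rng: np.random.Generator | None = None,
                max_redraws: int = 100) -> list[VirtualSubject]:
    """Seeded cohort of virtual subjects with recorded ground truths."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng() if rng is None else rng
    stages = _stage_sequence(n_subjects, stage_mix or DEFAULT_STAGE_MIX)
    subjects: list[VirtualSubject] = []
    for i, stage in enumerate(stages):
        for _ in range(max_redraws):
            truth = _draw_truth(model, stage, rng)
            if not model.is_crashed(truth):
                break
        else:
            raise RuntimeError("could not draw a non-crashing ground truth")
        measured = measure(model.evaluate(truth), noise, rng)
        subjects.append(VirtualSubject(subject_id=f"subject_{i:02d}", stage=stage,
                                       truth=truth, measured=measured))
    return subjects


def save_ground_truth(subjects: Sequence[VirtualSubject], model: ToyModel, path) -> None:
    """Ground-truth JSON: per subject, stage and normalized truth by parameter name."""
    payload = [
        {
            "subject_id": s.subject_id,
            "stage": s.stage,
            "truth": {n: float(v) for n, v in zip(model.space.names, s.truth)},
        }
        for s in subjects
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
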