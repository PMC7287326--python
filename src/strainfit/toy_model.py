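"""Bundled phenomenological forward model of regional ventricular strain.

This is a deliberately small stand-in for a full lumped-parameter heart
model.  It reproduces the regional strain phenomenology needed to exercise
screening, sampling and optimization — pre-stretch of weak or late-activated
segments, reduced peak strain, post-systolic shortening — via an
equal-tension coupling of the three right-ventricular free-wall segments:

* each segment obeys ``F(t) = k_s (u_s(t) - p_s) + c_s a_s(t)`` with
  ``u_s`` the segment strain (%), ``k_s`` a stiffness, ``p_s`` a pre-stretch
  offset, ``c_s`` a contractility, and ``a_s`` a ``sin^2`` activation pulse
  starting at the segment's activation time;
* the common wall tension ``F(t)`` is the unique value for which the mean of
  the three RV segment strains equals a prescribed global shortening
  waveform ``G(t)`` (raised-cosine pulse supported on ``[t_qrs, t_pvc]``,
  amplitude scaled by a cardiac-output-like factor);
* the septum and LV free wall are single segments driven by the same
  tension ``F(t)`` with their own parameters.

Strain is engineering strain in percent, re-referenced to zero at QRS onset;
negative values mean shortening.  A corner of the parameter hypercube (very
low stiffness combined with very high contractility) is declared
non-physiological and returns a *crashed* result, emulating forward models
whose numerics fail there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .param_space import ParameterSpace, WALL_SEGMENTS

RV_SEGMENTS = ("RV_apex", "RV_mid", "RV_base")

#: physical fallback values used when a registry does not carry a parameter
_DEFAULTS = {
    "SfAct": 120.0,     # kPa
    "k_lin": 10.0,      # kPa
    "dT": 0.0,          # s
    "Ls0": 1.90,        # um
    "av_delay": 0.12,   # s
    "rel_systole": 0.35,
    "cycle_time": 0.85,  # s
    "cardiac_output": 5.0,  # L/min
}


@dataclass
class StrainTrace:
    """Per-segment strain on a uniform time grid plus cycle event times."""

    t: np.ndarray                      # seconds, uniform grid spanning [0, T]
    strain: dict[str, np.ndarray]      # percent engineering strain per segment
    t_qrs: float
    t_pvc: float
    T: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_qrs < self.t_pvc < self.T + 1e-12):
            raise ValueError(
                f"event times must satisfy 0 <= t_qrs < t_pvc < T, got "
                f"({self.t_qrs}, {self.t_pvc}, {self.T})"
            )

    @property
    def segments(self) -> list[str]:
        return list(self.strain)

    def value_at(self, segment: str, time: float) -> float:
        """Linearly interpolated strain of one segment at an arbitrary time."""
        return float(np.interp(time, self.t, self.strain[segment]))

    def global_rv(self) -> np.ndarray:
        """Global RV free-wall strain: unweighted mean of the three RV segments."""
        return np.mean([self.strain[s] for s in RV_SEGMENTS], axis=0)


@dataclass
class ModelResult:
    status: Literal["ok", "crashed"]
    trace: StrainTrace | None = None

    def __post_init__(self) -> None:
        if self.status == "crashed" and self.trace is not None:
            raise ValueError("crashed results carry no trace")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class ToyModelConfig:
    dt: float = 0.002                   # s, sampling step of the output grid
    base_amplitude: float = 20.0        # % peak global shortening at reference output
    prestretch_per_um: float = 20.0     # % strain offset per um of Ls0 above reference
    ls0_ref: float = 1.90               # um
    co_ref: float = 5.0                 # L/min, cardiac output normalization
    # crash corner, in normalized coordinates over the wall-segment tissue params
    crash_k_lin_below: float = 0.05
    crash_sfact_above: float = 0.97


class ToyModel:
    """Forward model: normalized parameter point -> per-segment strain traces.

    Evaluation is pure and deterministic.  Registry parameters the model does
    not read (all ``aux_*`` placeholders, plus tissue parameters other than
    contractility, linear stiffness, activation delay and zero-stress
    sarcomere length) are genuine no-ops, so screening should flag them as
    unimportant.
    """

    #: per-segment parameter stems that influence the output
    TISSUE_USED = ("SfAct", "k_lin", "dT", "Ls0")
    #: global parameters that influence the output
    GLOBAL_USED = ("av_delay", "rel_systole", "cycle_time", "cardiac_output")

    def __init__(self, space: ParameterSpace, config: ToyModelConfig | None = None):
        self.space = space
        self.config = config or ToyModelConfig()
        # name -> registry index (or None when the registry lacks the
        # parameter, in which case the physical default is used)
        self._idx: dict[str, int | None] = {}
        self._default: dict[str, float] = {}
        for seg in WALL_SEGMENTS:
            for stem in self.TISSUE_USED:
                n = f"{stem}_{seg}"
                self._idx[n] = space.index(n) if n in space else None
                self._default[n] = _DEFAULTS[stem]
        for n in self.GLOBAL_USED:
            self._idx[n] = space.index(n) if n in space else None
            self._default[n] = _DEFAULTS[n]

    # ------------------------------------------------------------------ helpers
    @property
    def influential_names(self) -> list[str]:
        """Registry parameters that actually enter the model equations."""
        return [n for n, i in self._idx.items() if i is not None]

    def _value(self, phys: np.ndarray, name: str) -> float:
        i = self._idx[name]
        if i is None:
            return self._default[name]
        return float(phys[i])

    def _check_point(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.space.D,):
            raise ValueError(f"point must have length {self.space.D}, got shape {x.shape}")
        if np.any((x < 0.0) | (x > 1.0)):
            raise ValueError("point outside the unit hypercube [0, 1]^D")
        return x

    def is_crashed(self, x: Sequence[float]) -> bool:
        """Non-physiology predicate on normalized coordinates.

        Crashes when the softest wall (minimum normalized linear stiffness)
        is extremely soft while the strongest wall (maximum normalized
        contractility) is extremely strong — a corner covering a few percent
        of the hypercube.
        """
        x = np.asarray(x, dtype=float)
        k_idx = [self._idx[f"k_lin_{s}"] for s in WALL_SEGMENTS]
        c_idx = [self._idx[f"SfAct_{s}"] for s in WALL_SEGMENTS]
        k_idx = [i for i in k_idx if i is not None]
        c_idx = [i for i in c_idx if i is not None]
        if not k_idx or not c_idx:
            return False
        return bool(
            np.min(x[k_idx]) < self.config.crash_k_lin_below
            and np.max(x[c_idx]) > self.config.crash_sfact_above
        )

    def event_times(self, x: Sequence[float]) -> tuple[float, float, float]:
        """(t_qrs, t_pvc, T): QRS onset (0 by convention), pulmonary valve closure, cycle time."""
        x = self._check_point(x)
        phys = self.space.denormalize(x)
        T = self._value(phys, "cycle_time")
        av = self._value(phys, "av_delay")
        t_sys = self._value(phys, "rel_systole") * T
        return 0.0, av + t_sys, T

    # ------------------------------------------------------------------ forward
    def evaluate(self, x: Sequence[float]) -> ModelResult:
        x = self._check_point(x)
        if self.is_crashed(x):
            return ModelResult(status="crashed")
        phys = self.space.denormalize(x)
        cfg = self.config

        T = self._value(phys, "cycle_time")
        av = self._value(phys, "av_delay")
        t_sys = self._value(phys, "rel_systole") * T
        t_pvc = av + t_sys
        co_factor = self._value(phys, "cardiac_output") / cfg.co_ref
        amplitude = cfg.base_amplitude * co_factor

        n = int(round(T / cfg.dt))
        t = np.linspace(0.0, T, n + 1)

        # global RV shortening waveform: smooth pulse supported on
        # [av_delay, t_pvc] (isovolumic phase shows no net shortening) whose
        # peak sits at 80% of ejection — shortening accumulates through
        # ejection and recovers quickly around pulmonary valve closure
        s = np.clip((t - av) / (t_pvc - av), 0.0, 1.0)
        bump = s ** 4 * (1.0 - s)
        g = -amplitude * bump / (0.8 ** 4 * 0.2)

        def seg_params(seg: str) -> tuple[float, float, float, float]:
            c = self._value(phys, f"SfAct_{seg}")
            k = self._value(phys, f"k_lin_{seg}")
            p = cfg.prestretch_per_um * (self._value(phys, f"Ls0_{seg}") - cfg.ls0_ref)
            dT = self._value(phys, f"dT_{seg}")
            return c, k, p, dT

        def activation(dT: float) -> np.ndarray:
            t_act = av + dT
            phase = (t - t_act) / t_sys
            a = np.sin(np.pi * np.clip(phase, 0.0, 1.0)) ** 2
            a[(phase < 0.0) | (phase > 1.0)] = 0.0
            return a

        rv = [seg_params(s) for s in RV_SEGMENTS]
        rv_act = [activation(dT) for (_, _, _, dT) in rv]
        inv_k = np.array([1.0 / k for (_, k, _, _) in rv])
        p_bar = np.mean([p for (_, _, p, _) in rv])
        drive = np.mean([c * a / k for (c, k, _, _), a in zip(rv, rv_act)], axis=0)
        # common tension making mean RV strain equal G(t)
        F = (g - p_bar + drive) / np.mean(inv_k)

        strain: dict[str, np.ndarray] = {}
        for seg, (c, k, p, _), a in zip(RV_SEGMENTS, rv, rv_act):
            strain[seg] = p + (F - c * a) / k
        for seg in ("IVS", "LVfw"):
            c, k, p, dT = seg_params(seg)
            strain[seg] = p + (F - c * activation(dT)) / k

        # engineering strain referenced at QRS onset (t = 0)
        for seg in strain:
            strain[seg] = strain[seg] - strain[seg][0]

        return ModelResult(status="ok", trace=StrainTrace(t=t, strain=strain, t_qrs=0.0, t_pvc=t_pvc, T=T))
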