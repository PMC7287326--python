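"""Strain-curve morphology indices and the area-based fit error.

Seven indices summarise the morphology of one segment's strain curve:
times to 10/50/90% of total shortening, pre-stretch, systolic strain
(strain at pulmonary valve closure), post-systolic strain and peak strain.
"Total shortening" is measured from the early pre-stretch maximum down to
the peak (most negative) strain.

The fit error between a modelled and a measured trace is the sum over the
five wall segments of the time-integrated squared strain difference over a
fit window — QRS onset up to 50% relaxation of the global RV free-wall
strain — plus a penalty on the cycle-time mismatch:

    E_SS = alpha * sum_seg A_seg^2 + beta * (T_model - T_meas)^2,
    A_seg^2 = integral over window of (eps_model - eps_meas)^2 dt

with alpha = 1 /s and beta = 0.1 /s^2 by default.  The window end is taken
toward the end-of-cycle strain value rather than zero, which keeps the rule
well defined for measurements with baseline drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .toy_model import ModelResult, StrainTrace

SEGMENTS = ("RV_apex", "RV_mid", "RV_base", "IVS", "LVfw")
INDEX_NAMES = ("t10", "t50", "t90", "prestretch", "systolic_strain",
               "post_systolic_strain", "peak_strain")

#: resampling step (s) for area integrals, matching the model output grid
RESAMPLE_DT = 0.002

_FLAT_TOL = 1e-9  # % strain; spans below this are treated as degenerate


@dataclass(frozen=True)
class StrainIndices:
    t10: float
    t50: float
    t90: float
    prestretch: float
    systolic_strain: float
    post_systolic_strain: float
    peak_strain: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INDEX_NAMES], dtype=float)


@dataclass(frozen=True)
class FitWindow:
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"fit window must have t_start < t_end, got [{self.t_start}, {self.t_end}]")


@dataclass(frozen=True)
class ObjectiveWeights:
    alpha: float = 1.0   # 1/s
    beta: float = 0.1    # 1/s^2

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta >= 0):
            raise ValueError("require alpha > 0 and beta >= 0")


def _first_crossing_below(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First time at which y falls to or below `level`, linearly interpolated."""
    below = y <= level
    if not below.any():
        return float(t[-1])
    i = int(np.argmax(below))
    if i == 0 or y[i - 1] == y[i]:
        return float(t[i])
    frac = (y[i - 1] - level) / (y[i - 1] - y[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extract_indices(trace: StrainTrace, segment: str, t_pvc: float | None = None) -> StrainIndices:
    """The seven morphology indices of one segment's strain curve.

    Times are reported relative to QRS onset.  A flat curve (zero total
    shortening span) yields the degenerate convention: all times 0 and the
    ``degenerate`` flag set.
    """
    if segment not in trace.strain:
        raise ValueError(f"segment {segment!r} not present in trace")
    if t_pvc is None:
        t_pvc = trace.t_pvc
    sel = trace.t >= trace.t_qrs - 1e-12
    t = trace.t[sel]
    y = trace.strain[segment][sel]

    i_peak = int(np.argmin(y))
    peak = float(y[i_peak])
    prestretch = max(0.0, float(np.max(y[: i_peak + 1])))
    span = prestretch - peak
    systolic = float(np.interp(t_pvc, t, y))

    if span < _FLAT_TOL:
        return StrainIndices(0.0, 0.0, 0.0, prestretch, systolic,
                             systolic - peak, peak, degenerate=True)

    times = [_first_crossing_below(t, y, prestretch - frac * span) - trace.t_qrs
             for frac in (0.10, 0.50, 0.90)]
    return StrainIndices(times[0], times[1], times[2], prestretch,
                         systolic, systolic - peak, peak)


def indices_vector(trace: StrainTrace, t_pvc: float | None = None) -> np.ndarray:
    """All 7 indices x 5 segments flattened segment-major (length 35)."""
    return np.concatenate([extract_indices(trace, seg, t_pvc).as_array() for seg in SEGMENTS])


def indices_vector_names() -> list[str]:
    return [f"{seg}.{idx}" for seg in SEGMENTS for idx in INDEX_NAMES]


def fit_window(measured: StrainTrace) -> FitWindow:
    """Fit window of a measured trace: QRS onset to 50% relaxation of global RV strain.

    The global RV free-wall strain is the mean of the three RV segments.
    The window ends at the first time after the global peak at which the
    curve has recovered half-way toward its end-of-cycle value; curves that
    never recover that far end the window at cycle end (with a warning).
    """
    g = measured.global_rv()
    t = measured.t
    i_peak = int(np.argmin(g))
    peak = float(g[i_peak])
    end_value = float(g[-1])
    level = peak + 0.5 * (end_value - peak)

    if i_peak == len(t) - 1:  # still shortening at cycle end: no relaxation at all
        warnings.warn("global RV strain never reaches 50% relaxation; fit window ends at cycle end")
        return FitWindow(measured.t_qrs, float(t[-1]))
    tr, gr = t[i_peak:], g[i_peak:]
    above = gr >= level
    if not above.any():
        warnings.warn("global RV strain never reaches 50% relaxation; fit window ends at cycle end")
        return FitWindow(measured.t_qrs, float(t[-1]))
    i = int(np.argmax(above))
    if i == 0 or gr[i - 1] == gr[i]:
        t_end = float(tr[i])
    else:
        frac = (level - gr[i - 1]) / (gr[i] - gr[i - 1])
        t_end = float(tr[i - 1] + frac * (tr[i] - tr[i - 1]))
    return FitWindow(measured.t_qrs, t_end)


def segment_area_error(t_model: np.ndarray, eps_model: np.ndarray,
                       t_meas: np.ndarray, eps_meas: np.ndarray,
                       window: FitWindow, dt: float = RESAMPLE_DT) -> float:
    """A_seg^2: integrated squared strain difference over the window (%^2 s).

    Both curves are linearly interpolated onto a common uniform grid over
    the window and integrated with the trapezoid rule.
    """
    for t, label in ((t_model, "model"), (t_meas, "measured")):
        if window.t_start < t[0] - 1e-9 or window.t_end > t[-1] + 1e-9:
            raise ValueError(
                f"fit window [{window.t_start}, {window.t_end}] outside the "
                f"{label} series support [{t[0]}, {t[-1]}]"
            )
    length = window.t_end - window.t_start
    grid = np.linspace(window.t_start, window.t_end, max(2, int(round(length / dt)) + 1))
    diff = np.interp(grid, t_model, eps_model) - np.interp(grid, t_meas, eps_meas)
    return float(np.trapezoid(diff ** 2, grid))


def total_error(model: ModelResult | StrainTrace, measured: StrainTrace,
                weights: ObjectiveWeights = ObjectiveWeights(),
                window: FitWindow | None = None) -> float:
    """E_SS: weighted sum of the five segment area errors plus the cycle-time penalty.

    The fit window is derived from the *measured* trace (pass ``window`` to
    reuse a precomputed one).  A crashed model result scores +infinity.
    """
    if isinstance(model, ModelResult):
        if not model.ok:
            return float("inf")
        model = model.trace
    missing = [s for s in SEGMENTS if s not in model.strain or s not in measured.strain]
    if missing:
        raise ValueError(f"missing segments: {missing}")
    if window is None:
        window = fit_window(measured)
    # clip to the model's support: model cycles shorter than the window are
    # penalised through the cycle-time term, not by extrapolation
    w = FitWindow(window.t_start, min(window.t_end, float(model.t[-1])))
    area = sum(
        segment_area_error(model.t, model.strain[s], measured.t, measured.strain[s], w)
        for s in SEGMENTS
    )
    return weights.alpha * area + weights.beta * (model.T - measured.T) ** 2
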