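"""Parameter registry, [0, 1] normalization, and subset masks.

All optimization, screening and sampling in this package operates on
dimensionless coordinates: each physical parameter domain ``[lower, upper]``
is mapped affinely onto ``[0, 1]``.  A :class:`SubsetMask` restricts the
search to a subset of parameters, holding the excluded ones at fixed
normalized values (by default their normalized reference value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

GROUPS = ("RV_apex", "RV_mid", "RV_base", "IVS", "LVfw", "global")
#: the five ventricular wall segments (RV free wall split in three, septum, LV free wall)
WALL_SEGMENTS = GROUPS[:5]


@dataclass(frozen=True)
class ParameterDef:
    """One model parameter: physical bounds, reference value, and wall group."""

    name: str
    group: str
    lower: float
    upper: float
    reference: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for parameter {self.name!r}")
        if not self.lower < self.upper:
            raise ValueError(f"parameter {self.name!r}: lower must be < upper")
        if not (self.lower <= self.reference <= self.upper):
            raise ValueError(f"parameter {self.name!r}: reference outside [lower, upper]")


class ParameterSpace:
    """Ordered, immutable registry of parameters.

    Iteration order is stable: the order in which definitions were supplied.
    The default registry (:func:`build_default_registry`) is ordered
    group-major (RV_apex, RV_mid, RV_base, IVS, LVfw, global) and
    alphabetically within each group, so two constructions are identical.
    """

    def __init__(self, params: Iterable[ParameterDef]):
        self.params: tuple[ParameterDef, ...] = tuple(params)
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dupes}")
        self._index: dict[str, int] = {p.name: i for i, p in enumerate(self.params)}
        self._lower = np.array([p.lower for p in self.params], dtype=float)
        self._upper = np.array([p.upper for p in self.params], dtype=float)
        self._ref = np.array([p.reference for p in self.params], dtype=float)

    # -- basic container protocol -------------------------------------------------
    @property
    def D(self) -> int:
        return len(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def __iter__(self):
        return iter(self.params)

    def __getitem__(self, name: str) -> ParameterDef:
        return self.params[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def index(self, name: str) -> int:
        return self._index[name]

    def group_names(self, group: str) -> list[str]:
        return [p.name for p in self.params if p.group == group]

    # -- normalization ------------------------------------------------------------
    def normalize(self, physical: Sequence[float]) -> np.ndarray:
        """Map a physical parameter vector onto the unit hypercube.

        Raises ``ValueError`` naming the offending parameter when a value
        falls outside its ``[lower, upper]`` domain.
        """
        phys = np.asarray(physical, dtype=float)
        if phys.shape != (self.D,):
            raise ValueError(f"expected vector of length {self.D}, got shape {phys.shape}")
        bad = np.flatnonzero((phys < self._lower) | (phys > self._upper))
        if bad.size:
            p = self.params[bad[0]]
            raise ValueError(
                f"value {phys[bad[0]]!r} for parameter {p.name!r} outside "
                f"[{p.lower}, {p.upper}]"
            )
        return (phys - self._lower) / (self._upper - self._lower)

    def denormalize(self, x: Sequence[float]) -> np.ndarray:
        """Inverse of :meth:`normalize`: unit-hypercube point to physical values."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.D,):
            raise ValueError(f"expected vector of length {self.D}, got shape {x.shape}")
        if np.any((x < 0.0) | (x > 1.0)):
            i = int(np.flatnonzero((x < 0.0) | (x > 1.0))[0])
            raise ValueError(f"normalized coordinate {x[i]!r} for {self.params[i].name!r} outside [0, 1]")
        return self._lower + x * (self._upper - self._lower)

    @property
    def reference_normalized(self) -> np.ndarray:
        return self.normalize(self._ref)

    # -- YAML round trip ----------------------------------------------------------
    def to_yaml(self, path) -> None:
        entries = [
            dict(name=p.name, group=p.group, lower=float(p.lower), upper=float(p.upper),
                 reference=float(p.reference), units=p.units)
            for p in self.params
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(entries, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSpace":
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        return cls(ParameterDef(**e) for e in entries)


@dataclass
class SubsetMask:
    """Active-parameter mask over a registry.

    ``active`` lists the free parameter names (in registry order);
    ``fixed_values`` pins every other registry parameter at a normalized value.
    Together they must partition the registry.
    """

    space: ParameterSpace
    active: list[str]
    fixed_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [n for n in list(self.active) + list(self.fixed_values) if n not in self.space]
        if unknown:
            raise ValueError(f"unknown parameter names in mask: {unknown}")
        overlap = set(self.active) & set(self.fixed_values)
        if overlap:
            raise ValueError(f"parameters both active and fixed: {sorted(overlap)}")
        missing = set(self.space.names) - set(self.active) - set(self.fixed_values)
        if missing:
            raise ValueError(f"mask does not cover parameters: {sorted(missing)}")
        # keep registry order for reproducibility
        order = {n: i for i, n in enumerate(self.space.names)}
        self.active = sorted(self.active, key=order.__getitem__)

    @classmethod
    def full(cls, space: ParameterSpace) -> "SubsetMask":
        return cls(space, active=list(space.names))

    @classmethod
    def from_active(cls, space: ParameterSpace, active: Iterable[str],
                    fixed_at: Mapping[str, float] | None = None) -> "SubsetMask":
        """Mask with the given active set; others fixed at normalized reference."""
        active = list(active)
        ref = space.reference_normalized
        fixed = {n: float(ref[space.index(n)]) for n in space.names if n not in set(active)}
        if fixed_at:
            for k, v in fixed_at.items():
                if k in fixed:
                    fixed[k] = float(v)
        return cls(space, active=active, fixed_values=fixed)

    @property
    def d(self) -> int:
        """Dimension of the active subspace."""
        return len(self.active)

    @property
    def active_indices(self) -> np.ndarray:
        return np.array([self.space.index(n) for n in self.active], dtype=int)

    def restrict(self, sub_point: Sequence[float]) -> np.ndarray:
        """Embed a point of the active subspace into the full normalized space."""
        sub = np.asarray(sub_point, dtype=float)
        if sub.shape != (self.d,):
            raise ValueError(f"expected sub-point of length {self.d}, got shape {sub.shape}")
        full = np.empty(self.space.D, dtype=float)
        for name, value in self.fixed_values.items():
            full[self.space.index(name)] = value
        full[self.active_indices] = sub
        return full

    def project(self, full_point: Sequence[float]) -> np.ndarray:
        """Extract the active coordinates of a full-space point."""
        full = np.asarray(full_point, dtype=float)
        return full[self.active_indices]

    def without(self, names: Iterable[str], fixed_at: Mapping[str, float] | None = None) -> "SubsetMask":
        """A smaller mask with ``names`` moved to the fixed set (at reference by default)."""
        drop = set(names)
        unknown = drop - set(self.active)
        if unknown:
            raise ValueError(f"cannot drop non-active parameters: {sorted(unknown)}")
        ref = self.space.reference_normalized
        fixed = dict(self.fixed_values)
        for n in drop:
            fixed[n] = float(ref[self.space.index(n)])
        if fixed_at:
            fixed.update({k: float(v) for k, v in fixed_at.items() if k in drop})
        return SubsetMask(self.space, active=[n for n in self.active if n not in drop],
                          fixed_values=fixed)


# ---------------------------------------------------------------------------
# Default registry
# ---------------------------------------------------------------------------

# Twelve tissue parameters per wall segment.  Bounds are package fixtures:
# they are NOT a published table, only a plausible physical scale for each
# quantity.  Tissue properties of the RV mid and basal segments get wide
# ranges (the region where arrhythmogenic disease expresses); all other
# segments get narrow ranges around the same reference.
#               name                  units    narrow(lo, hi)      wide(lo, hi)       ref
_TISSUE_PARAMS = [
    ("SfAct",              "kPa",    (90.0, 150.0),   (20.0, 200.0),   120.0),  # contractility
    ("k1",                 "-",      (8.0, 12.0),     (4.0, 20.0),     10.0),   # passive stiffness exponent
    ("dT",                 "s",      (-0.01, 0.03),   (-0.03, 0.09),   0.0),    # activation delay
    ("AmRef",              "cm2",    (80.0, 120.0),   (60.0, 140.0),   100.0),  # wall reference area
    ("VWall",              "mL",     (60.0, 90.0),    (40.0, 110.0),   75.0),   # wall volume
    ("tau_contract",       "s",      (0.08, 0.12),    (0.05, 0.20),    0.10),   # contraction time constant
    ("tau_relax",          "s",      (0.04, 0.06),    (0.02, 0.12),    0.05),   # relaxation time constant
    ("v_shorten_max",      "um/s",   (6.0, 8.0),      (3.0, 12.0),     7.0),    # unloaded shortening velocity
    ("Ls0",                "um",     (1.85, 1.95),    (1.75, 2.05),    1.90),   # zero-stress sarcomere length
    ("k_lin",              "kPa",    (6.0, 14.0),     (2.0, 40.0),     10.0),   # linear stiffness component
    ("aux_a",              "-",      (0.4, 0.6),      (0.0, 1.0),      0.5),    # placeholder (no model effect)
    ("aux_b",              "-",      (0.4, 0.6),      (0.0, 1.0),      0.5),    # placeholder (no model effect)
]

# Six named global / non-ventricular parameters; the remainder of the 50 are
# placeholders standing in for circulation, valve and atrial parameters.
_GLOBAL_PARAMS = [
    ("heart_rate",        "1/min",  (50.0, 100.0),   70.0),
    ("cardiac_output",    "L/min",  (3.5, 6.5),      5.0),
    ("av_delay",          "s",      (0.08, 0.18),    0.12),
    ("rel_systole",       "-",      (0.28, 0.42),    0.35),
    ("cycle_time",        "s",      (0.6, 1.2),      0.85),
    ("map",               "mmHg",   (70.0, 110.0),   92.0),
]
_N_GLOBAL_PLACEHOLDERS = 44  # -> 50 global parameters in total


def build_default_registry() -> ParameterSpace:
    """The default 110-parameter registry.

    12 tissue parameters for each of the five wall segments (60 ventricular
    parameters) plus 50 global / non-ventricular parameters.  Construction is
    deterministic: group-major order, alphabetical within each group.
    """
    defs: list[ParameterDef] = []
    wide_groups = {"RV_mid", "RV_base"}
    for group in WALL_SEGMENTS:
        rows = []
        for name, units, narrow, wide, ref in _TISSUE_PARAMS:
            lo, hi = wide if group in wide_groups else narrow
            rows.append(ParameterDef(f"{name}_{group}", group, lo, hi, ref, units))
        defs.extend(sorted(rows, key=lambda p: p.name))
    rows = [ParameterDef(name, "global", lo, hi, ref, units)
            for name, units, (lo, hi), ref in _GLOBAL_PARAMS]
    rows += [ParameterDef(f"aux_global_{i:02d}", "global", 0.0, 1.0, 0.5, "-")
             for i in range(_N_GLOBAL_PLACEHOLDERS)]
    defs.extend(sorted(rows, key=lambda p: p.name))
    return ParameterSpace(defs)


def build_demo_registry() -> ParameterSpace:
    """A 20-parameter desk-scale registry for demos and end-to-end runs.

    Sixteen parameters drive the bundled toy model (regional contractility,
    linear stiffness and activation delay, plus the global timing and output
    parameters); four are inert placeholders that screening and reduction
    should discard.  Bounds follow the same wide/narrow convention as the
    full registry.
    """
    full = build_default_registry()
    names = [
        "SfAct_RV_apex", "k_lin_RV_apex", "dT_RV_apex",
        "SfAct_RV_mid", "k_lin_RV_mid", "dT_RV_mid",
        "SfAct_RV_base", "k_lin_RV_base", "dT_RV_base",
        "SfAct_IVS", "k_lin_IVS",
        "SfAct_LVfw",
        "av_delay", "cardiac_output", "cycle_time", "rel_systole",
        # inert placeholders
        "aux_a_RV_mid", "aux_b_RV_base", "aux_global_00", "aux_global_01",
    ]
    return ParameterSpace(full[n] for n in names)
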