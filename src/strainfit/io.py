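"""Strain-trace CSV dialect.

One file per subject: a comment header carrying the cycle event times,
then columns ``time_s, rv_apex, rv_mid, rv_base, ivs, lvfw`` (seconds and
percent strain)::

    # t_qrs=0.0
    # t_pvc=0.42
    # T=0.85
    time_s,rv_apex,rv_mid,rv_base,ivs,lvfw
    0.000,0.00,0.00,0.00,0.00,0.00
    ...

Readers validate the trace invariants; strain that is not zero at QRS onset
(beyond rounding) is re-referenced with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .toy_model import StrainTrace

_COLUMNS = {"rv_apex": "RV_apex", "rv_mid": "RV_mid", "rv_base": "RV_base",
            "ivs": "IVS", "lvfw": "LVfw"}
_META_KEYS = ("t_qrs", "t_pvc", "T")
_ZERO_TOL = 1e-6  # % strain at QRS onset before re-referencing kicks in


def write_strain_csv(trace: StrainTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# t_qrs={trace.t_qrs!r}\n")
        fh.write(f"# t_pvc={trace.t_pvc!r}\n")
        fh.write(f"# T={trace.T!r}\n")
        df = pd.DataFrame({"time_s": trace.t})
        for col, seg in _COLUMNS.items():
            df[col] = trace.strain[seg]
        df.to_csv(fh, index=False)


def read_strain_csv(path) -> StrainTrace:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = float(value)
    missing_meta = [k for k in _META_KEYS if k not in meta]
    if missing_meta:
        raise ValueError(f"{path}: missing header metadata: {missing_meta}")

    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("time_s", *_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")

    strain: dict[str, np.ndarray] = {}
    for col, seg in _COLUMNS.items():
        y = df[col].to_numpy(dtype=float)
        at_qrs = float(np.interp(meta["t_qrs"], t, y))
        if abs(at_qrs) > _ZERO_TOL:
            warnings.warn(f"{path}: {col} strain is {at_qrs:.3g}% at QRS onset; re-referencing")
            y = y - at_qrs
        strain[seg] = y
    return StrainTrace(t=t, strain=strain, t_qrs=meta["t_qrs"],
                       t_pvc=meta["t_pvc"], T=meta["T"])
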