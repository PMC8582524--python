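"""Tabular and JSON I/O shared by the CLI and the analysis drivers.

All formats are plain CSV/JSON.  Trajectories are written with 6
significant digits; observation tables serialize the dosing history as a
compact interval string (see :meth:`reachat.tumor_model.DoseSignal.encode`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .estimation import ObservationTable
from .tumor_model import DoseSignal, Trajectory, TumorState

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_observations",
    "read_observations",
    "write_json",
    "read_json",
]


def _fmt6(x: float) -> str:
    return f"{x:.6g}"


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory CSV with header ``t,H,A,V,c_osi`` at 6 significant digits."""
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format="%.6g")


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"t", "H", "A", "V", "c_osi"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"trajectory CSV must have columns {sorted(required)}")
    return df


def write_observations(tables: list[ObservationTable], path) -> None:
    """Observation CSV: columns ``id,t,channel,y,arm,dosing,init_H,init_A``."""
    frames = []
    for tab in tables:
        df = tab.data.copy()
        df.insert(0, "id", tab.id)
        df["arm"] = tab.arm
        df["dosing"] = tab.dose.encode()
        df["init_H"] = tab.init.H if tab.init is not None else np.nan
        df["init_A"] = tab.init.A if tab.init is not None else np.nan
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_observations(path) -> list[ObservationTable]:
    df = pd.read_csv(path)
    required = {"id", "t", "channel", "y"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"observation CSV must have columns {sorted(required)}")
    tables = []
    for ident, sub in df.groupby("id", sort=False):
        arm = "" if "arm" not in sub or pd.isna(sub["arm"].iloc[0]) else str(sub["arm"].iloc[0])
        dose = DoseSignal.off()
        if "dosing" in sub and not pd.isna(sub["dosing"].iloc[0]):
            dose = DoseSignal.decode(str(sub["dosing"].iloc[0]))
        init = None
        if "init_H" in sub and not pd.isna(sub["init_H"].iloc[0]):
            init = TumorState(0.0, float(sub["init_H"].iloc[0]), float(sub["init_A"].iloc[0]))
        tables.append(
            ObservationTable(
                id=str(ident),
                data=sub[["t", "channel", "y"]].astype({"t": float, "y": float}),
                arm=arm,
                dose=dose,
                init=init,
            )
        )
    return tables


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
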