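"""CSV/JSON readers and writers for CRCs, interval lists and profile tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crc import CRCDataset
from .dwell import DwellSequence
from .units import UnitError, to_molar

__all__ = [
    "read_crc_csv",
    "read_intervals_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "write_json_report",
]

CRC_COLUMNS = ("label", "concentration", "concentration_unit", "po")


def read_crc_csv(path, default_unit: str | None = None) -> dict[str, CRCDataset]:
    """Read CRC points grouped by label.

    Required columns: label, concentration, po and either a
    ``concentration_unit`` column or an explicit ``default_unit`` — units are
    never assumed.  Optional: sem, n, background, voltage_mV.
    """
    df = pd.read_csv(path)
    missing = {"label", "concentration", "po"} - set(df.columns)
    if missing:
        raise ValueError(f"CRC file missing columns: {sorted(missing)}")
    if "concentration_unit" in df.columns:
        units = df["concentration_unit"].astype(str)
    elif default_unit is not None:
        units = pd.Series([default_unit] * len(df))
    else:
        raise UnitError(
            "no concentration_unit column and no default_unit given; "
            "concentration units must be declared"
        )
    molar = np.array([to_molar(v, u) for v, u in zip(df["concentration"], units)])

    out: dict[str, CRCDataset] = {}
    for label, g in df.assign(A=molar).groupby("label", sort=False):
        points = g[["A", "po"]].copy()
        if "sem" in g.columns:
            points["sem"] = g["sem"].to_numpy()
        if "n" in g.columns:
            points["n"] = g["n"].to_numpy()
        out[str(label)] = CRCDataset(
            label=str(label),
            points=points,
            background=str(g["background"].iloc[0]) if "background" in g.columns else "",
            voltage=float(g["voltage_mV"].iloc[0]) if "voltage_mV" in g.columns else -100.0,
        )
    return out


def read_intervals_csv(path) -> dict[str, DwellSequence]:
    """Read interval lists (columns state, duration_ms, optional sweep_id)."""
    df = pd.read_csv(path)
    missing = {"state", "duration_ms"} - set(df.columns)
    if missing:
        raise ValueError(f"interval file missing columns: {sorted(missing)}")
    if "sweep_id" not in df.columns:
        df = df.assign(sweep_id=0)
    return {
        str(sweep): DwellSequence.from_frame(g)
        for sweep, g in df.groupby("sweep_id", sort=False)
    }


def read_profiles_csv(path) -> pd.DataFrame:
    """Read a profile table (label, KdC_M, KdO_M, L2, dG_LA, dG_HA, eta)."""
    df = pd.read_csv(path)
    if "eta" not in df.columns:
        raise ValueError("profile file must have an 'eta' column")
    return df


def write_profiles_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_json_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=_default))
    return path
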