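"""Delimited-text readers and writers for curves, peak tables and profiles.

All on-disk formats are plain text: whitespace/comma-delimited columns
with ``#`` comment lines.  Curves carry (q, intensity[, error]); peak
tables mirror the published layout (label, position, width, amplitude,
area); density profiles are (z, rho) with the run metadata in header
comments.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .peakfit import Axis, IntensityCurve

__all__ = [
    "read_curve",
    "write_curve",
    "read_peak_table",
    "write_peak_table",
    "read_profile",
    "write_profile",
    "read_component_table",
    "write_component_table",
]

PEAK_COLUMNS = ["label", "position", "width", "amplitude", "area"]
COMPONENT_COLUMNS = ["label", "position", "width", "amplitude", "electrons", "fraction"]


def read_curve(path, axis: Axis | str = Axis.OUT_OF_PLANE) -> IntensityCurve:
    """Read a 2- or 3-column delimited text curve (q, I[, err])."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns (q, intensity)")
    err = data[:, 2] if data.shape[1] >= 3 else None
    return IntensityCurve(Axis(axis), data[:, 0], data[:, 1], err)


def write_curve(path, curve: IntensityCurve, header: str = "") -> None:
    cols = [curve.q, curve.intensity]
    names = "q intensity"
    if curve.error is not None:
        cols.append(curve.error)
        names += " error"
    head = f"axis: {curve.axis.value}\n{names}"
    if header:
        head = header.rstrip("\n") + "\n" + head
    np.savetxt(path, np.column_stack(cols), header=head, fmt="%.10g")


def _read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[columns]


def read_peak_table(path) -> pd.DataFrame:
    """Peak table with columns label/position/width/amplitude/area."""
    return _read_table(path, PEAK_COLUMNS)


def write_peak_table(path, df: pd.DataFrame) -> None:
    df[PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_component_table(path) -> pd.DataFrame:
    """Gaussian-component table: label/position/width/amplitude/electrons/fraction."""
    return _read_table(path, COMPONENT_COLUMNS)


def write_component_table(path, df: pd.DataFrame) -> None:
    df[COMPONENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_profile(path, z, rho, metadata: dict | None = None) -> None:
    """Write a density profile as (z, rho) text with metadata in comments."""
    lines = []
    for key, val in (metadata or {}).items():
        lines.append(f"{key}: {val}")
    lines.append("z rho")
    np.savetxt(path, np.column_stack([z, rho]), header="\n".join(lines), fmt="%.10g")


def read_profile(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a (z, rho) profile; returns (z, rho, metadata dict)."""
    meta: dict[str, str] = {}
    body = []
    text = Path(path).read_text()
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                meta[key.strip()] = val.strip()
        else:
            body.append(line)
    data = np.loadtxt(_io.StringIO("\n".join(body)), ndmin=2)
    return data[:, 0], data[:, 1], meta
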