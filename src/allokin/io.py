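"""File I/O and assay-unit conversion.

Units are fixed at the file boundary: concentrations in mM, velocities in
U mg^-1, uptakes in Da, times in seconds.  The CSV dialect is UTF-8,
comma-separated, "." decimal, with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import VelocityDataset

__all__ = [
    "AssaySpec",
    "ASSAYS",
    "absorbance_slope_to_rate",
    "read_velocity_csv",
    "write_velocity_csv",
    "write_json_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AssaySpec:
    """Direct spectrophotometric assay constants.

    delta_eps is the signed molar extinction change of the reaction at the
    observation wavelength (M^-1 cm^-1); path_cm the cuvette path length.
    """

    substrate: str
    lambda_obs_nm: float
    delta_eps: float  # M^-1 cm^-1, signed
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_eps == 0:
            raise ValueError("delta_eps must be nonzero")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be positive")


#: Standard phosphorolysis assays: substrate depletion gives a negative
#: extinction change, so a falling absorbance trace yields a positive rate.
ASSAYS = {
    "Ado": AssaySpec("Ado", lambda_obs_nm=265.0, delta_eps=-1690.0),
    "m7Guo": AssaySpec("m7Guo", lambda_obs_nm=260.0, delta_eps=-4600.0),
}


def absorbance_slope_to_rate(dA_dt: float, spec: AssaySpec) -> float:
    """Convert an absorbance slope (AU/min) to a reaction rate (M/min).

    Beer–Lambert: rate = (dA/dt) / (delta_eps * path_cm).  With the negative
    delta_eps of a substrate-consumption assay, a negative slope converts to
    a positive rate.
    """
    return dA_dt / (spec.delta_eps * spec.path_cm)


def read_velocity_csv(path) -> VelocityDataset:
    """Read an initial-velocity table.

    Required columns: c0_mM, v0_Umg; optional: sd_Umg, n_rep.  Malformed
    rows are reported with their (1-based, header-inclusive) line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"c0_mM", "v0_Umg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    errors = []
    for col in ["c0_mM", "v0_Umg"] + [c for c in ("sd_Umg",) if c in df]:
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna() & df[col].notna()]:
            errors.append(f"line {i + 2}: non-numeric {col}={df[col][i]!r}")
        df[col] = vals
    for i in df.index[df["c0_mM"] < 0]:
        errors.append(f"line {i + 2}: negative concentration c0_mM={df['c0_mM'][i]}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return VelocityDataset.from_dataframe(df)


def write_velocity_csv(dataset: VelocityDataset, path) -> None:
    """Write a dataset in the dialect :func:`read_velocity_csv` reads."""
    dataset.to_dataframe().to_csv(path, index=False)


def write_json_report(payload: dict, path) -> None:
    """Write a versioned JSON report; numpy scalars are converted."""

    def _default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    out = {"schema_version": REPORT_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_default) + "\n")
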