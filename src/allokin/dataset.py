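"""Container for replicate initial-velocity measurements."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["VelocityDataset"]


@dataclass(frozen=True)
class VelocityDataset:
    """Initial velocities vs variable-substrate concentration.

    Attributes
    ----------
    c0 : ndarray
        Variable-substrate concentrations, mM, non-negative.  Stored sorted
        ascending; ties are allowed (independent measurements at one
        concentration).
    v0 : ndarray
        Replicate-mean initial velocities, U mg^-1.
    sd : ndarray
        Standard deviation of the average rate per point, U mg^-1; NaN where
        unavailable.
    n_rep : ndarray
        Replicate count per point (>= 1).
    metadata : mapping
        Free-form assay metadata (enzyme_form, variable_substrate,
        co_substrate, co_substrate_conc, ...).
    """

    c0: np.ndarray
    v0: np.ndarray
    sd: np.ndarray
    n_rep: np.ndarray
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c0 = np.asarray(self.c0, dtype=float)
        v0 = np.asarray(self.v0, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        n_rep = np.asarray(self.n_rep, dtype=int)
        if not (c0.shape == v0.shape == sd.shape == n_rep.shape) or c0.ndim != 1:
            raise ValueError("c0, v0, sd, n_rep must be 1-D arrays of equal length")
        if c0.size == 0:
            raise ValueError("empty dataset")
        if np.any(c0 < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(sd[np.isfinite(sd)] < 0):
            raise ValueError("standard deviations must be non-negative")
        if np.any(n_rep < 1):
            raise ValueError("replicate counts must be >= 1")
        order = np.argsort(c0, kind="stable")
        object.__setattr__(self, "c0", c0[order])
        object.__setattr__(self, "v0", v0[order])
        object.__setattr__(self, "sd", sd[order])
        object.__setattr__(self, "n_rep", n_rep[order])

    def __len__(self) -> int:
        return self.c0.size

    @classmethod
    def from_arrays(
        cls,
        c0,
        v0,
        sd=None,
        n_rep=None,
        metadata: Mapping[str, Any] | None = None,
    ) -> "VelocityDataset":
        c0 = np.asarray(c0, dtype=float)
        if sd is None:
            sd = np.full_like(c0, np.nan)
        if n_rep is None:
            n_rep = np.ones_like(c0, dtype=int)
        return cls(
            c0=c0,
            v0=np.asarray(v0, dtype=float),
            sd=np.asarray(sd, dtype=float),
            n_rep=np.asarray(n_rep, dtype=int),
            metadata=dict(metadata or {}),
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metadata: Mapping[str, Any] | None = None
    ) -> "VelocityDataset":
        """Build from a frame with columns c0_mM, v0_Umg [, sd_Umg, n_rep]."""
        required = {"c0_mM", "v0_Umg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        sd = df["sd_Umg"].to_numpy(float) if "sd_Umg" in df else None
        n_rep = df["n_rep"].to_numpy(int) if "n_rep" in df else None
        return cls.from_arrays(
            df["c0_mM"].to_numpy(float),
            df["v0_Umg"].to_numpy(float),
            sd=sd,
            n_rep=n_rep,
            metadata=metadata,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c0_mM": self.c0,
                "v0_Umg": self.v0,
                "sd_Umg": self.sd,
                "n_rep": self.n_rep,
            }
        )

    def weights(self, policy: str = "sd", cv: float = 0.05) -> np.ndarray:
        """Fitting weights w_i.

        policy "sd": w_i = 1/SD_i^2 (the assay-replicate weighting); a
        missing or zero SD raises, naming the offending point.
        policy "uniform": w_i = 1 (unweighted least squares).
        policy "relative": w_i = 1/(cv*v0_i)^2, a constant-CV error model.
        """
        if policy == "uniform":
            return np.ones_like(self.c0)
        if policy == "relative":
            if np.any(self.v0 == 0):
                raise ValueError("relative weighting undefined at v0 = 0")
            return 1.0 / (cv * self.v0) ** 2
        if policy == "sd":
            bad = ~np.isfinite(self.sd) | (self.sd == 0)
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"SD missing or zero at point {i} (c0={self.c0[i]:g} mM); "
                    "choose the 'uniform' or 'relative' weighting policy or "
                    "supply replicate SDs"
                )
            return 1.0 / self.sd**2
        raise ValueError(f"unknown weighting policy {policy!r}")
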