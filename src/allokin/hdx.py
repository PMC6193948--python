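"""Differential hydrogen/deuterium-exchange (HDX-MS) uptake analysis.

Backbone-amide deuterium uptake of peptic peptides, measured in replicate
over a short time series, reports local conformational flexibility.  Two
liganded states of a protein are compared peptide-by-peptide: a per-
timepoint uptake difference is called significant when it exceeds a global
threshold derived from the pooled replicate standard deviation,

    threshold = z_{(1+confidence)/2} * pooled_sd * sqrt(2 / n_rep)

the familiar confidence interval on a difference of two n_rep-replicate
means (98% confidence by default).  No back-exchange correction is applied;
all uptakes are raw centroid masses in Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

__all__ = [
    "PeptideUptakeSeries",
    "DifferentialResult",
    "uptake_summary",
    "pooled_sd",
    "significance_threshold",
    "compare_states",
    "read_uptake_csv",
]


@dataclass(frozen=True)
class PeptideUptakeSeries:
    """Replicate deuterium uptake of one peptide in one state.

    Attributes
    ----------
    peptide_id : str
    residue_range : (int, int)
        1-based inclusive protein numbering, e.g. (202, 216).
    state : str
        e.g. "apo", "binary_Pi", "ternary_Pi_FA".
    timepoints : ndarray
        Exchange times in seconds, strictly increasing.
    replicate_uptakes : ndarray, shape (n_timepoints, n_rep)
        Uptake in Da per (timepoint, replicate).
    """

    peptide_id: str
    residue_range: tuple[int, int]
    state: str
    timepoints: np.ndarray
    replicate_uptakes: np.ndarray

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        up = np.asarray(self.replicate_uptakes, dtype=float)
        if tp.ndim != 1 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be 1-D and strictly increasing")
        if up.ndim != 2 or up.shape[0] != tp.size:
            raise ValueError(
                "replicate_uptakes must have shape (n_timepoints, n_rep)"
            )
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "replicate_uptakes", up)

    @property
    def n_rep(self) -> int:
        return self.replicate_uptakes.shape[1]


@dataclass(frozen=True)
class DifferentialResult:
    """Per-timepoint uptake difference (state2 - state1) of one peptide."""

    peptide_id: str
    timepoints: np.ndarray
    delta: np.ndarray  # Da
    significant: np.ndarray  # bool, |delta| > threshold
    threshold: float  # Da
    direction: str  # increased | decreased | mixed | unchanged

    def to_dict(self) -> dict:
        return {
            "peptide_id": self.peptide_id,
            "timepoints_s": [float(x) for x in self.timepoints],
            "delta_da": [float(x) for x in self.delta],
            "significant": [bool(x) for x in self.significant],
            "threshold_da": float(self.threshold),
            "direction": self.direction,
        }


def uptake_summary(series: PeptideUptakeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint sample mean and sample SD (n-1 denominator).

    With a single replicate the SD is returned as NaN (undefined), not 0.
    """
    mean = series.replicate_uptakes.mean(axis=1)
    if series.n_rep < 2:
        sd = np.full_like(mean, np.nan)
    else:
        sd = series.replicate_uptakes.std(axis=1, ddof=1)
    return mean, sd


def pooled_sd(
    series_list: Sequence[PeptideUptakeSeries], mode: str = "global"
) -> float:
    """Pooled replicate SD across peptides/states/timepoints.

    mode "global" pools the replicate variances of every (peptide, state,
    timepoint) cell — the usual practice for a dataset-wide threshold.
    mode "per_timepoint_mean" averages per-timepoint pooled SDs (gives the
    same number when replicate counts are equal).
    """
    variances = []
    for s in series_list:
        if s.n_rep < 2:
            raise ValueError(f"peptide {s.peptide_id}: need >= 2 replicates")
        variances.append(s.replicate_uptakes.var(axis=1, ddof=1))
    allvar = np.concatenate(variances)
    if mode in ("global", "per_timepoint_mean"):
        return float(np.sqrt(allvar.mean()))
    raise ValueError(f"unknown pooling mode {mode!r}")


def significance_threshold(
    pooled_sd: float,
    n_rep: int,
    confidence: float = 0.98,
    quantile: str = "z",
) -> float:
    """Global significance threshold (Da) for a difference of means.

    threshold = q * pooled_sd * sqrt(2/n_rep), with q the two-sided normal
    quantile at the given confidence (default 98%).  ``quantile="t"``
    substitutes the Student-t quantile with n_rep - 1 degrees of freedom
    for small-sample per-peptide use.
    """
    if pooled_sd < 0:
        raise ValueError("pooled_sd must be non-negative")
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    pr = (1 + confidence) / 2
    if quantile == "z":
        q = norm.ppf(pr)
    elif quantile == "t":
        q = t_dist.ppf(pr, df=n_rep - 1)
    else:
        raise ValueError(f"unknown quantile {quantile!r}")
    return float(q * pooled_sd * np.sqrt(2.0 / n_rep))


def compare_states(
    s1: PeptideUptakeSeries, s2: PeptideUptakeSeries, threshold: float
) -> DifferentialResult:
    """Differential uptake of one peptide between two states.

    delta = mean(s2) - mean(s1) per timepoint; a timepoint is significant
    when |delta| > threshold.  A peptide counts as changed when ANY
    timepoint is significant (effects confined to the shortest exchange
    time are real and must not be averaged away).
    """
    if s1.peptide_id != s2.peptide_id:
        raise ValueError(
            f"peptide mismatch: {s1.peptide_id!r} vs {s2.peptide_id!r}"
        )
    if not np.array_equal(s1.timepoints, s2.timepoints):
        raise ValueError("timepoint grids differ between the two states")
    m1, _ = uptake_summary(s1)
    m2, _ = uptake_summary(s2)
    delta = m2 - m1
    significant = np.abs(delta) > threshold
    if not significant.any():
        direction = "unchanged"
    else:
        signs = np.sign(delta[significant])
        if np.all(signs > 0):
            direction = "increased"
        elif np.all(signs < 0):
            direction = "decreased"
        else:
            direction = "mixed"
    return DifferentialResult(
        peptide_id=s1.peptide_id,
        timepoints=s1.timepoints,
        delta=delta,
        significant=significant,
        threshold=float(threshold),
        direction=direction,
    )


def read_uptake_csv(path) -> list[PeptideUptakeSeries]:
    """Read per-replicate uptake records.

    Expected columns: peptide_id, start, end, state, time_s, replicate,
    uptake_da.  Returns one series per (peptide_id, state).
    """
    df = pd.read_csv(path)
    required = {"peptide_id", "start", "end", "state", "time_s", "replicate", "uptake_da"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) in {path}: {sorted(missing)}")
    out = []
    for (pid, state), grp in df.groupby(["peptide_id", "state"], sort=True):
        piv = grp.pivot_table(
            index="time_s", columns="replicate", values="uptake_da"
        ).sort_index()
        if piv.isna().any().any():
            raise ValueError(
                f"ragged replicates for peptide {pid!r} state {state!r}"
            )
        out.append(
            PeptideUptakeSeries(
                peptide_id=str(pid),
                residue_range=(int(grp["start"].iloc[0]), int(grp["end"].iloc[0])),
                state=str(state),
                timepoints=piv.index.to_numpy(float),
                replicate_uptakes=piv.to_numpy(float),
            )
        )
    return out
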