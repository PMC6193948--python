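"""Synthetic-data generators for every stage of the pipeline.

Raw assay data behind the published kinetic and exchange experiments are
not deposited anywhere, so the pipeline is exercised on simulated inputs
that mimic the study conditions: heteroscedastic replicate initial-velocity
datasets over wide cuvette-style concentration grids, replicate deuterium-
uptake curves at the standard five exchange timepoints, and cooperative
two-site titration occupancies.  Every generator is bit-reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import VelocityDataset
from .hdx import PeptideUptakeSeries
from .occupancy import ChainRecord, OccupancyTable
from .params import ISParams, MMParams
from .rates import eval_interacting_sites, eval_mm

__all__ = [
    "NoiseSpec",
    "TitrationSpec",
    "make_concentration_grid",
    "simulate_velocity_dataset",
    "simulate_null_ensemble",
    "simulate_hdx_uptake",
    "simulate_titration",
    "species_fractions",
    "solve_free_ligand",
    "HDX_TIMEPOINTS_S",
]

# standard exchange series: 10 s, 1 min, 20 min, 1 h, 4 h
HDX_TIMEPOINTS_S = (10.0, 60.0, 1200.0, 3600.0, 14400.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate measurement-noise law for velocity data.

    Per-replicate SD = sigma_abs + cv * v_true under mode "mixed";
    mode "absolute" uses sigma_abs alone, "relative" cv * v_true alone.
    """

    mode: str = "mixed"
    sigma_abs: float = 0.0
    cv: float = 0.05
    n_rep: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative", "mixed"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sigma_abs < 0 or self.cv < 0:
            raise ValueError("sigma_abs and cv must be non-negative")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")

    def sd(self, v_true: np.ndarray) -> np.ndarray:
        v = np.abs(np.asarray(v_true, dtype=float))
        if self.mode == "absolute":
            return np.full_like(v, self.sigma_abs)
        if self.mode == "relative":
            return self.cv * v
        return self.sigma_abs + self.cv * v


def make_concentration_grid(Km1: float, Km2: float, n_points: int = 16) -> np.ndarray:
    """Log-spaced concentration grid covering both Michaelis constants.

    Spans 0.1*Km1 to max(10*Km2, 100*Km1), emulating the broad range
    reachable with cuvettes of decreasing path length.
    """
    if Km1 <= 0 or Km2 <= 0:
        raise ValueError("Michaelis constants must be positive")
    if n_points < 6:
        raise ValueError("need at least 6 grid points")
    lo = 0.1 * Km1
    hi = max(10.0 * Km2, 100.0 * Km1)
    return np.logspace(np.log10(lo), np.log10(hi), n_points)


def simulate_velocity_dataset(
    truth_model: str,
    truth_params: MMParams | ISParams,
    grid: np.ndarray,
    noise: NoiseSpec,
) -> VelocityDataset:
    """Replicate initial-velocity dataset under MM or interacting-sites truth.

    At each grid concentration, ``noise.n_rep`` Gaussian replicate draws are
    taken around the true rate with the SD given by the noise law; the
    dataset stores the replicate mean, the standard deviation of the
    average rate (sample SD / sqrt(n_rep)) and the replicate count.
    Negative draws are allowed — they are measurement noise, not rates.
    """
    grid = np.asarray(grid, dtype=float)
    if truth_model == "MM":
        v_true = np.asarray(eval_mm(truth_params, grid), dtype=float)
    elif truth_model == "IS":
        v_true = np.asarray(eval_interacting_sites(truth_params, grid), dtype=float)
    else:
        raise ValueError(f"unknown truth_model {truth_model!r}")
    rng = np.random.default_rng(noise.seed)
    sd_law = noise.sd(v_true)
    draws = v_true[:, None] + sd_law[:, None] * rng.standard_normal(
        (grid.size, noise.n_rep)
    )
    v_mean = draws.mean(axis=1)
    if noise.n_rep > 1:
        sd_mean = draws.std(axis=1, ddof=1) / np.sqrt(noise.n_rep)
    else:
        sd_mean = np.full(grid.size, np.nan)
    return VelocityDataset.from_arrays(
        grid,
        v_mean,
        sd=sd_mean,
        n_rep=np.full(grid.size, noise.n_rep),
        metadata={
            "truth_model": truth_model,
            "noise_mode": noise.mode,
            "sigma_abs": noise.sigma_abs,
            "cv": noise.cv,
            "seed": noise.seed,
        },
    )


def simulate_null_ensemble(
    mm_params: MMParams,
    grid: np.ndarray,
    noise: NoiseSpec,
    n_datasets: int,
) -> list[VelocityDataset]:
    """Independent MM-truth datasets with seeds base_seed + index."""
    return [
        simulate_velocity_dataset(
            "MM",
            mm_params,
            grid,
            NoiseSpec(noise.mode, noise.sigma_abs, noise.cv, noise.n_rep,
                      seed=noise.seed + i),
        )
        for i in range(n_datasets)
    ]


def simulate_hdx_uptake(
    n_exchangeable: int,
    rate_constants,
    timepoints=HDX_TIMEPOINTS_S,
    noise_sd_da: float = 0.1,
    n_rep: int = 3,
    seed: int = 0,
    peptide_id: str = "p1",
    residue_range: tuple[int, int] = (1, 10),
    state: str = "apo",
) -> PeptideUptakeSeries:
    """Replicate deuterium-uptake curve of one peptide.

    Expected uptake(t) = sum_j (1 - exp(-k_j t)) over exchangeable amides
    (one first-order rate constant per amide, s^-1), plus iid Gaussian
    noise per replicate measurement.
    """
    k = np.asarray(rate_constants, dtype=float)
    if k.size != n_exchangeable:
        raise ValueError("need one rate constant per exchangeable amide")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    t = np.asarray(timepoints, dtype=float)
    expected = (1.0 - np.exp(-np.outer(t, k))).sum(axis=1)
    rng = np.random.default_rng(seed)
    reps = expected[:, None] + noise_sd_da * rng.standard_normal((t.size, n_rep))
    return PeptideUptakeSeries(
        peptide_id=peptide_id,
        residue_range=residue_range,
        state=state,
        timepoints=t,
        replicate_uptakes=reps,
    )


@dataclass(frozen=True)
class TitrationSpec:
    """Cooperative two-site (dimer) titration.

    The dimer binds ligand with stepwise association governed by the
    binding polynomial P(c) = 1 + 2 K1 c + coupling * K1^2 c^2 in free
    ligand c; ``coupling`` < 1 models negative cooperativity (the second
    site binds weaker once the first is occupied — the part-of-the-sites
    signature), coupling = 1 independent sites, > 1 positive cooperativity.
    """

    K1: float  # site association constant, mM^-1
    coupling: float
    ratios: tuple[float, ...]  # total ligand : protein(dimer) molar ratios
    protein_conc: float = 1.0  # mM dimer

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.coupling <= 0 or self.protein_conc <= 0:
            raise ValueError("K1, coupling and protein_conc must be positive")
        r = np.asarray(self.ratios, dtype=float)
        if np.any(r < 0) or np.any(np.diff(r) < 0):
            raise ValueError("ratios must be non-negative and non-decreasing")


def _bound_per_dimer(spec: TitrationSpec, c_free: float) -> float:
    """Mean ligands bound per dimer at free concentration c."""
    x = spec.K1 * c_free
    P = 1.0 + 2.0 * x + spec.coupling * x * x
    return (2.0 * x + 2.0 * spec.coupling * x * x) / P


def species_fractions(spec: TitrationSpec, c_free: float) -> tuple[float, float, float]:
    """Fractions of dimers with 0, 1 and 2 ligands bound at free conc c."""
    x = spec.K1 * c_free
    P = 1.0 + 2.0 * x + spec.coupling * x * x
    return 1.0 / P, 2.0 * x / P, spec.coupling * x * x / P


def solve_free_ligand(spec: TitrationSpec, total: float, max_bisect: int = 200) -> float:
    """Free-ligand concentration from conservation, by bisection on [0, total]."""
    if total == 0:
        return 0.0
    lo, hi = 0.0, total
    tol = 1e-12 * total
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        if spec.protein_conc * _bound_per_dimer(spec, mid) + mid - total > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= tol:
            return 0.5 * (lo + hi)
    raise RuntimeError(f"free-ligand bisection did not converge for total {total}")


def simulate_titration(spec: TitrationSpec, max_bisect: int = 200) -> list[OccupancyTable]:
    """Equilibrium per-site occupancies along a titration series.

    For each ligand:protein ratio the free-ligand concentration is solved
    from total-ligand conservation (bound + free = total) by bisection on
    [0, total] to 1e-12 relative tolerance, then per-site occupancy is the
    mean ligands bound per dimer divided by two.  Results are returned as
    two-chain :class:`OccupancyTable` records (chains S1, S2) so the
    occupancy-series tooling can consume them directly.
    """
    out = []
    for ratio in spec.ratios:
        total = ratio * spec.protein_conc
        c_free = solve_free_ligand(spec, total, max_bisect=max_bisect)
        occ = _bound_per_dimer(spec, c_free) / 2.0
        chains = (
            ChainRecord("S1", "open", occ if occ > 0 else None),
            ChainRecord("S2", "open", occ if occ > 0 else None),
        )
        out.append(
            OccupancyTable(
                structure_id=f"titration-{ratio:g}",
                molar_ratio=float(ratio),
                chains=chains,
                dimer_map=(("S1", "S2"),),
            )
        )
    return out
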