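"""Weighted nonlinear least-squares fitting of the kinetic rate laws.

The estimation problem is heteroscedastic: replicate velocities at low and
high substrate concentration (thin-cuvette measurements) carry very
different errors, so points are weighted by 1/SD^2 of the average rate.
Because the interacting-sites surface can show several shallow minima, the
optimizer is a multi-start local search: parameters are log-transformed
(which enforces positivity without constraints), starts are drawn from a
log-Latin-hypercube around the data-implied scale, and — for the
interacting-sites model — one start is always the Michaelis–Menten-embedded
point (a = b = 1, Km1 = Km_MM, Vmax1 = Vmax_MM / 2), which guarantees that
the best interacting-sites fit never has a larger weighted SSR than the
best Michaelis–Menten fit.

Usage follows the model/results idiom::

    model = InteractingSites(dataset, weighting="sd")
    res = model.fit(n_starts=20, seed=0)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dataset import VelocityDataset
from .params import ISParams, MMParams
from .rates import eval_interacting_sites, eval_mm

__all__ = [
    "FitError",
    "KineticModel",
    "MichaelisMenten",
    "InteractingSites",
    "KineticFitResults",
    "weighted_ssr",
    "fit_model",
]

# convergence: relative wssr change below this, else iteration cap
_FTOL = 1e-10
_XTOL = 1e-12
_MAX_ITER = 500
_TIE_REL = 1e-8


class FitError(RuntimeError):
    """No optimizer start produced a usable fit."""

    def __init__(self, message: str, start_trace: list[dict] | None = None):
        super().__init__(message)
        self.start_trace = start_trace or []


def weighted_ssr(
    model_id: str,
    params: MMParams | ISParams,
    dataset: VelocityDataset,
    weighting: str = "sd",
    cv: float = 0.05,
) -> float:
    """Weighted sum of squared residuals sum_i w_i (v0_i - model(c0_i))^2."""
    w = dataset.weights(weighting, cv=cv)
    if model_id == "MM":
        pred = eval_mm(params, dataset.c0)
    elif model_id == "IS":
        pred = eval_interacting_sites(params, dataset.c0)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return float(np.sum(w * (dataset.v0 - pred) ** 2))


class KineticModel:
    """Base class binding a rate law to a :class:`VelocityDataset`."""

    model_id: str = ""
    param_names: Sequence[str] = ()

    def __init__(
        self, dataset: VelocityDataset, weighting: str = "sd", cv: float = 0.05
    ):
        self.dataset = dataset
        self.weighting = weighting
        self.cv = cv
        self._w = dataset.weights(weighting, cv=cv)  # resolve (and validate) early
        p = len(self.param_names)
        if len(dataset) < p + 1:
            raise ValueError(
                f"{type(self).__name__} needs at least {p + 1} points, "
                f"got {len(dataset)}"
            )

    @classmethod
    def from_dataframe(cls, df, weighting: str = "sd", cv: float = 0.05, **meta):
        return cls(VelocityDataset.from_dataframe(df, metadata=meta), weighting, cv)

    # subclasses implement
    def _predict_array(self, x: np.ndarray, c0: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _params_object(self, x: np.ndarray):
        raise NotImplementedError

    def _start_points(self, n_starts: int, seed: int) -> list[np.ndarray]:
        raise NotImplementedError

    def _data_scales(self) -> np.ndarray:
        raise NotImplementedError

    # ------------------------------------------------------------------
    def predict(self, params, c0=None):
        """Model velocities at the dataset (or given) concentrations."""
        c = self.dataset.c0 if c0 is None else np.asarray(c0, dtype=float)
        x = self._params_array(params)
        return self._predict_array(x, c)

    def _params_array(self, params) -> np.ndarray:
        if isinstance(params, (MMParams, ISParams)):
            return np.array([getattr(params, n) for n in self.param_names], float)
        return np.asarray(params, dtype=float)

    def wssr(self, params) -> float:
        r = self.dataset.v0 - self.predict(params)
        return float(np.sum(self._w * r**2))

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        pred = self._predict_array(x, self.dataset.c0)
        return np.sqrt(self._w) * (self.dataset.v0 - pred)

    def _lhs_box(self, n_starts: int, seed: int, decades: float = 3.0) -> list[np.ndarray]:
        """Log-Latin-hypercube starts over [10^-decades, 10^decades] x scale."""
        scales = self._data_scales()
        p = len(scales)
        sampler = qmc.LatinHypercube(d=p, seed=np.random.default_rng(seed))
        u = sampler.random(n_starts)
        logs = np.log(scales) + (2 * u - 1) * decades * np.log(10.0)
        return [np.exp(row) for row in logs]

    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        transform: str = "log",
        max_iter: int = _MAX_ITER,
    ) -> "KineticFitResults":
        """Multi-start weighted least squares.

        Parameters
        ----------
        n_starts : int
            Number of Latin-hypercube starts (the deterministic data-implied
            and, for the interacting-sites model, MM-embedded starts are
            added on top).
        seed : int
            Seed for start generation; the fit itself is deterministic.
        transform : {"log", "natural"}
            Optimize log-parameters (default; enforces positivity) or raw
            parameters with positivity bounds.
        """
        starts = self._start_points(n_starts, seed)
        p = len(self.param_names)
        max_nfev = max_iter * (p + 1)
        trace: list[dict[str, Any]] = []
        best_x: np.ndarray | None = None
        best_wssr = np.inf
        best_idx = -1
        best_converged = False
        n_converged = 0

        for idx, x0 in enumerate(starts):
            try:
                if transform == "log":
                    sol = least_squares(
                        lambda t: self._residuals(np.exp(t)),
                        np.log(x0),
                        method="trf",
                        bounds=(np.log(x0) - 40, np.log(x0) + 40),
                        ftol=_FTOL,
                        xtol=_XTOL,
                        gtol=1e-14,
                        max_nfev=max_nfev,
                    )
                    x_opt = np.exp(sol.x)
                elif transform == "natural":
                    sol = least_squares(
                        self._residuals,
                        x0,
                        method="trf",
                        bounds=(np.full(p, 1e-300), np.full(p, np.inf)),
                        ftol=_FTOL,
                        xtol=_XTOL,
                        gtol=1e-14,
                        max_nfev=max_nfev,
                    )
                    x_opt = sol.x
                else:
                    raise ValueError(f"unknown transform {transform!r}")
            except ValueError as err:  # pragma: no cover - defensive
                trace.append(
                    {"start": idx, "x0": list(x0), "wssr": np.inf,
                     "converged": False, "error": str(err)}
                )
                continue
            wssr = 2.0 * sol.cost
            converged = bool(sol.status > 0 and sol.nfev < max_nfev)
            n_converged += converged
            trace.append(
                {"start": idx, "x0": [float(v) for v in x0],
                 "wssr": float(wssr), "converged": converged,
                 "nfev": int(sol.nfev)}
            )
            if np.isfinite(wssr) and (best_wssr - wssr) > _TIE_REL * max(wssr, 1e-300):
                best_wssr, best_x, best_idx = wssr, x_opt, idx
                best_converged = converged

        if best_x is None:
            raise FitError(
                f"no start of the {self.model_id} fit produced a finite "
                "weighted SSR",
                start_trace=trace,
            )

        dof = len(self.dataset) - p
        stderr = self._standard_errors(best_x, best_wssr, dof)
        return KineticFitResults(
            model=self,
            model_id=self.model_id,
            params=self._params_object(best_x),
            params_array=best_x,
            param_names=tuple(self.param_names),
            wssr=best_wssr,
            dof=dof,
            bse=stderr,
            n_starts=len(starts),
            converged_starts=n_converged,
            best_start_seed=best_idx,
            converged=best_converged,
            start_trace=trace,
            weighting=self.weighting,
            seed=seed,
        )

    def _standard_errors(self, x: np.ndarray, wssr: float, dof: int) -> np.ndarray:
        """Asymptotic standard errors from the weighted Jacobian.

        cov = s^2 (J^T W J)^-1 with s^2 = wssr/dof (the reduced weighted
        SSR).  A singular information matrix yields NaN entries rather than
        an exception.
        """
        p = len(x)
        m = len(self.dataset)
        J = np.empty((m, p))
        for j in range(p):
            h = 1e-6 * x[j]
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (
                self._predict_array(xp, self.dataset.c0)
                - self._predict_array(xm, self.dataset.c0)
            ) / (2 * h)
        A = J.T @ (self._w[:, None] * J)
        s2 = wssr / dof if dof > 0 else np.nan
        try:
            eig = np.linalg.eigvalsh(A)
            if eig[0] <= 1e-14 * max(eig[-1], 1e-300):
                return np.full(p, np.nan)
            cov = s2 * np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)
        var = np.diag(cov)
        return np.where(var >= 0, np.sqrt(np.abs(var)), np.nan)


class MichaelisMenten(KineticModel):
    """Michaelis–Menten model v = Vmax c / (Km + c) bound to a dataset."""

    model_id = "MM"
    param_names = ("Km", "Vmax")

    def _predict_array(self, x, c0):
        return x[1] * c0 / (x[0] + c0)

    def _params_object(self, x):
        return MMParams(Km=float(x[0]), Vmax=float(x[1]))

    def _data_scales(self):
        pos = self.dataset.c0[self.dataset.c0 > 0]
        kscale = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
        vscale = float(max(np.max(np.abs(self.dataset.v0)), 1e-12))
        return np.array([kscale, vscale])

    def _start_points(self, n_starts, seed):
        return [self._data_scales()] + self._lhs_box(n_starts, seed)


class InteractingSites(KineticModel):
    """Two-site interacting-sites model bound to a dataset.

    Parameters are (Km1, Vmax1, a, b); the saturating velocity is
    2 b Vmax1 and the second-site constants are Km2 = a Km1,
    Vmax2 = b Vmax1.
    """

    model_id = "IS"
    param_names = ("Km1", "Vmax1", "a", "b")

    def __init__(
        self,
        dataset: VelocityDataset,
        weighting: str = "sd",
        cv: float = 0.05,
        mm_results: "KineticFitResults | None" = None,
    ):
        super().__init__(dataset, weighting, cv)
        # an already-computed MM fit of the same dataset supplies the
        # embedded start directly (used by ensemble drivers)
        self._mm_results = mm_results

    def _predict_array(self, x, c0):
        K1, V1, a, b = x
        num = 2.0 * V1 * c0 / K1 + 2.0 * b * V1 * c0**2 / (a * K1**2)
        den = 1.0 + 2.0 * c0 / K1 + c0**2 / (a * K1**2)
        return num / den

    def _params_object(self, x):
        return ISParams(
            Km1=float(x[0]), Vmax1=float(x[1]), a=float(x[2]), b=float(x[3])
        )

    def _data_scales(self):
        pos = self.dataset.c0[self.dataset.c0 > 0]
        kscale = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
        vscale = float(max(np.max(np.abs(self.dataset.v0)), 1e-12)) / 2.0
        return np.array([kscale, vscale, 1.0, 1.0])

    def _start_points(self, n_starts, seed):
        # the MM-embedded start makes wssr(IS) <= wssr(MM) structural
        embedded = None
        mm_res = self._mm_results
        if mm_res is None:
            try:
                mm_res = MichaelisMenten(self.dataset, self.weighting, self.cv).fit(
                    n_starts=max(4, n_starts // 4), seed=seed
                )
            except FitError:
                mm_res = None
        if mm_res is not None:
            embedded = np.array(
                [mm_res.params.Km, mm_res.params.Vmax / 2.0, 1.0, 1.0]
            )
        starts = [] if embedded is None else [embedded]
        return starts + self._lhs_box(n_starts, seed)


@dataclass
class KineticFitResults:
    """Result of a multi-start weighted fit.

    Attributes mirror the usual results-object conventions: ``params`` is
    the fitted parameter bundle, ``bse`` the asymptotic standard errors
    (NaN where the information matrix was singular), ``wssr`` the weighted
    sum of squared residuals at the optimum and ``dof`` the residual
    degrees of freedom.
    """

    model: KineticModel
    model_id: str
    params: MMParams | ISParams
    params_array: np.ndarray
    param_names: tuple[str, ...]
    wssr: float
    dof: int
    bse: np.ndarray
    n_starts: int
    converged_starts: int
    best_start_seed: int
    converged: bool
    start_trace: list = field(repr=False, default_factory=list)
    weighting: str = "sd"
    seed: int = 0

    @property
    def stderr(self) -> dict[str, float]:
        return dict(zip(self.param_names, (float(s) for s in self.bse)))

    def predict(self, c0=None):
        return self.model.predict(self.params_array, c0)

    def resid(self) -> np.ndarray:
        return self.model.dataset.v0 - self.predict()

    def to_dict(self) -> dict:
        """JSON-serializable fit report."""
        out = {
            "model": self.model_id,
            "params": {n: float(v) for n, v in zip(self.param_names, self.params_array)},
            "stderr": {
                n: (None if not np.isfinite(s) else float(s))
                for n, s in zip(self.param_names, self.bse)
            },
            "wssr": float(self.wssr),
            "dof": int(self.dof),
            "n_points": len(self.model.dataset),
            "n_starts": int(self.n_starts),
            "converged_starts": int(self.converged_starts),
            "best_start_seed": int(self.best_start_seed),
            "weighting": self.weighting,
            "seed": int(self.seed),
        }
        if isinstance(self.params, ISParams):
            out["derived"] = {
                "Km2": self.params.Km2,
                "Vmax2": self.params.Vmax2,
                "saturating_velocity": 2.0 * self.params.Vmax2,
            }
        return out

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            f"{'Interacting-sites' if self.model_id == 'IS' else 'Michaelis-Menten'}"
            " weighted least-squares fit",
            "=" * 58,
            f"n points: {len(self.model.dataset):>4d}    dof: {self.dof:>4d}    "
            f"weighting: {self.weighting}",
            f"wssr: {self.wssr:.6g}    starts: {self.n_starts} "
            f"({self.converged_starts} converged, best #{self.best_start_seed})",
            "-" * 58,
            f"{'param':>8s} {'estimate':>14s} {'std.err':>12s}",
        ]
        for n, v, s in zip(self.param_names, self.params_array, self.bse):
            se = f"{s:.4g}" if np.isfinite(s) else "undefined"
            lines.append(f"{n:>8s} {v:>14.6g} {se:>12s}")
        if isinstance(self.params, ISParams):
            lines.append("-" * 58)
            lines.append(
                f"derived: Km2 = {self.params.Km2:.4g} mM, "
                f"Vmax2 = {self.params.Vmax2:.4g} U/mg, "
                f"2*Vmax2 = {2 * self.params.Vmax2:.4g} U/mg"
            )
        return "\n".join(lines)


def fit_model(
    dataset: VelocityDataset,
    model_id: str,
    weighting: str = "sd",
    cv: float = 0.05,
    n_starts: int = 20,
    seed: int = 0,
    transform: str = "log",
) -> KineticFitResults:
    """Functional wrapper: fit the named rate law to a dataset."""
    cls = {"MM": MichaelisMenten, "IS": InteractingSites}.get(model_id)
    if cls is None:
        raise ValueError(f"unknown model_id {model_id!r}")
    return cls(dataset, weighting=weighting, cv=cv).fit(
        n_starts=n_starts, seed=seed, transform=transform
    )
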