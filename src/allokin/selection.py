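"""Nested-model comparison by extra-sum-of-squares F-test.

The Michaelis–Menten law (2 parameters) is nested in the interacting-sites
law (4 parameters; a = b = 1 recovers MM with Vmax = 2 Vmax1), so the
significance of the weighted-SSR decrease is judged with

    F = ((wssr_MM - wssr_IS) / (p_IS - p_MM)) / (wssr_IS / (n - p_IS))

against the F(2, n - 4) distribution.  The richer model is selected only
when p < alpha (default 0.05, i.e. the 95% confidence level); a boundary
tie p == alpha keeps the simpler model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .fitting import InteractingSites, KineticFitResults, MichaelisMenten

__all__ = ["ModelComparison", "f_statistic", "select_model", "fit_and_select"]


@dataclass(frozen=True)
class ModelComparison:
    """F-test comparison of a simple and a complex nested fit."""

    f_value: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    selected: str  # "MM" or "IS"
    wssr_simple: float
    wssr_complex: float
    clamped: bool = False  # True when the raw numerator was negative

    def to_dict(self) -> dict:
        return {
            "f_value": self.f_value,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "selected": self.selected,
            "wssr_simple": self.wssr_simple,
            "wssr_complex": self.wssr_complex,
            "clamped": self.clamped,
        }

    def summary(self) -> str:
        return (
            f"F({self.df_num}, {self.df_den}) = {self.f_value:.4g}, "
            f"p = {self.p_value:.4g} (alpha = {self.alpha:g}) -> "
            f"{'interacting-sites' if self.selected == 'IS' else 'Michaelis-Menten'}"
        )


def f_statistic(
    wssr_simple: float,
    wssr_complex: float,
    p_simple: int,
    p_complex: int,
    n: int,
) -> float:
    """Extra-sum-of-squares F statistic.

    A negative numerator (the complex fit did not actually improve, which
    can happen up to solver tolerance) clamps F to 0 with a warning.
    """
    if wssr_simple < 0 or wssr_complex < 0:
        raise ValueError("weighted SSR values must be non-negative")
    if p_complex <= p_simple:
        raise ValueError("p_complex must exceed p_simple")
    if n <= p_complex:
        raise ValueError(
            f"need more points than parameters: n={n}, p_complex={p_complex}"
        )
    num = (wssr_simple - wssr_complex) / (p_complex - p_simple)
    if num < 0:
        warnings.warn(
            "complex model has larger weighted SSR than the simple one; "
            "clamping F to 0",
            stacklevel=2,
        )
        return 0.0
    if wssr_complex == 0:
        return np.inf if num > 0 else 0.0
    return float(num / (wssr_complex / (n - p_complex)))


def select_model(
    fit_mm: KineticFitResults,
    fit_is: KineticFitResults,
    alpha: float = 0.05,
) -> ModelComparison:
    """Choose between the MM and interacting-sites fits of one dataset."""
    if fit_mm.model_id != "MM" or fit_is.model_id != "IS":
        raise ValueError("expected an MM fit and an IS fit, in that order")
    if fit_mm.model.dataset is not fit_is.model.dataset and not (
        np.array_equal(fit_mm.model.dataset.c0, fit_is.model.dataset.c0)
        and np.array_equal(fit_mm.model.dataset.v0, fit_is.model.dataset.v0)
    ):
        raise ValueError("the two fits are not on the same dataset")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = len(fit_mm.model.dataset)
    p_s, p_c = len(fit_mm.param_names), len(fit_is.param_names)
    raw_num = fit_mm.wssr - fit_is.wssr
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_value = f_statistic(fit_mm.wssr, fit_is.wssr, p_s, p_c, n)
    df_num, df_den = p_c - p_s, n - p_c
    p_value = float(f_dist.sf(f_value, df_num, df_den))
    return ModelComparison(
        f_value=f_value,
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        alpha=alpha,
        selected="IS" if p_value < alpha else "MM",
        wssr_simple=fit_mm.wssr,
        wssr_complex=fit_is.wssr,
        clamped=bool(raw_num < 0),
    )


def fit_and_select(
    dataset,
    weighting: str = "sd",
    cv: float = 0.05,
    n_starts: int = 20,
    mm_starts: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[KineticFitResults, KineticFitResults, ModelComparison]:
    """Fit both rate laws to one dataset and run the F-test.

    The MM fit is computed once and reused as the embedded start of the
    interacting-sites search, which both saves work and enforces the
    nesting inequality wssr(IS) <= wssr(MM).
    """
    res_mm = MichaelisMenten(dataset, weighting, cv).fit(
        n_starts=n_starts if mm_starts is None else mm_starts, seed=seed
    )
    res_is = InteractingSites(dataset, weighting, cv, mm_results=res_mm).fit(
        n_starts=n_starts, seed=seed
    )
    return res_mm, res_is, select_model(res_mm, res_is, alpha=alpha)
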