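"""Initial-velocity rate laws.

Two algebraically equivalent printed forms of the interacting-sites law are
provided.  Writing K1 = Km1, V1 = Vmax1:

form "eq1"::

    v0(c0) = (2*V1*c0/K1 + 2*b*V1*c0^2/(a*K1^2))
             / (1 + 2*c0/K1 + c0^2/(a*K1^2))

form "eq2" (in terms of Km2 = a*K1, Vmax2 = b*V1)::

    v0(c0) = (2*V1*Km2*c0 + 2*Vmax2*c0^2)
             / (K1*Km2 + 2*Km2*c0 + c0^2)

Both vanish at c0 = 0, approach 2*Vmax2 as c0 -> inf, and have
low-concentration slope 2*Vmax1/Km1.  With a = b = 1 the law reduces to
Michaelis–Menten with Vmax = 2*Vmax1 and Km = Km1.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike

from .params import ISParams, MMParams

__all__ = ["eval_mm", "eval_interacting_sites"]


def _check_concentrations(c0: ArrayLike) -> np.ndarray:
    c = np.asarray(c0, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return c


def eval_mm(params: MMParams, c0: ArrayLike) -> np.ndarray | float:
    """Michaelis–Menten velocity Vmax*c0/(Km + c0).

    Monotone non-decreasing in c0 and bounded above by Vmax.  Accepts scalar
    or array concentrations (mM); returns velocities in U mg^-1.
    """
    c = _check_concentrations(c0)
    v = params.Vmax * c / (params.Km + c)
    return v if v.ndim else float(v)


def eval_interacting_sites(
    params: ISParams, c0: ArrayLike, form: str = "eq1"
) -> np.ndarray | float:
    """Interacting-sites velocity, evaluated with either printed form.

    Parameters
    ----------
    params : ISParams
    c0 : array-like
        Variable-substrate concentration(s), mM, >= 0.
    form : {"eq1", "eq2"}
        Which algebraic expression to evaluate.  Both agree to floating-point
        round-off; "eq1" is written in (Km1, Vmax1, a, b), "eq2" in
        (Km1, Km2, Vmax1, Vmax2).
    """
    c = _check_concentrations(c0)
    K1, V1, a, b = params.Km1, params.Vmax1, params.a, params.b
    if form == "eq1":
        num = 2.0 * V1 * c / K1 + 2.0 * b * V1 * c**2 / (a * K1**2)
        den = 1.0 + 2.0 * c / K1 + c**2 / (a * K1**2)
    elif form == "eq2":
        K2, V2 = params.Km2, params.Vmax2
        num = 2.0 * V1 * K2 * c + 2.0 * V2 * c**2
        den = K1 * K2 + 2.0 * K2 * c + c**2
    else:
        raise ValueError(f"form must be 'eq1' or 'eq2', got {form!r}")
    v = num / den
    return v if v.ndim else float(v)
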