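"""Parameter bundles for the Michaelis–Menten and interacting-sites rate laws.

The interacting-sites model describes a dimer of catalytic sites in which
occupation of one site changes the apparent Michaelis constant of its
neighbour by a factor ``a`` and the apparent maximal velocity by a factor
``b``:  Km2 = a * Km1 and Vmax2 = b * Vmax1.  ``a > 1`` with ``b`` near 1 is
the signature of negative cooperativity in substrate binding; ``a < 1``
indicates positive cooperativity.

Units follow the assay convention throughout: concentrations in mM,
velocities in U mg^-1 (micromol substrate converted per minute per mg
enzyme).  Unit conversion is the caller's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _require_positive_finite(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(
                f"{name} must be strictly positive and finite, got {value!r}"
            )


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten parameters.

    Parameters
    ----------
    Km : float
        Michaelis constant, mM.  Strictly positive.
    Vmax : float
        Maximal velocity, U mg^-1.  Strictly positive.
    """

    Km: float
    Vmax: float

    def __post_init__(self) -> None:
        _require_positive_finite(Km=self.Km, Vmax=self.Vmax)


@dataclass(frozen=True)
class ISParams:
    """Interacting-sites (two-site allosteric) parameters.

    The canonical parameterization is (Km1, Vmax1, a, b); the second-site
    constants Km2 = a*Km1 and Vmax2 = b*Vmax1 are derived views.

    Parameters
    ----------
    Km1 : float
        Apparent Michaelis constant of a site when its neighbour is free, mM.
    Vmax1 : float
        Apparent maximal velocity of a site when its neighbour is free,
        U mg^-1.
    a : float
        Michaelis-constant interaction factor, dimensionless.
    b : float
        Maximal-velocity interaction factor, dimensionless.
    """

    Km1: float
    Vmax1: float
    a: float
    b: float

    def __post_init__(self) -> None:
        _require_positive_finite(Km1=self.Km1, Vmax1=self.Vmax1, a=self.a, b=self.b)
        _require_positive_finite(Km2=self.a * self.Km1, Vmax2=self.b * self.Vmax1)

    @property
    def Km2(self) -> float:
        """Apparent Michaelis constant with the neighbouring site occupied."""
        return self.a * self.Km1

    @property
    def Vmax2(self) -> float:
        """Apparent maximal velocity with the neighbouring site occupied."""
        return self.b * self.Vmax1

    @classmethod
    def from_site_constants(
        cls, Km1: float, Vmax1: float, Km2: float, Vmax2: float
    ) -> "ISParams":
        """Build from the two sites' (Km, Vmax) pairs."""
        a, b = interaction_factors(Km1, Km2, Vmax1, Vmax2)
        return cls(Km1=Km1, Vmax1=Vmax1, a=a, b=b)


def interaction_factors(
    Km1: float, Km2: float, Vmax1: float, Vmax2: float
) -> tuple[float, float]:
    """Interaction factors (a, b) from the two sites' constants.

    a = Km2/Km1 and b = Vmax2/Vmax1; round-trips with
    :func:`derive_secondary_parameters` to machine precision.
    """
    _require_positive_finite(Km1=Km1, Km2=Km2, Vmax1=Vmax1, Vmax2=Vmax2)
    return Km2 / Km1, Vmax2 / Vmax1


def derive_secondary_parameters(params: ISParams) -> tuple[float, float]:
    """Second-site constants (Km2, Vmax2) = (a*Km1, b*Vmax1)."""
    return params.Km2, params.Vmax2


def saturating_velocity(params: ISParams) -> float:
    """Limiting velocity at saturating variable substrate: 2*Vmax2.

    Both sites of the dimer turn over with the occupied-neighbour velocity
    Vmax2, so the hexamer-normalized rate law plateaus at 2*b*Vmax1.  Note
    that reports sometimes quote Vmax2 itself as "the activity"; this
    function always returns the rate-law plateau 2*Vmax2 and the raw Vmax2
    remains available as ``params.Vmax2``.
    """
    return 2.0 * params.b * params.Vmax1
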