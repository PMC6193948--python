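"""Published kinetic parameters for hexameric E. coli PNP.

Transcription of the published table of interacting-sites parameters for
the wild-type (WT) enzyme and its Asp204Ala/Arg217Ala double mutant (DM),
fitted to initial-velocity data with either phosphate or the nucleoside as
the variable substrate.  Each printed number is stored together with its
number of printed decimal places so that consistency checks can honour the
rounding of the source: the printed interaction factors a = Km2/Km1 and
b = Vmax2/Vmax1 were computed from unrounded fits, so recomputing them from
the rounded table entries can differ in the last digit.

Units: Km in mM, Vmax in U mg^-1; a and b dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Printed", "KineticTableRow", "KINETIC_PARAMETER_TABLE", "WT_M7GUO_TRUTH"]


@dataclass(frozen=True)
class Printed:
    """A published number and the decimal places it was printed with.

    ``approximate`` marks entries the source prints with a tilde and flags
    as having relative errors above 50%; for those the consistency radius
    is taken as 10% of the value rather than half a last digit.
    """

    value: float
    decimals: int
    approximate: bool = False

    @property
    def half_ulp(self) -> float:
        """Rounding radius implied by how the number was printed."""
        base = 0.5 * 10.0 ** (-self.decimals)
        if self.approximate:
            return max(base, 0.1 * abs(self.value))
        return base

    @property
    def lo(self) -> float:
        return self.value - self.half_ulp

    @property
    def hi(self) -> float:
        return self.value + self.half_ulp


@dataclass(frozen=True)
class KineticTableRow:
    enzyme: str  # WT | DM | NR (non-recombinant, literature)
    nucleoside: str  # Ado | m7Guo
    variable_substrate: str  # phosphate | nucleoside
    Km1: Printed
    Vmax1: Printed
    Km2: Printed
    Vmax2: Printed
    a: Printed
    b: Printed
    source: str = "this_study"

    def interaction_factor_bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Ranges of Km2/Km1 and Vmax2/Vmax1 under printed-rounding of inputs."""
        a_range = (self.Km2.lo / self.Km1.hi, self.Km2.hi / self.Km1.lo)
        b_range = (self.Vmax2.lo / self.Vmax1.hi, self.Vmax2.hi / self.Vmax1.lo)
        return a_range, b_range


KINETIC_PARAMETER_TABLE: tuple[KineticTableRow, ...] = (
    KineticTableRow(
        "NR", "m7Guo", "phosphate",
        Km1=Printed(0.015, 3), Vmax1=Printed(16, 0),
        Km2=Printed(0.135, 3), Vmax2=Printed(11, 0),
        a=Printed(9, 0), b=Printed(0.69, 2),
        source="literature",
    ),
    KineticTableRow(
        "WT", "m7Guo", "phosphate",
        Km1=Printed(0.015, 3), Vmax1=Printed(10.8, 1),
        Km2=Printed(4.0, 1), Vmax2=Printed(8.2, 1),
        a=Printed(267, 0), b=Printed(0.76, 2),
    ),
    KineticTableRow(
        "DM", "m7Guo", "phosphate",
        Km1=Printed(0.066, 3), Vmax1=Printed(32.5, 1),
        Km2=Printed(6.8, 1), Vmax2=Printed(44.2, 1),
        a=Printed(103, 0), b=Printed(1.4, 1),
    ),
    KineticTableRow(
        "WT", "Ado", "phosphate",
        Km1=Printed(0.23, 2), Vmax1=Printed(20.8, 1),
        Km2=Printed(3.6, 1), Vmax2=Printed(19.3, 1),
        a=Printed(15.9, 1), b=Printed(0.93, 2),
    ),
    KineticTableRow(
        "DM", "Ado", "phosphate",
        Km1=Printed(0.28, 2), Vmax1=Printed(0.021, 3),
        Km2=Printed(15.2, 1), Vmax2=Printed(0.050, 3),
        a=Printed(55, 0), b=Printed(2.4, 1),
    ),
    KineticTableRow(
        "DM", "m7Guo", "nucleoside",
        Km1=Printed(0.110, 3, approximate=True), Vmax1=Printed(18, 0, approximate=True),
        Km2=Printed(0.024, 3), Vmax2=Printed(29.2, 1),
        a=Printed(0.22, 2), b=Printed(1.5, 1, approximate=True),
    ),
    KineticTableRow(
        "DM", "Ado", "nucleoside",
        Km1=Printed(0.013, 3), Vmax1=Printed(0.011, 3),
        Km2=Printed(0.005, 3), Vmax2=Printed(0.043, 3),
        a=Printed(0.38, 2), b=Printed(4.0, 1, approximate=True),
    ),
)

#: Canonical simulation truth: the WT/m7Guo phosphate-variable row expressed
#: in the (Km1, Vmax1, a, b) parameterization with exact Km2 = 4.0 and
#: Vmax2 = 8.2 (a = 4.0/0.015, b = 8.2/10.8).
WT_M7GUO_TRUTH = {
    "Km1": 0.015,
    "Vmax1": 10.8,
    "a": 4.0 / 0.015,
    "b": 8.2 / 10.8,
}
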