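"""Hansen-space geometry: triples, spheres, distances and RED.

The Hansen framework decomposes a compound's cohesive energy density into
three partial solubility parameters, all in MPa^0.5:

* ``delta_d`` — dispersion (London) interactions,
* ``delta_p`` — polar (dipole) interactions,
* ``delta_h`` — hydrogen-bonding interactions.

The total parameter is the Euclidean norm, ``delta_t**2 = delta_d**2 +
delta_p**2 + delta_h**2``.  Solute–solvent affinity is measured by the
Hansen distance

    Ra = sqrt(4*(dD_a - dD_b)**2 + (dP_a - dP_b)**2 + (dH_a - dH_b)**2)

where the conventional factor 4 doubles the weight of the dispersion axis,
and by the relative energy difference RED = Ra / R0, with R0 the interaction
radius of the solute's solubility sphere.  RED < 1 predicts a good solvent;
RED near 1 is a boundary case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal


class HansenError(ValueError):
    """Base class for domain validation errors."""


class InvalidTripleError(HansenError):
    """A Hansen triple had a negative or non-finite component."""


class InvalidSphereError(HansenError):
    """A solubility sphere had a non-positive interaction radius."""


@dataclass(frozen=True)
class HspTriple:
    """A point in Hansen space (``delta_d``, ``delta_p``, ``delta_h``), MPa^0.5."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        for name in ("delta_d", "delta_p", "delta_h"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise InvalidTripleError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise InvalidTripleError(f"{name} must be >= 0, got {value}")

    @property
    def total(self) -> float:
        """Total solubility parameter delta_t (MPa^0.5)."""
        return math.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_d, self.delta_p, self.delta_h)

    def to_dict(self) -> dict[str, float]:
        return {
            "delta_d": self.delta_d,
            "delta_p": self.delta_p,
            "delta_h": self.delta_h,
        }


@dataclass(frozen=True)
class HansenSphere:
    """A solute's Hansen solubility sphere: center plus interaction radius R0."""

    center: HspTriple
    radius_r0: float
    solute_name: str = ""
    provenance: Literal["fitted", "literature"] = "fitted"

    def __post_init__(self) -> None:
        if not math.isfinite(self.radius_r0) or self.radius_r0 <= 0:
            raise InvalidSphereError(
                f"radius_r0 must be a positive finite number, got {self.radius_r0!r}"
            )

    def to_dict(self) -> dict:
        return {
            "solute": self.solute_name,
            "center": self.center.to_dict(),
            "r0": self.radius_r0,
            "provenance": self.provenance,
        }


@dataclass(frozen=True)
class RdComparison:
    """Relative deviation between an HSP from this analysis and a literature value.

    ``rd_percent = |this_work - literature| / denominator * 100`` with the
    denominator picked by ``denominator_convention``.  The default convention
    divides by the literature value.
    """

    this_work: float
    literature: float
    rd_percent: float
    denominator_convention: Literal["literature", "this_work"] = "literature"


def total_parameter(t: HspTriple) -> float:
    """Total solubility parameter delta_t = sqrt(dD**2 + dP**2 + dH**2)."""
    return t.total


def hansen_distance(a: HspTriple, b: HspTriple, *, visual: bool = False) -> float:
    """Hansen distance Ra between two points in Hansen space (MPa^0.5).

    By default the dispersion difference is weighted by the conventional
    factor 4.  ``visual=True`` drops that factor, giving the plain Euclidean
    distance as seen in 3-D sphere renderings; that variant must not be used
    for RED-based solvent selection.
    """
    w = 1.0 if visual else 4.0
    return math.sqrt(
        w * (a.delta_d - b.delta_d) ** 2
        + (a.delta_p - b.delta_p) ** 2
        + (a.delta_h - b.delta_h) ** 2
    )


def red(solute: HansenSphere, solvent: HspTriple) -> float:
    """Relative energy difference RED = Ra / R0 (dimensionless).

    RED < 1 places the solvent inside the solute's solubility sphere
    (predicted good solvent); RED > 1 places it outside.
    """
    return hansen_distance(solute.center, solvent) / solute.radius_r0


def relative_deviation(
    this_work: float,
    literature: float,
    convention: Literal["literature", "this_work"] = "literature",
) -> RdComparison:
    """Percent relative deviation between a fitted and a literature HSP.

    The magnitude of the difference is divided by the literature value
    (default) or by the fitted value, per ``convention``.
    """
    if convention not in ("literature", "this_work"):
        raise HansenError(f"unknown denominator convention {convention!r}")
    denominator = literature if convention == "literature" else this_work
    if denominator == 0:
        raise HansenError(f"zero denominator for convention {convention!r}")
    rd = abs(this_work - literature) / abs(denominator) * 100.0
    return RdComparison(this_work, literature, rd, convention)


# Display rounding used in human-readable reports: HSPs to 1 decimal,
# RED to 2 decimals, RD to 1 decimal.  Full precision is kept internally.

def round_hsp(value: float) -> float:
    return round(value, 1)


def round_red(value: float) -> float:
    return round(value, 2)


def round_rd(value: float) -> float:
    return round(value, 1)
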