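"""RED screening of binary solvent blends.

The HSPs of a binary mixture are the mole-fraction-weighted average of the
two pure solvents' parameters, component by component:

    delta_i(mix) = delta_i(1) * x1 + delta_i(2) * (1 - x1),   i = D, P, H.

Because the blend moves linearly through Hansen space, the squared Hansen
distance to a solute center is a convex quadratic in composition, so a RED
profile has at most one interior minimum.  An interior minimum strictly
below both pure-solvent REDs predicts a synergistic blend: a solubility
maximum at (approximately) the minimum-RED composition.  Profiles are
indexed by the mole fraction of solvent 2 (the ketone cosolvent in typical
alcohol + ketone screens).

Mole-fraction weighting is the default and the convention used throughout;
a volume-fraction variant is available but needs user-supplied molar
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd

from .core import HansenError, HansenSphere, HspTriple, hansen_distance, red
from .solvents import SolventRecord


class MixtureError(HansenError):
    """Invalid mixture specification."""


def default_grid(step: float = 0.1) -> tuple[float, ...]:
    """Composition grid 0, step, ..., 1 (pure endpoints included)."""
    n = int(round(1.0 / step))
    return tuple(round(i * step, 10) for i in range(n + 1))


@dataclass(frozen=True)
class BinaryMixtureSpec:
    """Two solvents plus a strictly increasing grid of solvent-2 mole fractions."""

    solvent1: SolventRecord
    solvent2: SolventRecord
    grid: tuple[float, ...] = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise MixtureError("empty composition grid")
        if g.min() < 0 or g.max() > 1:
            raise MixtureError("grid mole fractions must lie in [0, 1]")
        if np.any(np.diff(g) <= 0):
            raise MixtureError("grid must be strictly increasing")

    @property
    def system(self) -> str:
        return f"{self.solvent1.name} + {self.solvent2.name}"


@dataclass(frozen=True)
class ProfilePoint:
    x2: float
    mix_hsp: HspTriple
    ra: float
    red: float


@dataclass(frozen=True)
class RedProfile:
    """RED versus composition for one solute / binary-solvent system."""

    solute: HansenSphere
    mixture: BinaryMixtureSpec
    points: tuple[ProfilePoint, ...]
    shape: Literal["interior_minimum", "monotonic"]
    x_min_grid: float
    x_min_closed_form: float
    red_min_closed_form: float
    curvature: float  # quadratic coefficient of Ra^2(x); flatness diagnostic

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x2": p.x2,
                    "delta_d": p.mix_hsp.delta_d,
                    "delta_p": p.mix_hsp.delta_p,
                    "delta_h": p.mix_hsp.delta_h,
                    "ra": p.ra,
                    "red": p.red,
                }
                for p in self.points
            ]
        )

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def mix_hsp(s1: HspTriple, s2: HspTriple, x1: float) -> HspTriple:
    """Mixture HSPs at mole fraction ``x1`` of solvent 1 (linear blend)."""
    if not 0.0 <= x1 <= 1.0:
        raise MixtureError(f"mole fraction must be in [0, 1], got {x1}")
    x2 = 1.0 - x1
    return HspTriple(
        s1.delta_d * x1 + s2.delta_d * x2,
        s1.delta_p * x1 + s2.delta_p * x2,
        s1.delta_h * x1 + s2.delta_h * x2,
    )


def mix_hsp_volume(
    s1: HspTriple, s2: HspTriple, x1: float, molar_volume1: float, molar_volume2: float
) -> HspTriple:
    """Volume-fraction blend (non-default); needs molar volumes in cm3/mol."""
    if molar_volume1 <= 0 or molar_volume2 <= 0:
        raise MixtureError("molar volumes must be positive")
    if not 0.0 <= x1 <= 1.0:
        raise MixtureError(f"mole fraction must be in [0, 1], got {x1}")
    v1 = x1 * molar_volume1
    v2 = (1.0 - x1) * molar_volume2
    phi1 = v1 / (v1 + v2)
    return mix_hsp(s1, s2, phi1)


def _quadratic_coefficients(
    solute: HansenSphere, s1: HspTriple, s2: HspTriple
) -> tuple[float, float, float]:
    """Coefficients of Ra^2(x) = a x^2 + b x + c, x = mole fraction of solvent 2."""
    w = np.array([4.0, 1.0, 1.0])  # factor-4 dispersion weighting
    v = np.array(s1.as_tuple()) - np.array(solute.center.as_tuple())
    u = np.array(s2.as_tuple()) - np.array(s1.as_tuple())
    a = float(np.sum(w * u * u))
    b = float(2.0 * np.sum(w * u * v))
    c = float(np.sum(w * v * v))
    return a, b, c


def min_red_closed_form(
    solute: HansenSphere, s1: HspTriple, s2: HspTriple
) -> tuple[float, float]:
    """Exact minimum-RED composition along the s1 -> s2 mixing segment.

    Returns ``(x_star, red_min)`` with ``x_star`` the mole fraction of
    solvent 2.  Since Ra^2 is quadratic with non-negative curvature, the
    unconstrained vertex is clamped to [0, 1]; a degenerate (constant)
    profile returns x_star = 0.
    """
    a, b, c = _quadratic_coefficients(solute, s1, s2)
    if a > 0:
        x_star = min(1.0, max(0.0, -b / (2.0 * a)))
    else:
        # s1 == s2 in Hansen space: profile is constant; report the left endpoint.
        x_star = 0.0
    ra_sq = max(0.0, a * x_star**2 + b * x_star + c)
    return x_star, float(np.sqrt(ra_sq) / solute.radius_r0)


def red_profile(solute: HansenSphere, mixture: BinaryMixtureSpec) -> RedProfile:
    """RED at every grid composition, with shape and minimum diagnostics.

    ``shape`` is ``interior_minimum`` when the grid minimum lies strictly
    below both endpoint REDs (synergy expected), else ``monotonic``.
    Grid ties resolve to the smaller solvent-2 fraction.
    """
    s1, s2 = mixture.solvent1.hsp, mixture.solvent2.hsp
    points = []
    for x2 in mixture.grid:
        m = mix_hsp(s1, s2, 1.0 - x2)
        ra = hansen_distance(solute.center, m)
        points.append(ProfilePoint(float(x2), m, ra, ra / solute.radius_r0))

    reds = np.array([p.red for p in points])
    # ties (within float noise, e.g. a flat profile) resolve to the smaller x
    idx_min = int(np.flatnonzero(reds <= reds.min() + 1e-12)[0])
    x_min_grid = points[idx_min].x2

    end_lo = red(solute, mix_hsp(s1, s2, 1.0))
    end_hi = red(solute, mix_hsp(s1, s2, 0.0))
    interior = reds[idx_min] < end_lo and reds[idx_min] < end_hi
    shape = "interior_minimum" if interior else "monotonic"

    x_star, red_min = min_red_closed_form(solute, s1, s2)
    a, _, _ = _quadratic_coefficients(solute, s1, s2)
    return RedProfile(
        solute=solute,
        mixture=mixture,
        points=tuple(points),
        shape=shape,
        x_min_grid=float(x_min_grid),
        x_min_closed_form=float(x_star),
        red_min_closed_form=red_min,
        curvature=a,
    )


def predict_synergy(solute: HansenSphere, mixture: BinaryMixtureSpec) -> dict:
    """Serializable synergy report for one solute / binary-solvent system.

    ``synergy`` is true when the RED profile has an interior minimum, i.e.
    some blend matches the solute better than either pure solvent.
    """
    profile = red_profile(solute, mixture)
    reds = [p.red for p in profile.points]
    return {
        "system": mixture.system,
        "solute": solute.solute_name,
        "synergy": profile.shape == "interior_minimum",
        "x_at_min": profile.x_min_grid,
        "red_at_min": float(min(reds)),
        "x_min_closed_form": profile.x_min_closed_form,
        "red_min_closed_form": profile.red_min_closed_form,
        "endpoint_reds": [reds[0], reds[-1]],
        "curvature": profile.curvature,
    }
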