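"""Constrained fitting of a solute's Hansen solubility sphere.

Given good/bad solvent labels and the solvents' literature HSPs, the fitter
searches for the center (delta_d, delta_p, delta_h) and interaction radius
R0 that best separate good solvents (inside, RED <= 1) from bad ones
(outside, RED > 1).

Constraints (physically motivated for polyphenol-like solutes):

    10 <= delta_d <= 25,   5 <= delta_p <= 25,   5 <= delta_h <= 25,
    R0 >= 1,  R0 >= Ra_good_max  (every good solvent inside the sphere).

The radius is handled by substitution rather than penalty: candidates are
parameterized as (delta_d, delta_p, delta_h, s) with

    R0 = max(1, Ra_good_max) + s,        s in [0, slack_max],

so every candidate satisfies the containment constraint by construction.
The nominal handbook guideline R0 <= 10 can conflict with containment when
a distant good solvent binds the radius; containment wins and a
:class:`ConstraintConflictWarning` names the binding solvent.

The maximized objective is a penalized data-fit desirability: the geometric
mean of per-solvent desirabilities d_i, with d_i = 1 for a correctly
classified solvent and d_i = exp(-|Ra_i - R0|) otherwise, so the objective
reaches 1 exactly at perfect separation and decays with how deep each
misclassified solvent sits on the wrong side of the boundary.  On the
perfect-separation plateau ties are resolved hierarchically: first toward a
larger separation margin between the outermost good and innermost bad
solvent (a weakly weighted bonus that centers the boundary in the gap
between the classes), then toward smaller R0 by a tiny radius penalty.

The global search is a seeded evolutionary algorithm
(:func:`scipy.optimize.differential_evolution`) restarted ``n_restarts``
times; the initial guess for the center is the component-wise mean of the
good solvents' HSPs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .classify import SolubilityMeasurement, SolventLabel, classify
from .core import HansenError, HansenSphere, HspTriple
from .solvents import SolventLibrary, lookup

R0_GUIDELINE_MAX = 10.0
R0_MIN = 1.0
MARGIN_TIE_WEIGHT = 1e-3


class FitError(HansenError):
    """Sphere fitting could not be carried out."""


class NoGoodSolventsError(FitError):
    """At least one good solvent is required to anchor the sphere."""


class ConstraintConflictWarning(UserWarning):
    """Containment of a good solvent forces R0 beyond the nominal bound."""


class DegenerateLabelsWarning(UserWarning):
    """All solvents share one label; the fit is under-determined."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings; defaults encode the printed constraint box."""

    bounds: tuple[tuple[float, float], ...] = ((10.0, 25.0), (5.0, 25.0), (5.0, 25.0))
    slack_max: float = 2.0
    seed: int = 42
    n_restarts: int = 10
    popsize: int = 20
    maxiter: int = 300
    polish: bool = True
    objective: str = "penalized_datafit"
    tie_break_weight: float = 1e-7

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PerSolvent:
    name: str
    label: str
    ra: float
    red: float
    correctly_classified: bool


@dataclass(frozen=True)
class FitResult:
    """Fitted (or evaluated) sphere plus per-solvent diagnostics.

    ``data_fit_percent`` is 100 x (correctly classified solvents) / (total),
    where correct means good with RED <= 1 or bad with RED > 1.
    ``objective_value`` is the geometric-mean desirability (1 at perfect
    separation).
    """

    sphere: HansenSphere
    data_fit_percent: float
    per_solvent: tuple[PerSolvent, ...]
    objective_value: float
    n_evaluations: int = 0
    seed_used: Optional[int] = None

    def to_dict(self) -> dict:
        d = self.sphere.to_dict()
        d.update(
            data_fit_percent=self.data_fit_percent,
            objective_value=self.objective_value,
            n_evaluations=self.n_evaluations,
            seed=self.seed_used,
            per_solvent=[
                {
                    "name": p.name,
                    "label": p.label,
                    "ra": p.ra,
                    "red": p.red,
                    "correctly_classified": p.correctly_classified,
                }
                for p in self.per_solvent
            ],
        )
        return d


def _resolve(labels: Sequence[SolventLabel], lib: SolventLibrary):
    names = [l.solvent for l in labels]
    coords = np.array(
        [lookup(lib, name).hsp.as_tuple() for name in names], dtype=float
    )
    good = np.array([l.label == "good" for l in labels], dtype=bool)
    return names, coords, good


def _distances(center: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Factor-4 Hansen distances; ``center`` shape (3,) or (3, S)."""
    c = np.atleast_2d(center.T).T  # (3, S)
    diff_d = c[0][None, :] - coords[:, 0][:, None]
    diff_p = c[1][None, :] - coords[:, 1][:, None]
    diff_h = c[2][None, :] - coords[:, 2][:, None]
    return np.sqrt(4.0 * diff_d**2 + diff_p**2 + diff_h**2)  # (n, S)


def _fitness(z: np.ndarray, coords: np.ndarray, good: np.ndarray, tie: float):
    """Negative desirability (to minimize) for candidates z of shape (4,) or (4, S).

    Tie-break hierarchy on the perfect-classification plateau: a small bonus
    for the separation margin (min bad Ra - max good Ra) centers the sphere
    boundary inside the empty annulus between the two classes, and a tiny
    radius penalty then drives the slack s to zero (smallest feasible R0).
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 1
    if scalar:
        z = z[:, None]
    ra = _distances(z[:3], coords)  # (n, S)
    ra_good_max = ra[good].max(axis=0)  # (S,)
    r0 = np.maximum(R0_MIN, ra_good_max) + z[3]
    red = ra / r0[None, :]
    inside = red <= 1.0
    correct = np.where(good[:, None], inside, ~inside)
    log_d = np.where(correct, 0.0, -np.abs(ra - r0[None, :]))
    objective = np.exp(log_d.mean(axis=0))
    if (~good).any():
        margin = ra[~good].min(axis=0) - ra_good_max
    else:
        margin = np.zeros_like(r0)
    fitness = -objective - MARGIN_TIE_WEIGHT * margin + tie * r0
    return fitness[0] if scalar else fitness


def _diagnostics(
    sphere: HansenSphere,
    names: Sequence[str],
    coords: np.ndarray,
    good: np.ndarray,
    labels: Sequence[SolventLabel],
):
    center = np.array(sphere.center.as_tuple())
    ra = _distances(center, coords)[:, 0]
    red = ra / sphere.radius_r0
    inside = red <= 1.0
    correct = np.where(good, inside, ~inside)
    per = tuple(
        PerSolvent(n, l.label, float(a), float(r), bool(c))
        for n, l, a, r, c in zip(names, labels, ra, red, correct)
    )
    data_fit = 100.0 * correct.mean()
    log_d = np.where(correct, 0.0, -np.abs(ra - sphere.radius_r0))
    objective = float(np.exp(log_d.mean()))
    return per, float(data_fit), objective


def evaluate_sphere(
    sphere: HansenSphere, labels: Sequence[SolventLabel], lib: SolventLibrary
) -> FitResult:
    """Per-solvent Ra/RED and data-fit percentage for a given sphere.

    No optimization: use this to audit any sphere, including literature ones.
    """
    if not labels:
        raise FitError("no labels supplied")
    names, coords, good = _resolve(labels, lib)
    per, data_fit, objective = _diagnostics(sphere, names, coords, good, labels)
    return FitResult(sphere, data_fit, per, objective)


def fit_sphere(
    labels: Sequence[SolventLabel],
    lib: SolventLibrary,
    config: Optional[FitConfig] = None,
    solute_name: str = "",
) -> FitResult:
    """Fit center and radius to good/bad labels by seeded global optimization.

    Deterministic for a fixed ``config.seed``.  Requires at least four
    labeled solvents, at least one of them good.
    """
    config = config or FitConfig()
    if len(labels) < 4:
        raise FitError(f"need >= 4 labeled solvents, got {len(labels)}")
    names, coords, good = _resolve(labels, lib)
    if not good.any():
        raise NoGoodSolventsError("no good solvents: the sphere is unanchored")
    if good.all():
        warnings.warn(
            "all solvents are good: returning the minimal feasible enclosing sphere",
            DegenerateLabelsWarning,
            stacklevel=2,
        )

    lo = np.array([b[0] for b in config.bounds] + [0.0])
    hi = np.array([b[1] for b in config.bounds] + [config.slack_max])
    x0 = np.empty(4)
    x0[:3] = np.clip(coords[good].mean(axis=0), lo[:3], hi[:3])
    x0[3] = 0.0

    best = None
    n_evals = 0
    for restart in range(config.n_restarts):
        rng = np.random.default_rng([config.seed, restart])
        result = differential_evolution(
            _fitness,
            bounds=list(zip(lo, hi)),
            args=(coords, good, config.tie_break_weight),
            seed=rng,
            x0=x0,
            maxiter=config.maxiter,
            popsize=config.popsize,
            tol=1e-8,
            mutation=(0.5, 1.0),
            recombination=0.7,
            polish=config.polish,
            vectorized=True,
            updating="deferred",
        )
        n_evals += int(result.nfev)
        if best is None or result.fun < best.fun:
            best = result

    z = np.clip(best.x, lo, hi)
    center = HspTriple(*z[:3])
    ra = _distances(np.array(z[:3]), coords)[:, 0]
    ra_good_max = float(ra[good].max())
    binding = names[int(np.argmax(np.where(good, ra, -np.inf)))]
    r0 = max(R0_MIN, ra_good_max) + float(z[3])
    if ra_good_max > R0_GUIDELINE_MAX:
        warnings.warn(
            f"good solvent {binding!r} forces R0 = {r0:.2f} beyond the nominal "
            f"upper bound {R0_GUIDELINE_MAX}; containment takes precedence",
            ConstraintConflictWarning,
            stacklevel=2,
        )
    sphere = HansenSphere(center, r0, solute_name=solute_name, provenance="fitted")
    per, data_fit, objective = _diagnostics(sphere, names, coords, good, labels)
    return FitResult(
        sphere,
        data_fit,
        per,
        objective,
        n_evaluations=n_evals,
        seed_used=config.seed,
    )


def threshold_sweep(
    measurements: Sequence[SolubilityMeasurement],
    lib: SolventLibrary,
    thresholds: Sequence[float] = (15.0, 20.0, 30.0),
    overrides: Optional[Mapping[str, str]] = None,
    config: Optional[FitConfig] = None,
    solute_name: str = "",
) -> dict[float, FitResult]:
    """Re-label at several solubility thresholds and refit at each.

    Mirrors the robustness check of re-running the sphere fit with
    alternative classification limits (e.g. 15, 20 and 30 g/L).
    """
    out: dict[float, FitResult] = {}
    for threshold in thresholds:
        labels = classify(measurements, threshold=threshold, overrides=overrides)
        out[float(threshold)] = fit_sphere(labels, lib, config, solute_name=solute_name)
    return out
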