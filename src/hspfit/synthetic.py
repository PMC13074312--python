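"""Synthetic solvent-screening datasets with a known ground-truth sphere.

Emulates the statistical structure of a monosolvent solubility screen:
solvents scattered in a box of Hansen space, a ground-truth solubility
sphere, good/bad labels by RED <= 1, and solubility magnitudes that decay
with RED.  The generative solubility map is declared, not physical:

    s(RED) = s_max * exp(-k * RED^2) * exp(eps),   eps ~ Normal(0, sigma^2)

so with sigma = 0 thresholding at s_max * exp(-k) recovers the sphere
labels exactly.  A boundary margin keeps solvents away from RED ~ 1 where
any classifier is unstable; label noise flips observed labels
independently.  Everything is reproducible from a single seed, with
per-stage substreams derived deterministically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

from .classify import SolubilityMeasurement, SolventLabel, write_measurements_csv
from .core import HansenError, HansenSphere, HspTriple
from .solvents import SolventLibrary, SolventRecord, write_library

# Default sampling box. Chosen so that, against the default truth sphere and
# the factor-4 metric, roughly 40% of sampled solvents are good — the
# good-solvent fraction observed in real monosolvent screens of this kind.
# A wider box (e.g. delta_d up to 20) leaves almost every sample outside the
# sphere and produces screens with no good solvents to anchor a fit.
DEFAULT_BOX = ((13.0, 16.0), (3.0, 17.0), (3.0, 21.0))


class SyntheticError(HansenError):
    """Invalid generator configuration."""


class InfeasibleMarginError(SyntheticError):
    """The boundary margin rejects (almost) every candidate solvent."""


@dataclass(frozen=True)
class SolubilityMap:
    """Parameters of the RED -> solubility decay (g/L)."""

    s_max: float = 100.0
    decay: float = math.log(5.0)  # threshold s_max*exp(-k) = 20 g/L
    sigma: float = 0.25

    @property
    def label_threshold(self) -> float:
        """The g/L threshold that recovers the sphere labels when sigma = 0."""
        return self.s_max * math.exp(-self.decay)


@dataclass(frozen=True)
class SyntheticConfig:
    n_solvents: int = 20
    box: tuple[tuple[float, float], ...] = DEFAULT_BOX
    truth: HansenSphere = field(
        default_factory=lambda: HansenSphere(
            HspTriple(12.0, 10.0, 12.0), 8.0, "synthetic-solute", "literature"
        )
    )
    boundary_margin: float = 0.15
    label_noise: float = 0.0
    solubility_map: SolubilityMap = field(default_factory=SolubilityMap)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_solvents < 1:
            raise SyntheticError("n_solvents must be >= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise SyntheticError("label_noise must be in [0, 0.5)")
        if self.boundary_margin < 0:
            raise SyntheticError("boundary_margin must be >= 0")
        if len(self.box) != 3 or any(lo > hi for lo, hi in self.box):
            raise SyntheticError("box must be three (lo, hi) ranges")

    def to_dict(self) -> dict:
        return {
            "n_solvents": self.n_solvents,
            "box": [list(b) for b in self.box],
            "truth": self.truth.to_dict(),
            "boundary_margin": self.boundary_margin,
            "label_noise": self.label_noise,
            "solubility_map": asdict(self.solubility_map),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated library, measurements, and both true and observed labels."""

    library: SolventLibrary
    measurements: tuple[SolubilityMeasurement, ...]
    true_labels: tuple[SolventLabel, ...]
    observed_labels: tuple[SolventLabel, ...]
    config: SyntheticConfig


def _true_red(coords: np.ndarray, truth: HansenSphere) -> np.ndarray:
    center = np.array(truth.center.as_tuple())
    d = coords - center[None, :]
    return np.sqrt(4.0 * d[:, 0] ** 2 + d[:, 1] ** 2 + d[:, 2] ** 2) / truth.radius_r0


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Sample a screening dataset from the generative model above.

    Solvents are drawn uniformly in the box and rejection-sampled so no
    true RED falls within ``boundary_margin`` of 1.  Raises
    :class:`InfeasibleMarginError` when the rejection rate exceeds 99%.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_points, rng_noise, rng_flip = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    lo = np.array([b[0] for b in config.box])
    hi = np.array([b[1] for b in config.box])
    margin = config.boundary_margin

    accepted: list[np.ndarray] = []
    drawn = kept = 0
    chunk = max(512, 8 * config.n_solvents)
    while sum(len(a) for a in accepted) < config.n_solvents:
        pts = rng_points.uniform(lo, hi, size=(chunk, 3))
        reds = _true_red(pts, config.truth)
        ok = (reds <= 1.0 - margin) | (reds >= 1.0 + margin)
        accepted.append(pts[ok])
        drawn += chunk
        kept += int(ok.sum())
        if drawn >= 100 * chunk and kept / drawn < 0.01:
            raise InfeasibleMarginError(
                f"boundary margin {margin} rejects {100 * (1 - kept / drawn):.1f}% "
                "of candidates; use a smaller margin or a wider box"
            )
    coords = np.concatenate(accepted)[: config.n_solvents]
    reds = _true_red(coords, config.truth)

    smap = config.solubility_map
    eps = (
        rng_noise.normal(0.0, smap.sigma, size=config.n_solvents)
        if smap.sigma > 0
        else np.zeros(config.n_solvents)
    )
    solubility = smap.s_max * np.exp(-smap.decay * reds**2) * np.exp(eps)

    truly_good = reds <= 1.0
    flips = rng_flip.random(config.n_solvents) < config.label_noise

    records, measurements, true_labels, observed_labels = [], [], [], []
    for i in range(config.n_solvents):
        name = f"solvent-{i:03d}"
        records.append(
            SolventRecord(name, HspTriple(*coords[i]), source="synthetic")
        )
        measurements.append(
            SolubilityMeasurement(
                solute=config.truth.solute_name,
                solvent=name,
                solubility_g_per_l=float(solubility[i]),
            )
        )
        true_lab = "good" if truly_good[i] else "bad"
        obs_lab = ("bad" if true_lab == "good" else "good") if flips[i] else true_lab
        rationale = "above_threshold" if true_lab == "good" else "below_threshold"
        true_labels.append(SolventLabel(name, true_lab, rationale))
        observed_labels.append(
            SolventLabel(name, obs_lab, "manual_override" if flips[i] else rationale)
        )

    return SyntheticDataset(
        library=SolventLibrary(tuple(records), version=f"synthetic-seed{config.seed}"),
        measurements=tuple(measurements),
        true_labels=tuple(true_labels),
        observed_labels=tuple(observed_labels),
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: Union[str, Path]) -> dict:
    """Write solvents.csv, solubility.csv and metadata.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "solvents": outdir / "solvents.csv",
        "solubility": outdir / "solubility.csv",
        "metadata": outdir / "metadata.json",
    }
    write_library(dataset.library, paths["solvents"])
    write_measurements_csv(dataset.measurements, paths["solubility"])
    with open(paths["metadata"], "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
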