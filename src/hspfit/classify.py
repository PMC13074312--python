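"""Good/bad solvent classification from equilibrium solubility data.

Sphere fitting needs a binary label per solvent.  A solvent is "good" when
the solute's equilibrium solubility reaches a threshold (20 g/L by default,
inclusive), "bad" otherwise; solvents too insoluble to quantify are bad by
construction.  Explicit per-solvent overrides are supported for judgment
calls near the threshold and are recorded with a ``manual_override``
rationale — they are never inferred.

Classification works in g/L.  Converting to or from mole-fraction
solubility needs solvent density and molar masses and is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import pandas as pd

from .core import HansenError

DEFAULT_THRESHOLD_G_PER_L = 20.0

Label = Literal["good", "bad"]
Rationale = Literal[
    "above_threshold", "below_threshold", "insoluble_unquantifiable", "manual_override"
]


class ClassificationError(HansenError):
    """Invalid measurements or classification settings."""


@dataclass(frozen=True)
class SolubilityMeasurement:
    """One solute-solvent equilibrium solubility datum.

    ``solubility_g_per_l`` is the measured value when ``quantifiable``;
    ``is_lower_bound`` marks entries recorded as "at least this soluble"
    (e.g. >100 g/L), which classify like ordinary values.  Temperature and
    pressure are metadata, defaulting to 298.15 K and 0.1 MPa.
    """

    solute: str
    solvent: str
    solubility_g_per_l: Optional[float] = None
    quantifiable: bool = True
    is_lower_bound: bool = False
    temperature_k: float = 298.15
    pressure_mpa: float = 0.1

    def __post_init__(self) -> None:
        if self.quantifiable:
            if self.solubility_g_per_l is None:
                raise ClassificationError(
                    f"{self.solvent}: quantifiable measurement needs a value"
                )
            if self.solubility_g_per_l < 0:
                raise ClassificationError(
                    f"{self.solvent}: solubility must be >= 0"
                )


@dataclass(frozen=True)
class SolventLabel:
    solvent: str
    label: Label
    rationale: Rationale


def classify(
    measurements: Sequence[SolubilityMeasurement],
    threshold: float = DEFAULT_THRESHOLD_G_PER_L,
    overrides: Optional[Mapping[str, Label]] = None,
) -> list[SolventLabel]:
    """Label each solvent good/bad against a solubility threshold (g/L).

    Quantifiable solubility at or above the threshold gives ``good``
    (inclusive lower bound), below gives ``bad``; unquantifiable entries are
    ``bad``.  ``overrides`` (solvent name -> label) are applied last with
    rationale ``manual_override``.
    """
    if threshold <= 0:
        raise ClassificationError(f"threshold must be > 0, got {threshold}")
    seen: set[str] = set()
    labels: list[SolventLabel] = []
    overrides = dict(overrides or {})
    for m in measurements:
        key = m.solvent.strip().lower()
        if key in seen:
            raise ClassificationError(f"duplicate measurement for {m.solvent!r}")
        seen.add(key)
        if not m.quantifiable:
            lab = SolventLabel(m.solvent, "bad", "insoluble_unquantifiable")
        elif m.solubility_g_per_l >= threshold:
            lab = SolventLabel(m.solvent, "good", "above_threshold")
        else:
            lab = SolventLabel(m.solvent, "bad", "below_threshold")
        forced = overrides.pop(m.solvent, overrides.pop(key, None))
        if forced is not None:
            if forced not in ("good", "bad"):
                raise ClassificationError(f"override for {m.solvent!r} must be good/bad")
            lab = SolventLabel(m.solvent, forced, "manual_override")
        labels.append(lab)
    if overrides:
        raise ClassificationError(
            f"overrides for unmeasured solvents: {sorted(overrides)}"
        )
    return labels


def classification_summary(labels: Sequence[SolventLabel]) -> dict:
    """Deterministic summary: counts plus alphabetically sorted name lists."""
    if not labels:
        raise ClassificationError("no labels to summarize")
    good = sorted(l.solvent for l in labels if l.label == "good")
    bad = sorted(l.solvent for l in labels if l.label == "bad")
    return {
        "n_total": len(labels),
        "n_good": len(good),
        "n_bad": len(bad),
        "good": good,
        "bad": bad,
    }


# ---------------------------------------------------------------- CSV I/O


def read_measurements_csv(path: Union[str, Path]) -> list[SolubilityMeasurement]:
    """Read measurements from CSV (columns ``solute,solvent,solubility_g_per_L,
    quantifiable[,is_lower_bound,temperature_K,pressure_MPa]``)."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ClassificationError(f"empty measurements table: {path}") from exc
    missing = {"solute", "solvent", "solubility_g_per_L", "quantifiable"} - set(
        frame.columns
    )
    if missing:
        raise ClassificationError(f"missing columns: {sorted(missing)}")
    if len(frame) == 0:
        raise ClassificationError(f"measurements table has no rows: {path}")
    out = []
    for _, row in frame.iterrows():
        quant = _as_bool(row["quantifiable"])
        value = row["solubility_g_per_L"]
        out.append(
            SolubilityMeasurement(
                solute=str(row["solute"]),
                solvent=str(row["solvent"]),
                solubility_g_per_l=float(value) if quant and pd.notna(value) else None,
                quantifiable=quant,
                is_lower_bound=_as_bool(row.get("is_lower_bound", False)),
                temperature_k=float(row.get("temperature_K", 298.15)),
                pressure_mpa=float(row.get("pressure_MPa", 0.1)),
            )
        )
    return out


def write_measurements_csv(
    measurements: Sequence[SolubilityMeasurement], path: Union[str, Path]
) -> None:
    rows = [
        {
            "solute": m.solute,
            "solvent": m.solvent,
            "solubility_g_per_L": m.solubility_g_per_l,
            "quantifiable": m.quantifiable,
            "is_lower_bound": m.is_lower_bound,
            "temperature_K": m.temperature_k,
            "pressure_MPa": m.pressure_mpa,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_labels_csv(labels: Sequence[SolventLabel], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [{"solvent": l.solvent, "label": l.label, "rationale": l.rationale} for l in labels]
    ).to_csv(path, index=False)


def read_labels_csv(path: Union[str, Path]) -> list[SolventLabel]:
    frame = pd.read_csv(path)
    missing = {"solvent", "label"} - set(frame.columns)
    if missing:
        raise ClassificationError(f"missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        rationale = row.get("rationale", "above_threshold")
        if pd.isna(rationale):
            rationale = "above_threshold"
        out.append(SolventLabel(str(row["solvent"]), str(row["label"]), str(rationale)))
    return out


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() in ("true", "1", "yes", "t")
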