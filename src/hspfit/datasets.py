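"""Study data for trans-resveratrol and hesperetin.

Bundles the published results of the monosolvent solubility screen of the
two polyphenols at 298.15 K and 0.1 MPa: the fitted Hansen spheres, the
good/bad solvent classifications that produced them (20 g/L threshold,
with the judgment-call override for hesperetin in n-propyl acetate), and
the printed subset of the underlying solubility values.

The source article tabulates the full solubility data only in its
appendix; here the quantified values quoted in the running text are kept
(entries recorded only as "above 100 g/L" carry ``is_lower_bound=True``),
which is sufficient to reproduce every classification decision discussed.
The exact identity of the resveratrol screen's 17 solvents is likewise
reconstructed: 8 good + 9 bad, excluding 1-butanol (measured afterwards as
an out-of-sample check) and three solvents that sit deep outside the
sphere either way.
"""

from __future__ import annotations

from .classify import SolubilityMeasurement, SolventLabel
from .core import HansenSphere, HspTriple

RESVERATROL = "trans-resveratrol"
HESPERETIN = "hesperetin"

#: Fitted spheres as published (MPa^0.5).
RESVERATROL_SPHERE = HansenSphere(
    HspTriple(12.2, 9.9, 12.7), 10.1, RESVERATROL, "literature"
)
HESPERETIN_SPHERE = HansenSphere(
    HspTriple(12.7, 10.3, 12.5), 10.7, HESPERETIN, "literature"
)

STUDY_SPHERES = {RESVERATROL: RESVERATROL_SPHERE, HESPERETIN: HESPERETIN_SPHERE}

RESVERATROL_GOOD = (
    "ethanol",
    "methanol",
    "1-propanol",
    "acetone",
    "methyl ethyl ketone",
    "methyl isobutyl ketone",
    "ethyl lactate",
    "ethyl acetate",
)
RESVERATROL_BAD = (
    "water",
    "1-octanol",
    "acetonitrile",
    "isopropyl acetate",
    "n-propyl acetate",
    "n-butyl acetate",
    "n-hexane",
    "cyclohexane",
    "p-xylene",
)

HESPERETIN_GOOD = (
    "methanol",
    "acetone",
    "methyl ethyl ketone",
    "methyl isobutyl ketone",
    "ethyl lactate",
    "n-propyl acetate",  # manual override: 18.62 g/L, just below the threshold
)
HESPERETIN_BAD = (
    "water",
    "ethanol",
    "1-propanol",
    "1-octanol",
    "acetonitrile",
    "ethyl acetate",
    "isopropyl acetate",
    "n-butyl acetate",
    "n-hexane",
    "n-decane",
    "cyclohexane",
    "cyclooctane",
    "diisopropyl ether",
    "p-xylene",
)

_UNQUANTIFIABLE = (
    "n-hexane",
    "n-decane",
    "cyclohexane",
    "cyclooctane",
    "p-xylene",
)


def _labels(good, bad, overrides=()) -> tuple[SolventLabel, ...]:
    out = []
    for name in good:
        rationale = "manual_override" if name in overrides else "above_threshold"
        out.append(SolventLabel(name, "good", rationale))
    for name in bad:
        rationale = (
            "insoluble_unquantifiable" if name in _UNQUANTIFIABLE else "below_threshold"
        )
        out.append(SolventLabel(name, "bad", rationale))
    return tuple(out)


def resveratrol_labels() -> tuple[SolventLabel, ...]:
    """The 17-solvent good/bad classification of trans-resveratrol."""
    return _labels(RESVERATROL_GOOD, RESVERATROL_BAD)


def hesperetin_labels() -> tuple[SolventLabel, ...]:
    """The 20-solvent good/bad classification of hesperetin."""
    return _labels(HESPERETIN_GOOD, HESPERETIN_BAD, overrides=("n-propyl acetate",))


def resveratrol_measurements() -> tuple[SolubilityMeasurement, ...]:
    """Quantified resveratrol solubilities quoted in the running text (g/L)."""
    floor = dict(is_lower_bound=True)
    rows = [
        ("acetone", 100.0, floor),
        ("methyl ethyl ketone", 100.0, floor),
        ("ethanol", 100.0, floor),
        ("methanol", 100.0, floor),
        ("1-propanol", 33.38, {}),
        ("methyl isobutyl ketone", 31.82, {}),
        ("ethyl lactate", 27.14, {}),
        ("ethyl acetate", 20.89, {}),
        ("1-butanol", 18.38, {}),
    ]
    return tuple(
        SolubilityMeasurement(RESVERATROL, solvent, value, **extra)
        for solvent, value, extra in rows
    )


def hesperetin_measurements() -> tuple[SolubilityMeasurement, ...]:
    """Quantified hesperetin solubilities quoted in the running text (g/L)."""
    rows = [
        ("acetone", 102.80),
        ("methyl ethyl ketone", 77.66),
        ("n-propyl acetate", 18.62),
        ("1-butanol", 7.71),
    ]
    return tuple(
        SolubilityMeasurement(HESPERETIN, solvent, value) for solvent, value in rows
    )


#: The five binary systems screened, as (solvent 1, solvent 2 = ketone or co-alcohol).
MIXTURE_SYSTEMS = (
    ("methanol", "methyl ethyl ketone"),
    ("ethanol", "methyl ethyl ketone"),
    ("methanol", "methyl isobutyl ketone"),
    ("ethanol", "methyl isobutyl ketone"),
    ("methanol", "ethanol"),
)
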