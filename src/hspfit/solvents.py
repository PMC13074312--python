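"""Bundled literature Hansen parameters for common solvents, plus CSV I/O.

Solvent HSPs are treated as frozen physical constants (like atomic masses):
the packaged table transcribes 25 degC handbook values and records a source
tag per row.  User-supplied tables use the same CSV dialect
(``name,delta_d,delta_p,delta_h[,synonyms,source]``, comma-separated, UTF-8,
decimal point).
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from .core import HansenError, HspTriple

BUILTIN_TAG = "study"
_BUILTIN_VERSION = "study-1"


class SolventLibraryError(HansenError):
    """Malformed, empty or ambiguous solvent table."""


class UnknownSolventError(KeyError):
    """Requested solvent is not in the library; message lists near matches."""


def canonical_name(name: str) -> str:
    """Lowercase, trim, and collapse internal whitespace."""
    return re.sub(r"\s+", " ", str(name).strip().lower())


@dataclass(frozen=True)
class SolventRecord:
    """One solvent: canonical name, synonyms, Hansen triple, source tag."""

    name: str
    hsp: HspTriple
    synonyms: tuple[str, ...] = ()
    source: str = ""


@dataclass(frozen=True)
class SolventLibrary:
    """Validated collection of solvent records with unambiguous lookup."""

    records: tuple[SolventRecord, ...]
    version: str = "user"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, SolventRecord] = {}
        for rec in self.records:
            for key in (rec.name, *rec.synonyms):
                ck = canonical_name(key)
                if not ck:
                    continue
                if ck in index and index[ck] is not rec:
                    raise SolventLibraryError(
                        f"duplicate or ambiguous solvent name {key!r}"
                    )
                index[ck] = rec
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return canonical_name(name) in self._index

    def names(self) -> list[str]:
        return [rec.name for rec in self.records]

    def lookup(self, name: str) -> SolventRecord:
        return lookup(self, name)


def lookup(lib: SolventLibrary, name: str) -> SolventRecord:
    """Resolve a solvent by canonical name or synonym (case-insensitive).

    Raises :class:`UnknownSolventError` naming the nearest matches when the
    name cannot be resolved.
    """
    key = canonical_name(name)
    rec = lib._index.get(key)
    if rec is None:
        near = difflib.get_close_matches(key, lib._index.keys(), n=3, cutoff=0.5)
        hint = f"; nearest matches: {', '.join(near)}" if near else ""
        raise UnknownSolventError(f"unknown solvent {name!r}{hint}")
    return rec


def load_library(source: Union[str, Path] = BUILTIN_TAG) -> SolventLibrary:
    """Load a solvent library from a CSV path or the builtin ``"study"`` tag.

    The builtin table covers the 21 monosolvents of the study (water, four
    alcohols, three ketones, acetonitrile, five esters, two alkanes, two
    cycloalkanes, diisopropyl ether, p-xylene, plus 1-butanol).
    """
    if isinstance(source, str) and source == BUILTIN_TAG:
        with resources.files("hspfit.data").joinpath("solvents.csv").open("rb") as fh:
            frame = pd.read_csv(fh)
        version = _BUILTIN_VERSION
    else:
        path = Path(source)
        if not path.exists():
            raise SolventLibraryError(f"solvent table not found: {path}")
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise SolventLibraryError(f"empty solvent table: {path}") from exc
        version = path.name
    return library_from_frame(frame, version=version)


def library_from_frame(frame: pd.DataFrame, version: str = "user") -> SolventLibrary:
    required = {"name", "delta_d", "delta_p", "delta_h"}
    missing = required - set(frame.columns)
    if missing:
        raise SolventLibraryError(f"missing columns: {sorted(missing)}")
    if len(frame) == 0:
        raise SolventLibraryError("solvent table has no rows")

    records: list[SolventRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        name = canonical_name(row["name"])
        if not name:
            raise SolventLibraryError("blank solvent name")
        if name in seen:
            raise SolventLibraryError(f"duplicate solvent name {row['name']!r}")
        seen.add(name)
        try:
            hsp = HspTriple(
                float(row["delta_d"]), float(row["delta_p"]), float(row["delta_h"])
            )
        except (TypeError, ValueError, HansenError) as exc:
            raise SolventLibraryError(f"invalid HSPs for {name!r}: {exc}") from exc
        synonyms: tuple[str, ...] = ()
        if "synonyms" in frame.columns and pd.notna(row.get("synonyms")) and str(row["synonyms"]).strip():
            synonyms = tuple(
                s.strip() for s in str(row["synonyms"]).split(";") if s.strip()
            )
        src = ""
        if "source" in frame.columns and pd.notna(row.get("source")):
            src = str(row["source"])
        records.append(SolventRecord(name, hsp, synonyms, src))
    return SolventLibrary(tuple(records), version=version)


def write_library(lib: SolventLibrary, path: Union[str, Path]) -> None:
    """Write a library back to CSV (round-trips with :func:`load_library`)."""
    rows = [
        {
            "name": rec.name,
            "delta_d": rec.hsp.delta_d,
            "delta_p": rec.hsp.delta_p,
            "delta_h": rec.hsp.delta_h,
            "synonyms": ";".join(rec.synonyms),
            "source": rec.source,
        }
        for rec in lib.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
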