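"""ADME screening of herbal compound libraries.

A multi-herb formula such as Huanglian Jiedu Decoction contains hundreds of
constituents, most of which never reach systemic circulation or are too
chemically unlike approved drugs to act as one.  This module screens a
compound library down to its *active ingredients* using two standard ADME
parameters:

* **oral bioavailability (OB, %F)** — the unchanged fraction of an orally
  administered dose that reaches systemic circulation, expressed in percent;
* **drug-likeness (DL)** — the Tanimoto similarity between a compound's
  molecular-descriptor vector and the descriptor vector of an average
  approved drug, a unitless index in [0, 1].

The conventional retention rule, applied inclusively, keeps compounds with
OB >= 30% and DL >= 0.18.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatchError,
    EmptyInputError,
    ParseError,
    UndefinedInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "ScreenCriteria",
    "tanimoto_dl",
    "screen_compounds",
    "attach_drug_likeness",
    "read_compound_table",
    "write_compound_table",
]


@dataclass(frozen=True)
class Compound:
    """One herbal ingredient with its ADME screening parameters.

    ``descriptors`` optionally holds the molecular-descriptor vector from
    which a DL index can be computed against a reference drug-average vector.
    """

    name: str
    herb: str
    ob: float
    dl: float | None = None
    descriptors: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValueError("compound name must be nonempty")
        if not np.isfinite(self.ob) or self.ob < 0:
            raise ValueError(f"{self.name}: OB must be finite and >= 0, got {self.ob}")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"{self.name}: DL must lie in [0, 1], got {self.dl}")
        if self.descriptors is not None:
            arr = np.asarray(self.descriptors, dtype=float)
            if arr.size == 0 or not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.name}: descriptors must be nonempty and finite")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical (name, herb) identity: trimmed and case-folded."""
        return (self.name.strip().casefold(), self.herb.strip().casefold())


@dataclass(frozen=True)
class ScreenCriteria:
    """Inclusive OB/DL retention thresholds (percent and unitless)."""

    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self):
        if not (np.isfinite(self.ob_min) and np.isfinite(self.dl_min)):
            raise ValueError("screen thresholds must be finite")
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValueError("screen thresholds must be >= 0")


def tanimoto_dl(a: Sequence[float], b: Sequence[float]) -> float:
    """Tanimoto similarity between two molecular-descriptor vectors.

    Computes ``(a . b) / (|a|^2 + |b|^2 - a . b)``.  For vectors with
    nonnegative entries the value lies in [0, 1], equals 1 iff the vectors
    are identical (and nonzero), and is symmetric in its arguments.
    Used to score a compound's drug-likeness against the descriptor average
    of approved drugs.

    Raises
    ------
    DimensionMismatchError
        If the vectors differ in length.
    UndefinedInputError
        If both vectors are zero (the index is undefined).
    """
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.shape != bv.shape:
        raise DimensionMismatchError(
            f"descriptor lengths differ: {av.size} vs {bv.size}"
        )
    if av.size == 0:
        raise UndefinedInputError("empty descriptor vectors")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise ValueError("descriptor vectors must be finite")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        # |a-b|^2 + a.b = 0 with nonnegative entries only when both are zero
        raise UndefinedInputError("Tanimoto index undefined for two zero vectors")
    return dot / denom


def screen_compounds(
    library: Sequence[Compound], criteria: ScreenCriteria = ScreenCriteria()
) -> tuple[list[Compound], list[Compound]]:
    """Partition a library into retained active ingredients and discards.

    A compound is retained when ``ob >= ob_min`` AND ``dl >= dl_min``, both
    inclusive.  Input order is preserved within each partition.  Compounds
    with no DL value are discarded (they cannot satisfy the DL criterion).
    """
    if len(library) == 0:
        raise EmptyInputError("cannot screen an empty compound library")
    retained: list[Compound] = []
    discarded: list[Compound] = []
    for c in library:
        if c.dl is not None and c.ob >= criteria.ob_min and c.dl >= criteria.dl_min:
            retained.append(c)
        else:
            discarded.append(c)
    logger.info(
        "screen: %d compounds in, %d retained, %d discarded (ob>=%g, dl>=%g)",
        len(library), len(retained), len(discarded), criteria.ob_min, criteria.dl_min,
    )
    return retained, discarded


def attach_drug_likeness(
    library: Sequence[Compound],
    reference: Sequence[float],
    atol: float = 1e-6,
) -> list[Compound]:
    """Fill in DL from descriptors where absent, against a reference vector.

    ``reference`` is the descriptor vector of an average approved drug.  A
    supplied DL always wins; if it disagrees with the descriptor-derived
    value by more than ``atol`` a warning is logged.  Compounds without
    descriptors pass through unchanged.
    """
    out: list[Compound] = []
    for c in library:
        if c.descriptors is None:
            out.append(c)
            continue
        computed = tanimoto_dl(c.descriptors, reference)
        if c.dl is None:
            out.append(replace(c, dl=computed))
        else:
            if abs(c.dl - computed) > atol:
                logger.warning(
                    "%s (%s): supplied DL %.6f disagrees with descriptor-derived "
                    "%.6f; keeping supplied value", c.name, c.herb, c.dl, computed,
                )
            out.append(c)
    return out


_REQUIRED_COLUMNS = ("herb", "name", "ob", "dl")


def read_compound_table(path: str | Path) -> list[Compound]:
    """Read a compound library from a TSV with columns herb, name, ob, dl.

    An optional ``descriptors`` column holds semicolon-joined floats.
    Duplicate (name, herb) rows after canonicalization are rejected; parse
    failures report the offending 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}", line=1)

    compounds: list[Compound] = []
    seen: dict[tuple[str, str], int] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            ob = float(row["ob"])
        except ValueError:
            raise ParseError(f"non-numeric OB value {row['ob']!r}", line=line) from None
        dl_raw = row["dl"].strip()
        try:
            dl = float(dl_raw) if dl_raw else None
        except ValueError:
            raise ParseError(f"non-numeric DL value {dl_raw!r}", line=line) from None
        descriptors = None
        if "descriptors" in df.columns and row["descriptors"].strip():
            try:
                descriptors = tuple(
                    float(x) for x in row["descriptors"].split(";") if x.strip()
                )
            except ValueError:
                raise ParseError(
                    f"malformed descriptor list {row['descriptors']!r}", line=line
                ) from None
        try:
            c = Compound(name=row["name"], herb=row["herb"], ob=ob, dl=dl,
                         descriptors=descriptors)
        except ValueError as exc:
            raise ParseError(str(exc), line=line) from None
        if c.key in seen:
            raise ParseError(
                f"duplicate compound {row['name']!r} under herb {row['herb']!r} "
                f"(first seen at line {seen[c.key]})", line=line,
            )
        seen[c.key] = line
        compounds.append(c)
    return compounds


def write_compound_table(compounds: Sequence[Compound], path: str | Path) -> None:
    """Write a compound library as TSV; inverse of :func:`read_compound_table`."""
    rows = []
    for c in compounds:
        rows.append({
            "herb": c.herb,
            "name": c.name,
            "ob": c.ob,
            "dl": "" if c.dl is None else c.dl,
            "descriptors": "" if c.descriptors is None
            else ";".join(repr(x) for x in c.descriptors),
        })
    df = pd.DataFrame(rows, columns=["herb", "name", "ob", "dl", "descriptors"])
    if all(not r["descriptors"] for r in rows):
        df = df.drop(columns=["descriptors"])
    df.to_csv(path, sep="\t", index=False)
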