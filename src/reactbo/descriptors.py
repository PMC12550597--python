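"""Catalyst descriptor tables.

A catalyst is a categorical choice carrying the physicochemical descriptors
used throughout the package: Mayr's nucleophilicity parameter *N* (the
coordinate used by the chemistry-based encoding), the Mayr sensitivity *s*,
the molar mass (for process-mass-intensity accounting) and a cost per gram
(for the cost objective).  Tables are plain CSV files with one catalyst per
row.

Nucleophilicities for an untested catalyst can be back-estimated from
observed yields of a small calibration set via ordinary least squares on
the (yield, N) pairs, exploiting the near-linear yield–N relationship of
nucleophile-catalysed acyl transfer at fixed conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Catalyst",
    "CatalystSet",
    "load_catalyst_table",
    "write_catalyst_table",
    "estimate_missing_nucleophilicity",
    "NucleophilicityNotIdentifiable",
]

#: sources a nucleophilicity value may come from
N_SOURCES = ("database", "regression_estimate", "fixture")

#: slope below which yield carries no usable information about N (per N unit)
SLOPE_TOL = 1e-6

REQUIRED_COLUMNS = ("name", "nucleophilicity", "molar_mass", "cost_per_g")


class NucleophilicityNotIdentifiable(ValueError):
    """Raised when observed yields do not constrain the nucleophilicity."""


@dataclass(frozen=True)
class Catalyst:
    """One nucleophilic catalyst with its descriptor values.

    Parameters
    ----------
    name
        Short unique identifier.
    nucleophilicity
        Mayr nucleophilicity parameter N (dimensionless).
    sensitivity
        Mayr sensitivity parameter s (dimensionless); defaults to 1.0 when
        a table does not provide it.
    molar_mass
        g/mol, used for mass-based objectives.
    cost_per_g
        Abstract currency units per gram.
    n_source
        Provenance of the N value: ``database``, ``regression_estimate``
        or ``fixture``.
    """

    name: str
    nucleophilicity: float
    molar_mass: float
    cost_per_g: float
    sensitivity: float = 1.0
    n_source: str = "database"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("catalyst name must be non-empty")
        if not math.isfinite(self.nucleophilicity):
            raise ValueError(f"nucleophilicity of {self.name!r} must be finite")
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass of {self.name!r} must be > 0")
        if self.cost_per_g < 0:
            raise ValueError(f"cost_per_g of {self.name!r} must be >= 0")
        if self.n_source not in N_SOURCES:
            raise ValueError(
                f"n_source of {self.name!r} must be one of {N_SOURCES}, got {self.n_source!r}"
            )


@dataclass(frozen=True)
class CatalystSet:
    """Ordered collection of distinct catalysts."""

    catalysts: tuple[Catalyst, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.catalysts]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate catalyst names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.catalysts)

    def __iter__(self):
        return iter(self.catalysts)

    def __getitem__(self, i: int) -> Catalyst:
        return self.catalysts[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.catalysts)

    @property
    def nucleophilicities(self) -> np.ndarray:
        return np.array([c.nucleophilicity for c in self.catalysts], dtype=float)

    def by_name(self, name: str) -> Catalyst:
        for c in self.catalysts:
            if c.name == name:
                return c
        raise KeyError(f"unknown catalyst {name!r}; known: {list(self.names)}")

    def index(self, name: str) -> int:
        for i, c in enumerate(self.catalysts):
            if c.name == name:
                return i
        raise KeyError(f"unknown catalyst {name!r}; known: {list(self.names)}")

    def subset(self, names: Sequence[str]) -> "CatalystSet":
        return CatalystSet(
            tuple(self.by_name(n) for n in names),
            provenance=f"{self.provenance} (subset)",
        )


def load_catalyst_table(path: str | Path) -> CatalystSet:
    """Read a catalyst descriptor table from CSV.

    Required columns: ``name, nucleophilicity, molar_mass, cost_per_g``.
    Optional: ``sensitivity`` (default 1.0) and ``n_source`` (default
    ``database``).  File order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"name": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"catalyst table {path} is missing required column {col!r}")
    if "sensitivity" not in df.columns:
        df["sensitivity"] = 1.0
    df["sensitivity"] = df["sensitivity"].fillna(1.0)
    if "n_source" not in df.columns:
        df["n_source"] = "database"
    catalysts = []
    for i, row in df.iterrows():
        for col in ("nucleophilicity", "molar_mass", "cost_per_g", "sensitivity"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric {col} {row[col]!r} in row {i} ({row['name']!r}) of {path}"
                ) from None
        catalysts.append(
            Catalyst(
                name=str(row["name"]),
                nucleophilicity=float(row["nucleophilicity"]),
                sensitivity=float(row["sensitivity"]),
                molar_mass=float(row["molar_mass"]),
                cost_per_g=float(row["cost_per_g"]),
                n_source=str(row["n_source"]),
            )
        )
    return CatalystSet(tuple(catalysts), provenance=str(path))


def write_catalyst_table(catalyst_set: CatalystSet, path: str | Path) -> None:
    """Write a catalyst set back to CSV (inverse of :func:`load_catalyst_table`)."""
    df = pd.DataFrame(
        {
            "name": [c.name for c in catalyst_set],
            "nucleophilicity": [c.nucleophilicity for c in catalyst_set],
            "sensitivity": [c.sensitivity for c in catalyst_set],
            "molar_mass": [c.molar_mass for c in catalyst_set],
            "cost_per_g": [c.cost_per_g for c in catalyst_set],
            "n_source": [c.n_source for c in catalyst_set],
        }
    )
    df.to_csv(path, index=False)


def estimate_missing_nucleophilicity(
    known: Iterable[tuple[Catalyst, float]],
    unknown_yield: float,
) -> float:
    """Estimate an unknown catalyst's N from its observed yield.

    Fits yield = a + b*N by unweighted ordinary least squares on the known
    (catalyst, yield) pairs, then inverts: ``N_hat = (unknown_yield - a)/b``.

    Raises
    ------
    NucleophilicityNotIdentifiable
        If the fitted slope magnitude is below ``SLOPE_TOL`` (yields flat
        in N) or fewer than two distinct N values are supplied.
    """
    pairs = list(known)
    ns = np.array([c.nucleophilicity for c, _ in pairs], dtype=float)
    ys = np.array([y for _, y in pairs], dtype=float)
    if len(np.unique(ns)) < 2:
        raise NucleophilicityNotIdentifiable(
            "need at least 2 catalysts with distinct nucleophilicities"
        )
    if np.any((ys < 0) | (ys > 1)) or not 0 <= unknown_yield <= 1:
        raise ValueError("yields must be fractions in [0, 1]")
    A = np.column_stack([np.ones_like(ns), ns])
    (a, b), *_ = np.linalg.lstsq(A, ys, rcond=None)
    if abs(b) < SLOPE_TOL:
        raise NucleophilicityNotIdentifiable(
            "nucleophilicity not identifiable from yields (regression slope ~ 0)"
        )
    return float((unknown_yield - a) / b)


def with_estimated_nucleophilicity(
    catalyst: Catalyst,
    known: Iterable[tuple[Catalyst, float]],
    observed_yield: float,
) -> Catalyst:
    """Return a copy of ``catalyst`` with N estimated by regression.

    The returned catalyst carries ``n_source='regression_estimate'``.
    """
    n_hat = estimate_missing_nucleophilicity(known, observed_yield)
    return replace(catalyst, nucleophilicity=n_hat, n_source="regression_estimate")
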