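"""Species x trait tables for the leaf economics spectrum.

Nine traits drive the analysis: leaf life span (LLS, months), leaf mass
per area (LMA, g m-2), construction cost (CC, g glucose g-1), leaf
water-to-dry-mass ratio (Wm), nitrogen and phosphorus per dry mass
(Nmass, Pmass, mg g-1), mass-based photosynthesis and dark respiration
(Amass, Rmass, nmol g-1 s-1), and photosynthetic nitrogen-use efficiency
(PNUE, umol CO2 mol-1 N s-1).  Species carry a leaf habit
(evergreen/deciduous) and an elevation label (low/middle/high).

All traits must be strictly positive so that the standard log10
transform is defined; a ``transformed`` flag guards against applying it
twice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_COLUMNS: tuple[str, ...] = (
    "LLS", "LMA", "CC", "Wm", "Nmass", "Pmass", "Amass", "Rmass", "PNUE",
)
HABITS: tuple[str, ...] = ("evergreen", "deciduous")
ELEVATIONS: tuple[str, ...] = ("low", "middle", "high")

#: molar mass of nitrogen (g/mol), used in the PNUE unit conversion
N_MOLAR_MASS = 14.0067


class TraitTableError(ValueError):
    """Invalid trait table (missing column, non-positive value, duplicate
    species, unknown habit/elevation label)."""


@dataclass
class TraitTable:
    """Validated species x trait table.

    ``data`` is indexed by species and holds ``habit``, ``elevation``,
    the nine trait columns and any extra columns (preserved but never
    entering computations).  ``transformed`` records whether the trait
    columns are on the log10 scale.
    """

    data: pd.DataFrame
    transformed: bool = False

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def traits(self) -> pd.DataFrame:
        return self.data[list(TRAIT_COLUMNS)]

    def habit(self) -> pd.Series:
        return self.data["habit"]

    def elevation(self) -> pd.Series:
        return self.data["elevation"]


def _validate(df: pd.DataFrame, *, transformed: bool) -> None:
    required = ["habit", "elevation", *TRAIT_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise TraitTableError(f"missing required column {col!r}")
    dupes = df.index[df.index.duplicated()].tolist()
    if dupes:
        raise TraitTableError(f"duplicate species: {sorted(set(dupes))}")
    bad_habit = df.loc[~df["habit"].isin(HABITS), "habit"]
    if len(bad_habit):
        sp = bad_habit.index[0]
        raise TraitTableError(
            f"unknown habit {bad_habit.iloc[0]!r} for species {sp!r} "
            f"(allowed: {HABITS})"
        )
    bad_elev = df.loc[~df["elevation"].isin(ELEVATIONS), "elevation"]
    if len(bad_elev):
        sp = bad_elev.index[0]
        raise TraitTableError(
            f"unknown elevation {bad_elev.iloc[0]!r} for species {sp!r} "
            f"(allowed: {ELEVATIONS})"
        )
    if not transformed:
        for col in TRAIT_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                sp = vals.index[vals.isna()][0]
                raise TraitTableError(
                    f"non-numeric value in column {col!r}, species {sp!r}"
                )
            nonpos = vals <= 0
            if nonpos.any():
                sp = vals.index[nonpos][0]
                raise TraitTableError(
                    f"non-positive value {vals[sp]} in column {col!r}, "
                    f"species {sp!r} (log10 would be undefined)"
                )


def make_trait_table(df: pd.DataFrame, *, transformed: bool = False) -> TraitTable:
    """Build a validated :class:`TraitTable` from a DataFrame indexed by
    species (or with a ``species`` column)."""
    df = df.copy()
    if "species" in df.columns:
        df = df.set_index("species")
    df.index = df.index.astype(str)
    df.index.name = "species"
    for col in TRAIT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    _validate(df, transformed=transformed)
    return TraitTable(data=df, transformed=transformed)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_trait_table(path, *, sep: str | None = None) -> TraitTable:
    """Read a delimited trait table (CSV/TSV inferred from content).

    Required columns: species, habit, elevation and the nine traits;
    unknown columns are preserved as opaque metadata.  Errors name the
    offending row and column.
    """
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "species" not in df.columns:
        raise TraitTableError("missing required column 'species'")
    return make_trait_table(df)


def write_trait_table(table: TraitTable, path, *, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=True)


def construction_cost(cmass) -> np.ndarray | float:
    """Leaf construction cost (g glucose g-1) from carbon content
    (mg g-1): CC = (5.39 * C - 1191) / 1000.

    Carbon contents at or below the zero crossing (1191/5.39 ~ 220.96
    mg g-1) give a non-positive cost, which is biologically invalid for
    leaf tissue and rejected.
    """
    c = np.asarray(cmass, dtype=float)
    if np.any(c <= 1191.0 / 5.39):
        raise ValueError(
            "carbon content at or below 1191/5.39 mg g-1 gives a "
            "non-positive construction cost"
        )
    cc = (5.39 * c - 1191.0) / 1000.0
    return float(cc) if np.isscalar(cmass) else cc


def pnue(amass, nmass) -> np.ndarray | float:
    """Photosynthetic nitrogen-use efficiency (umol CO2 mol-1 N s-1).

    Mass-based A/N with unit conversion: Amass in nmol g-1 s-1, Nmass in
    mg g-1; multiplying by the molar mass of N (14.0067 g/mol) converts
    nmol CO2 per mg N to umol CO2 per mol N.
    """
    a = np.asarray(amass, dtype=float)
    n = np.asarray(nmass, dtype=float)
    if np.any(n <= 0):
        raise ValueError("Nmass must be positive")
    out = a * N_MOLAR_MASS / n
    return float(out) if np.isscalar(amass) and np.isscalar(nmass) else out


def log10_table(table: TraitTable) -> TraitTable:
    """Return a copy with every trait column log10-transformed.

    A second application is refused (the ``transformed`` flag guards
    against accidental double transformation).
    """
    if table.transformed:
        raise TraitTableError("table is already log10-transformed")
    df = table.data.copy()
    for col in TRAIT_COLUMNS:
        vals = df[col].astype(float)
        nonpos = vals <= 0
        if nonpos.any():
            sp = vals.index[nonpos][0]
            raise TraitTableError(
                f"non-positive value {vals[sp]} in column {col!r}, "
                f"species {sp!r}: log10 undefined"
            )
        df[col] = np.log10(vals)
    return TraitTable(data=df, transformed=True)


def complete_cases(table: TraitTable) -> TraitTable:
    """Drop species missing any of the nine traits (listwise deletion),
    logging the count removed."""
    mask = table.traits().notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("complete_cases: dropped %d species with missing traits", dropped)
    return TraitTable(data=table.data.loc[mask].copy(), transformed=table.transformed)


# ---------------------------------------------------------------------------
# Environment table

ENV_COLUMNS: tuple[str, ...] = (
    "elevation", "elevation_m", "replicate",
    "MAT", "soil_total_N", "soil_total_P", "soil_CN", "soil_NP",
)
ENV_VARIABLES: tuple[str, ...] = (
    "MAT", "soil_total_N", "soil_total_P", "soil_CN", "soil_NP",
)


def validate_environment(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-plot environment table (MAT, soil totals and ratios
    with replicate rows per elevation)."""
    for col in ENV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"environment table missing column {col!r}")
    for col in ("soil_CN", "soil_NP"):
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive ratio in column {col!r}")
    counts = df.groupby("elevation").size()
    if (counts < 1).any():
        raise ValueError("each elevation needs at least one replicate")
    return df


def read_environment(path, *, sep: str | None = None) -> pd.DataFrame:
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return validate_environment(df)


def write_environment(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)
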