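"""Measurement tables for limb-bone allometry.

A measurement table holds one row per species: live body mass plus the
maximum length and minimum diaphyseal circumference of the humerus and
femur, with clade and lifestyle labels.  Internal units are grams and
millimetres throughout; user-facing mass output is additionally reported
in kilograms.  Missing measurements are NaN, never zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "VARIABLES",
    "MeasurementTable",
    "SubsetCriteria",
    "BivariateLogSample",
    "read_measurements",
    "write_measurements",
    "derive_variables",
    "subset_table",
    "bivariate_sample",
]

#: canonical column order of a measurement CSV
COLUMNS = [
    "species",
    "class",
    "clade",
    "lifestyle",
    "body_mass_g",
    "humerus_length_mm",
    "humerus_circ_mm",
    "femur_length_mm",
    "femur_circ_mm",
    "source",
]

MEASUREMENT_COLUMNS = [
    "body_mass_g",
    "humerus_length_mm",
    "humerus_circ_mm",
    "femur_length_mm",
    "femur_circ_mm",
]

KNOWN_CLASSES = {"Mammalia", "Reptilia", "Lissamphibia"}

#: short variable labels used across the analysis modules -> data column
VARIABLES = {
    "BM": "body_mass_g",
    "L_H": "humerus_length_mm",
    "C_H": "humerus_circ_mm",
    "L_F": "femur_length_mm",
    "C_F": "femur_circ_mm",
    "C_H+F": "combined_circ_mm",
}


class MeasurementError(ValueError):
    """Raised when a table violates the measurement-data contract."""


@dataclass
class MeasurementTable:
    """Species-level limb measurements backed by a pandas DataFrame.

    Parameters
    ----------
    df
        One row per species with (at least) the canonical columns.
    provenance
        Free-text origin of the data (file path, simulation config, ...).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise MeasurementError(f"missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        sp = self.df["species"]
        if sp.isna().any() or (sp.astype(str).str.strip() == "").any():
            raise MeasurementError("empty species name")
        dup = sp[sp.duplicated()]
        if len(dup):
            raise MeasurementError(f"duplicate species: {sorted(set(dup))}")
        unknown = set(self.df["class"].dropna()) - KNOWN_CLASSES
        if unknown:
            raise MeasurementError(f"unknown class labels: {sorted(unknown)}")
        for col in MEASUREMENT_COLUMNS:
            vals = pd.to_numeric(self.df[col], errors="coerce")
            bad = self.df.loc[vals.notna() & (vals <= 0), "species"]
            if len(bad):
                raise MeasurementError(
                    f"non-positive {col} for species: {list(bad)}"
                )
            if col == "body_mass_g" and vals.isna().any():
                bad = self.df.loc[vals.isna(), "species"]
                raise MeasurementError(f"missing body mass for: {list(bad)}")
            self.df[col] = vals.astype(float)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return list(self.df["species"])

    def class_counts(self) -> dict[str, int]:
        return self.df["class"].value_counts().to_dict()

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(self.df.copy(), self.provenance)


def read_measurements(
    path, dialect: dict[str, str] | None = None, provenance: str | None = None
) -> MeasurementTable:
    """Read a measurement CSV.

    ``dialect`` maps canonical column names to the names used in the file,
    e.g. ``{"body_mass_g": "Mass (kg)"}``.  A source column name ending in
    ``_kg`` or ``(kg)`` is converted to grams; ``_cm``/``(cm)`` to
    millimetres.  Blank cells become missing values.
    """
    raw = pd.read_csv(path)
    dialect = dialect or {}
    out = pd.DataFrame()
    for col in COLUMNS:
        src = dialect.get(col, col)
        if src not in raw.columns:
            if col in ("source", "lifestyle", "clade"):
                out[col] = [""] * len(raw)
                continue
            raise MeasurementError(f"column {src!r} not found in {path}")
        series = raw[src]
        if col in MEASUREMENT_COLUMNS:
            series = pd.to_numeric(series, errors="coerce")
            low = src.lower()
            if col == "body_mass_g" and ("kg" in low.split("_") or "(kg)" in low):
                series = series * 1000.0
            elif col != "body_mass_g" and ("cm" in low.split("_") or "(cm)" in low):
                series = series * 10.0
        out[col] = series
    return MeasurementTable(out, provenance or str(path))


def write_measurements(table: MeasurementTable, path) -> None:
    """Write the canonical columns as CSV (lossless round trip)."""
    table.df[COLUMNS].to_csv(path, index=False)


def derive_variables(table: MeasurementTable) -> MeasurementTable:
    """Add the combined stylopodial circumference and log10 columns.

    ``combined_circ_mm`` is the sum of humeral and femoral circumferences
    and is missing when either component is missing.  ``log_<col>`` columns
    hold log10 of each measurement.  Idempotent; original fields unchanged.
    """
    df = table.df.copy()
    df["combined_circ_mm"] = df["humerus_circ_mm"] + df["femur_circ_mm"]
    for col in MEASUREMENT_COLUMNS + ["combined_circ_mm"]:
        with np.errstate(invalid="ignore"):
            df["log_" + col] = np.log10(df[col])
    return MeasurementTable(df, table.provenance)


@dataclass
class SubsetCriteria:
    """Row filter for :func:`subset_table`.

    Mass thresholds are in grams; ``mass_at_most_g`` keeps rows with
    body mass <= the threshold, ``mass_above_g`` keeps rows strictly
    above it (matching the "<= 168 kg" / "> 100 kg" subset semantics).
    """

    classes: set[str] | None = None
    clades: set[str] | None = None
    mass_at_most_g: float | None = None
    mass_above_g: float | None = None
    exclude_species: set[str] = field(default_factory=set)
    include_lissamphibia: bool = False

    def mask(self, df: pd.DataFrame) -> pd.Series:
        keep = pd.Series(True, index=df.index)
        if not self.include_lissamphibia and (
            self.classes is None or "Lissamphibia" not in self.classes
        ):
            keep &= df["class"] != "Lissamphibia"
        if self.classes is not None:
            keep &= df["class"].isin(self.classes)
        if self.clades is not None:
            keep &= df["clade"].isin(self.clades)
        if self.mass_at_most_g is not None:
            keep &= df["body_mass_g"] <= self.mass_at_most_g
        if self.mass_above_g is not None:
            keep &= df["body_mass_g"] > self.mass_above_g
        if self.exclude_species:
            keep &= ~df["species"].isin(self.exclude_species)
        return keep


def subset_table(table: MeasurementTable, criteria: SubsetCriteria) -> MeasurementTable:
    """Return the rows satisfying every criterion, fields untouched."""
    df = table.df[criteria.mask(table.df)].reset_index(drop=True)
    if len(df) == 0:
        warnings.warn("subset criteria matched no records", stacklevel=2)
    return MeasurementTable(df, table.provenance)


@dataclass
class BivariateLogSample:
    """Aligned log10 (x, y) pairs for one variable-pair analysis."""

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be aligned 1-d arrays")
        if len(self.x) != len(self.species):
            raise ValueError("species labels must align with data")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("sample contains non-finite values")
        if self.n < 3:
            raise ValueError("need at least 3 complete pairs")

    @property
    def n(self) -> int:
        return len(self.x)

    def swapped(self) -> "BivariateLogSample":
        return BivariateLogSample(self.y_name, self.x_name, self.y.copy(), self.x.copy(), list(self.species))


def bivariate_sample(
    table: MeasurementTable, x_var: str, y_var: str
) -> BivariateLogSample:
    """Extract the complete-case log10 sample for a pair of variables.

    Variables are the short labels of :data:`VARIABLES` ("BM", "L_H",
    "C_H", "L_F", "C_F", "C_H+F").  Rows missing either member are dropped
    (no imputation), so sample sizes differ between length- and
    circumference-based analyses.
    """
    for v in (x_var, y_var):
        if v not in VARIABLES:
            raise KeyError(f"unknown variable {v!r}; choose from {sorted(VARIABLES)}")
    df = table.df
    if "combined_circ_mm" not in df.columns:
        df = derive_variables(table).df
    xs = np.log10(df[VARIABLES[x_var]].to_numpy(dtype=float))
    ys = np.log10(df[VARIABLES[y_var]].to_numpy(dtype=float))
    ok = np.isfinite(xs) & np.isfinite(ys)
    return BivariateLogSample(
        x_var, y_var, xs[ok], ys[ok], list(df.loc[ok, "species"])
    )
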