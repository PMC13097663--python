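"""Allometric size correction of linear morphometric traits.

Linear measurements scale with body size; before multivariate comparison
each trait Y is adjusted to a common body size with the allometric
transformation

    Z_i = Y_i * (SVL_bar / SVL_i) ** b,

where SVL is snout-vent length (the size metric), SVL_bar its arithmetic
mean over the analysis subset, and b the OLS slope of log(Y) on log(SVL)
estimated across the same subset (globally for interspecific analyses,
per species for intraspecific ones).  SVL itself is excluded from the
corrected variable set.  Corrected traits are z-score standardized column
by column before entering multivariate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "TRAITS",
    "FACTOR_COLUMNS",
    "TraitTable",
    "AllometricModel",
    "read_trait_table",
    "fit_allometric_slope",
    "size_correct",
    "standardize_matrix",
]

#: the nine linear traits (mm) plus body mass (g); SVL is the size metric
TRAITS = ["ED", "EED", "FTL", "HH", "HL", "HW", "IND", "IOD", "SED", "Weight"]
FACTOR_COLUMNS = ["specimen_id", "species", "region", "island", "sex"]


@dataclass
class TraitTable:
    """Raw trait measurements with specimen factors.

    ``data`` holds one row per specimen with the factor columns, SVL and the
    trait columns; ``incomplete`` flags rows with any missing measurement
    (such rows are excluded from analyses).
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=lambda: list(TRAITS))

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.traits + ["SVL"] if c not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"trait table lacks columns: {missing_cols}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def incomplete(self) -> pd.Series:
        return self.data[self.traits + ["SVL"]].isna().any(axis=1)

    def complete_rows(self) -> "TraitTable":
        return TraitTable(self.data.loc[~self.incomplete].reset_index(drop=True), self.traits)

    def species_counts(self) -> dict[str, int]:
        return self.data["species"].value_counts().to_dict()


@dataclass
class AllometricModel:
    """Fitted log-log allometric slopes per trait plus the reference mean SVL."""

    slopes: dict[str, float]
    mean_svl: float
    scope: str = "global"  # "global" | "per-species"

    def __post_init__(self) -> None:
        if self.mean_svl <= 0:
            raise ValidationError("mean SVL must be positive")
        bad = {t: b for t, b in self.slopes.items() if not np.isfinite(b)}
        if bad:
            raise ValidationError(f"non-finite allometric slopes: {bad}")


def read_trait_table(path: str | Path, traits: list[str] | None = None) -> TraitTable:
    """Read a trait CSV (specimen_id, factors, SVL plus the trait columns)."""
    traits = list(TRAITS) if traits is None else traits
    df = pd.read_csv(path)
    needed = ["specimen_id", "SVL"] + traits
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in traits + ["SVL"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} (file line {row})"
            ) from None
    for col in FACTOR_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(str)
    return TraitTable(df, traits)


def fit_allometric_slope(Y: np.ndarray, SVL: np.ndarray) -> float:
    """OLS slope of log(Y) on log(SVL) (natural logs; slope is base-invariant)."""
    Y = np.asarray(Y, dtype=float)
    SVL = np.asarray(SVL, dtype=float)
    if Y.shape != SVL.shape or Y.ndim != 1:
        raise ValidationError("Y and SVL must be equal-length vectors")
    if Y.size < 3:
        raise ValidationError("need at least 3 observations to fit a slope")
    if (Y <= 0).any() or (SVL <= 0).any():
        raise ValidationError("allometric fit requires strictly positive values")
    x = np.log(SVL)
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in SVL")
    y = np.log(Y)
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def fit_allometric_model(
    table: TraitTable, scope: str = "global"
) -> AllometricModel | dict[str, AllometricModel]:
    """Fit slopes for every trait; per-species scope returns one model per species."""
    tab = table.complete_rows()
    if scope == "global":
        svl = tab.data["SVL"].to_numpy()
        slopes = {t: fit_allometric_slope(tab.data[t].to_numpy(), svl) for t in tab.traits}
        return AllometricModel(slopes, float(svl.mean()), scope="global")
    if scope == "per-species":
        out = {}
        for sp, sub in tab.data.groupby("species"):
            svl = sub["SVL"].to_numpy()
            slopes = {t: fit_allometric_slope(sub[t].to_numpy(), svl) for t in tab.traits}
            out[sp] = AllometricModel(slopes, float(svl.mean()), scope="per-species")
        return out
    raise ValidationError(f"unknown scope {scope!r}")


def size_correct(table: TraitTable, model: AllometricModel) -> TraitTable:
    """Apply Z = Y * (mean_SVL / SVL)^b to every trait column.

    Rows with missing data are dropped first (they cannot be corrected).
    The corrected table keeps the factor columns and SVL (for reference);
    SVL is never part of the corrected response set.
    """
    tab = table.complete_rows()
    missing = [t for t in tab.traits if t not in model.slopes]
    if missing:
        raise ValidationError(f"model lacks slopes for traits: {missing}")
    df = tab.data.copy()
    svl = df["SVL"].to_numpy(dtype=float)
    if (svl <= 0).any():
        raise ValidationError("SVL must be strictly positive")
    ratio = model.mean_svl / svl
    for t in tab.traits:
        df[t] = df[t].to_numpy(dtype=float) * ratio ** model.slopes[t]
    return TraitTable(df, tab.traits)


def standardize_matrix(table: TraitTable | pd.DataFrame) -> np.ndarray:
    """Column-wise z-scores (ddof=1) of the trait columns, as an n x p matrix."""
    if isinstance(table, TraitTable):
        df = table.complete_rows().data[table.traits]
    else:
        df = table
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows to standardize")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [df.columns[i] for i in zero]
        raise ValidationError(f"zero-variance trait columns: {names}")
    return (X - X.mean(axis=0)) / sd
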