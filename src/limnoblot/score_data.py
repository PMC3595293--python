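"""Ordinal RLBH score matrices and habitat environmental tables.

The screening design assays every habitat with every probe, so the score
matrix has no missing cells: each cell is an ordinal signal-strength score
in {0 (no signal), 1 (weak), 2 (normal), 3 (strong)}.  Environmental
covariates other than pH may be missing and are propagated as NaN — they
are flagged, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "BinaryMatrix",
    "HabitatTable",
    "binarize",
    "align",
    "OPTIONAL_COVARIATES",
]

logger = logging.getLogger(__name__)

OPTIONAL_COVARIATES = (
    "conductivity",
    "oxygen",
    "absorbance",
    "altitude",
    "temperature",
    "latitude",
    "longitude",
)


def _check_unique(values: Iterable[str], what: str) -> None:
    values = list(values)
    if len(set(values)) != len(values):
        dupes = sorted({v for v in values if list(values).count(v) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass(frozen=True)
class ScoreMatrix:
    """Habitats × probes table of ordinal detection scores in {0,1,2,3}."""

    df: pd.DataFrame  # index: habitat_id, columns: probe names, int values

    def __post_init__(self) -> None:
        df = self.df
        _check_unique(df.index, "habitat ids")
        _check_unique(df.columns, "probe names")
        if df.isna().any().any():
            raise ValueError("score matrix has missing cells")
        arr = df.to_numpy()
        bad = ~np.isin(arr, (0, 1, 2, 3))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"score out of range at habitat {df.index[i]!r}, probe "
                f"{df.columns[j]!r}: {arr[i, j]!r} (allowed: 0,1,2,3)"
            )
        object.__setattr__(
            self, "df", df.astype(np.int64).rename_axis(index="habitat_id", columns=None)
        )

    @property
    def habitat_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def probe_names(self) -> list[str]:
        return list(self.df.columns)

    @classmethod
    def read(cls, path: str | Path, dialect: str = "tsv") -> "ScoreMatrix":
        sep = {"tsv": "\t", "csv": ","}[dialect]
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def write(self, path: str | Path, dialect: str = "tsv") -> None:
        sep = {"tsv": "\t", "csv": ","}[dialect]
        self.df.rename_axis("habitat_id").to_csv(path, sep=sep)


@dataclass(frozen=True)
class BinaryMatrix:
    """Habitats × probes detection (1) / no-detection (0) matrix."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        _check_unique(df.index, "habitat ids")
        _check_unique(df.columns, "probe names")
        if df.isna().any().any():
            raise ValueError("binary matrix has missing cells")
        if not np.isin(df.to_numpy(), (0, 1)).all():
            raise ValueError("binary matrix values must be 0 or 1")
        object.__setattr__(
            self, "df", df.astype(np.int64).rename_axis(index="habitat_id", columns=None)
        )

    @property
    def habitat_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def probe_names(self) -> list[str]:
        return list(self.df.columns)

    def write(self, path: str | Path, dialect: str = "tsv") -> None:
        sep = {"tsv": "\t", "csv": ","}[dialect]
        self.df.rename_axis("habitat_id").to_csv(path, sep=sep)


def binarize(m: ScoreMatrix | BinaryMatrix) -> BinaryMatrix:
    """Detection = any score above 0 (weak/normal/strong all count).

    Idempotent on an already-binary matrix.
    """
    return BinaryMatrix((m.df > 0).astype(np.int64))


@dataclass(frozen=True)
class HabitatTable:
    """Per-habitat environment: pH (mandatory) plus optional covariates.

    Columns beyond pH — conductivity (µS/cm), oxygen (mg/L), absorbance
    (DOC proxy), altitude (m), temperature (°C), latitude/longitude
    (decimal degrees) — may be missing per habitat (NaN); downstream
    stages must skip, not impute, them.
    """

    df: pd.DataFrame  # index: habitat_id

    def __post_init__(self) -> None:
        df = self.df
        _check_unique(df.index, "habitat ids")
        if "pH" not in df.columns:
            raise ValueError("habitat table: mandatory column 'pH' is missing")
        ph = df["pH"]
        if ph.isna().any():
            missing = list(df.index[ph.isna()])
            raise ValueError(f"habitat table: pH missing for habitats {missing}")
        if ((ph < 0) | (ph > 14)).any():
            bad = list(df.index[(ph < 0) | (ph > 14)])
            raise ValueError(f"habitat table: pH outside [0,14] for habitats {bad}")
        for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
            if col in df.columns:
                vals = df[col].dropna()
                if ((vals < lo) | (vals > hi)).any():
                    raise ValueError(f"habitat table: {col} outside [{lo},{hi}]")
        for col in ("conductivity", "oxygen", "absorbance"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise ValueError(f"habitat table: negative {col}")
        object.__setattr__(self, "df", df.rename_axis(index="habitat_id", columns=None))

    @property
    def habitat_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def ph(self) -> pd.Series:
        return self.df["pH"]

    def missing_flags(self) -> pd.DataFrame:
        """True where an optional covariate is unavailable for a habitat."""
        cols = [c for c in OPTIONAL_COVARIATES if c in self.df.columns]
        return self.df[cols].isna()

    @classmethod
    def read(cls, path: str | Path, dialect: str = "tsv") -> "HabitatTable":
        sep = {"tsv": "\t", "csv": ","}[dialect]
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"habitat table {path}: non-numeric value in column {col!r}: {exc}")
        return cls(df)

    def write(self, path: str | Path, dialect: str = "tsv") -> None:
        sep = {"tsv": "\t", "csv": ","}[dialect]
        self.df.rename_axis("habitat_id").to_csv(path, sep=sep)


def align(
    m: ScoreMatrix | BinaryMatrix, habitats: HabitatTable
) -> tuple[ScoreMatrix | BinaryMatrix, HabitatTable]:
    """Restrict both tables to their common habitats, in matrix row order.

    Dropped-row counts are logged; an empty intersection is an error.
    Alignment is invariant to the input row order of either table.
    """
    common = [h for h in m.habitat_ids if h in set(habitats.habitat_ids)]
    if not common:
        raise ValueError("align: no habitats in common between matrix and habitat table")
    dropped_m = len(m.habitat_ids) - len(common)
    dropped_h = len(habitats.habitat_ids) - len(common)
    if dropped_m or dropped_h:
        logger.info("align: dropped %d matrix rows and %d habitat rows", dropped_m, dropped_h)
    aligned_m = type(m)(m.df.loc[common])
    aligned_h = HabitatTable(habitats.df.loc[common])
    return aligned_m, aligned_h
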