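"""Fermentation-record tables: I/O, min-max normalization, yield levels, splits.

A fermentation record holds nine culture-condition variables (glucose, yeast
extract, KH2PO4, MgSO4, liquid volume, pH, temperature, rotational speed,
inoculation amount) and, optionally, the observed Welan gum production in g/L.
Tables are plain CSV with a header row; in memory they are pandas DataFrames
with the canonical column names in :data:`CONDITION_COLUMNS`.

Normalization is the affine min-max map

    y = (y_max - y_min) * (x - x_min) / (x_max - x_min) + y_min

applied per column, with the normalized range defaulting to [0, 1].  Records
are stratified into low / mid / high yield levels (boundaries 5 and 20 g/L)
before the 70/30 train/test split so that each level contributes
proportionally to both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CONDITION_COLUMNS",
    "PRODUCTION_COLUMN",
    "ALL_COLUMNS",
    "FermentationRecord",
    "ScalingParams",
    "YieldLevel",
    "SplitResult",
    "normalize_column",
    "denormalize_column",
    "fit_scaling",
    "assign_level",
    "stratified_split",
    "read_table",
    "write_table",
]

#: Canonical condition-variable columns, in gene order x1..x9.
CONDITION_COLUMNS: tuple[str, ...] = (
    "glucose",              # g/L
    "yeast",                # g/L
    "kh2po4",               # g/L
    "mgso4",                # g/L
    "liquid_volume",        # mL
    "ph",                   # dimensionless
    "temperature",          # deg C
    "rotational_speed",     # rpm
    "inoculation_amount",   # % (as printed)
)

PRODUCTION_COLUMN = "production"  # g/L

ALL_COLUMNS: tuple[str, ...] = CONDITION_COLUMNS + (PRODUCTION_COLUMN,)

#: Yield-level boundaries in g/L: [0, 5) low, [5, 20] mid, (20, inf) high.
LOW_MID_BOUNDARY = 5.0
MID_HIGH_BOUNDARY = 20.0


@dataclass(frozen=True)
class FermentationRecord:
    """One fermentation run: nine condition values plus optional yield."""

    glucose: float
    yeast: float
    kh2po4: float
    mgso4: float
    liquid_volume: float
    ph: float
    temperature: float
    rotational_speed: float
    inoculation_amount: float
    production: float | None = None

    def __post_init__(self) -> None:
        for name in CONDITION_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for condition {name!r}: {v}")
        if self.production is not None and self.production < 0:
            raise ValueError(f"production must be >= 0, got {self.production}")

    @property
    def conditions(self) -> np.ndarray:
        """Condition vector (x1..x9) as a float array."""
        return np.array([getattr(self, c) for c in CONDITION_COLUMNS], dtype=float)

    @classmethod
    def from_mapping(cls, row: Mapping[str, float]) -> "FermentationRecord":
        kwargs = {c: float(row[c]) for c in CONDITION_COLUMNS}
        if PRODUCTION_COLUMN in row and row[PRODUCTION_COLUMN] is not None:
            p = row[PRODUCTION_COLUMN]
            kwargs[PRODUCTION_COLUMN] = None if p is None or pd.isna(p) else float(p)
        return cls(**kwargs)


class YieldLevel(str, Enum):
    """Production stratum; levels partition [0, inf)."""

    LOW = "low"    # [0, 5) g/L
    MID = "mid"    # [5, 20] g/L
    HIGH = "high"  # (20, inf) g/L


def assign_level(production: float) -> YieldLevel:
    """Map a production value (g/L) to its yield level.

    Boundary convention: 5 g/L belongs to mid, 20 g/L belongs to mid
    ("more than 20" is read strictly).
    """
    if production < 0 or not np.isfinite(production):
        raise ValueError(f"production must be a finite non-negative value, got {production}")
    if production < LOW_MID_BOUNDARY:
        return YieldLevel.LOW
    if production <= MID_HIGH_BOUNDARY:
        return YieldLevel.MID
    return YieldLevel.HIGH


@dataclass
class ScalingParams:
    """Per-column min-max scaling parameters.

    ``x_min``/``x_max`` are in raw units per column; ``y_min``/``y_max`` are
    the target normalized range (default [0, 1]).
    """

    x_min: dict[str, float]
    x_max: dict[str, float]
    y_min: float = 0.0
    y_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.y_min < self.y_max:
            raise ValueError(f"require y_min < y_max, got {self.y_min} >= {self.y_max}")
        for col in self.x_min:
            if not self.x_max[col] > self.x_min[col]:
                raise ValueError(
                    f"degenerate scaling for column {col!r}: "
                    f"x_max ({self.x_max[col]}) must exceed x_min ({self.x_min[col]})"
                )

    @property
    def columns(self) -> list[str]:
        return list(self.x_min)

    def normalize(self, table: pd.DataFrame) -> pd.DataFrame:
        """Normalize every scaled column present in ``table``; others pass through."""
        out = table.copy()
        for col in self.columns:
            if col in out.columns:
                out[col] = normalize_column(out[col].to_numpy(float), self, col)
        return out

    def denormalize(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.columns:
            if col in out.columns:
                out[col] = denormalize_column(out[col].to_numpy(float), self, col)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScalingParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(x_min=d["x_min"], x_max=d["x_max"], y_min=d["y_min"], y_max=d["y_max"])


def normalize_column(
    values: np.ndarray | Iterable[float], params: ScalingParams, column: str
) -> np.ndarray:
    """Min-max normalize one column of raw values."""
    if column not in params.x_min:
        raise KeyError(f"no scaling parameters for column {column!r}")
    x = np.asarray(values, dtype=float)
    lo, hi = params.x_min[column], params.x_max[column]
    if not hi > lo:
        raise ValueError(f"degenerate column {column!r}: x_max == x_min == {lo}")
    return (params.y_max - params.y_min) * (x - lo) / (hi - lo) + params.y_min


def denormalize_column(
    values: np.ndarray | Iterable[float], params: ScalingParams, column: str
) -> np.ndarray:
    """Inverse of :func:`normalize_column`."""
    if column not in params.x_min:
        raise KeyError(f"no scaling parameters for column {column!r}")
    if not params.y_max > params.y_min:
        raise ValueError("degenerate normalized range: y_max == y_min")
    y = np.asarray(values, dtype=float)
    lo, hi = params.x_min[column], params.x_max[column]
    return (y - params.y_min) * (hi - lo) / (params.y_max - params.y_min) + lo


def fit_scaling(
    table: pd.DataFrame,
    columns: Iterable[str] | None = None,
    y_min: float = 0.0,
    y_max: float = 1.0,
) -> ScalingParams:
    """Fit per-column extrema on ``table``.

    By default scales every canonical column present (conditions and, if
    present, production).  Raises on constant columns, which cannot be
    min-max scaled.
    """
    if columns is None:
        columns = [c for c in ALL_COLUMNS if c in table.columns]
    x_min: dict[str, float] = {}
    x_max: dict[str, float] = {}
    for col in columns:
        vals = table[col].to_numpy(float)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if not hi > lo:
            raise ValueError(f"constant column {col!r} (all values {lo}): cannot scale")
        x_min[col], x_max[col] = lo, hi
    return ScalingParams(x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max)


@dataclass
class SplitResult:
    """Stratified train/test split with the seed that produced it."""

    train: pd.DataFrame
    test: pd.DataFrame
    level_counts: dict[str, int]
    seed: int
    train_frac: float = 0.7

    def __post_init__(self) -> None:
        n = len(self.train) + len(self.test)
        if n == 0:
            raise ValueError("empty split")


def stratified_split(
    table: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> SplitResult:
    """Shuffle within each yield level and take the first 70% as training data.

    Per level, records are permuted by a generator seeded with ``seed`` and the
    first ``floor(train_frac * n_level)`` go to train, the remainder to test.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must lie in (0, 1), got {train_frac}")
    if PRODUCTION_COLUMN not in table.columns:
        raise ValueError("stratified_split requires a production column")
    rng = np.random.default_rng(seed)
    levels = table[PRODUCTION_COLUMN].map(assign_level)
    train_parts: list[pd.DataFrame] = []
    test_parts: list[pd.DataFrame] = []
    counts: dict[str, int] = {lv.value: 0 for lv in YieldLevel}
    for level in YieldLevel:  # fixed order => deterministic
        sub = table.loc[levels == level]
        counts[level.value] = len(sub)
        if len(sub) == 0:
            continue
        perm = rng.permutation(len(sub))
        n_train = int(np.floor(train_frac * len(sub)))
        train_parts.append(sub.iloc[perm[:n_train]])
        test_parts.append(sub.iloc[perm[n_train:]])
    train = pd.concat(train_parts) if train_parts else table.iloc[:0]
    test = pd.concat(test_parts) if test_parts else table.iloc[:0]
    return SplitResult(
        train=train.reset_index(drop=True),
        test=test.reset_index(drop=True),
        level_counts=counts,
        seed=seed,
        train_frac=train_frac,
    )


def read_table(path: str | Path, require_production: bool = False) -> pd.DataFrame:
    """Read a fermentation table from CSV.

    The header must name all nine condition columns; the production column is
    optional (candidate condition sets have none).  Non-numeric cells raise
    with their row and column identity.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in CONDITION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if require_production and PRODUCTION_COLUMN not in raw.columns:
        raise ValueError(f"{path}: missing required column {PRODUCTION_COLUMN!r}")
    cols = [c for c in ALL_COLUMNS if c in raw.columns]
    out = raw[cols].copy()
    for col in cols:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: "
                f"{out[col].iloc[row]!r}"
            )
        if coerced.isna().any() and col != PRODUCTION_COLUMN:
            row = int(coerced.isna().idxmax())
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        out[col] = coerced.astype(float)
    return out


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a fermentation table to CSV (lossless numeric round trip)."""
    cols = [c for c in ALL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.17g")
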