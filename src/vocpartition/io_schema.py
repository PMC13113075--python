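"""Data model, CSV I/O and structural validation for the acoustic feature table.

One row of the table is one 20-second acoustic sample cut from a 60-second
recording of a single pig under one distress condition in one growth phase.
The factor structure is strictly nested: Animal -> growth phase -> distress
condition -> recording -> sample.  Only the pitch trait may be missing
(pitch tracking fails on unvoiced or noisy segments); every other trait must
be complete, and a table violating that is rejected at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEX_LEVELS: tuple[str, ...] = ("female", "male")
PHASE_LEVELS: tuple[str, ...] = ("farrowing", "nursery", "growing", "finishing")
CONDITION_LEVELS: tuple[str, ...] = ("normal", "pain", "hunger", "thirst", "cold", "heat")

#: Canonical acoustic trait columns, in fixed written order.
TRAITS: tuple[str, ...] = (
    "energy", "duration", "amp_max", "amp_min", "intensity",
    "pitch", "f1", "f2", "f3", "f4",
)
FACTORS: tuple[str, ...] = ("animal_id", "sex", "phase", "condition", "recording_id")
KEY_COLUMNS: tuple[str, ...] = ("animal_id", "recording_id", "sample_index")
ALL_COLUMNS: tuple[str, ...] = FACTORS + ("sample_index",) + TRAITS

#: Traits that must be strictly positive when present.
_POSITIVE_TRAITS = ("duration", "pitch", "f1", "f2", "f3", "f4")


class SchemaError(ValueError):
    """A required column is absent or the schema mapping is malformed."""


class ValidationError(ValueError):
    """Cell values violate the closed level sets or numeric constraints."""


class IntegrityError(ValueError):
    """Structural integrity violated (duplicate keys, inconsistent sex)."""


@dataclass(frozen=True)
class FeatureTable:
    """A validated table of acoustic samples.

    Wraps a :class:`pandas.DataFrame` whose columns follow the canonical
    naming; construction always validates, so any ``FeatureTable`` in hand
    satisfies the structural invariants.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate(self.data))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(c for c in TRAITS if c in self.data.columns)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return FACTORS

    def equals(self, other: "FeatureTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        return a.equals(b)


def _as_categorical(s: pd.Series, levels: Sequence[str], name: str) -> pd.Series:
    s = s.astype(str)
    bad = ~s.isin(levels)
    if bad.any():
        rows = list(s.index[bad][:10])
        vals = sorted(set(s[bad]))
        raise ValidationError(
            f"column {name!r} contains levels outside {list(levels)}: "
            f"{vals} (rows {rows})"
        )
    return pd.Series(pd.Categorical(s, categories=list(levels)), index=s.index, name=name)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in FACTORS + ("sample_index",) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"required column(s) missing: {missing_cols}")
    traits = [c for c in TRAITS if c in df.columns]
    if not traits:
        raise SchemaError("no acoustic trait columns present")

    df = df.copy()
    df["animal_id"] = df["animal_id"].astype(str)
    df["recording_id"] = df["recording_id"].astype(str)
    df["sex"] = _as_categorical(df["sex"], SEX_LEVELS, "sex")
    df["phase"] = _as_categorical(df["phase"], PHASE_LEVELS, "phase")
    df["condition"] = _as_categorical(df["condition"], CONDITION_LEVELS, "condition")

    try:
        df["sample_index"] = df["sample_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"sample_index must be integer: {exc}") from None
    if not df["sample_index"].isin([1, 2, 3]).all():
        bad = df.index[~df["sample_index"].isin([1, 2, 3])][:10]
        raise ValidationError(f"sample_index outside {{1,2,3}} (rows {list(bad)})")

    for c in traits:
        df[c] = pd.to_numeric(df[c], errors="coerce")
        na = df[c].isna()
        if c != "pitch" and na.any():
            raise ValidationError(
                f"trait {c!r} has missing values (rows {list(df.index[na][:10])}); "
                "only pitch may be missing"
            )
        present = df[c].dropna()
        if not np.isfinite(present).all():
            raise ValidationError(f"trait {c!r} has non-finite values")
        if c in _POSITIVE_TRAITS and (present <= 0).any():
            bad = present.index[present <= 0][:10]
            raise ValidationError(f"trait {c!r} must be > 0 (rows {list(bad)})")

    if len(df):
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].head(5).to_dict("records")
            raise IntegrityError(f"duplicate (animal_id, recording_id, sample_index): {keys}")
        per_rec = df.groupby(["animal_id", "recording_id"], observed=True).size()
        if (per_rec > 3).any():
            raise IntegrityError("more than 3 samples share one (animal_id, recording_id)")
        sex_n = df.groupby("animal_id", observed=True)["sex"].nunique()
        if (sex_n > 1).any():
            bad = list(sex_n.index[sex_n > 1][:10])
            raise IntegrityError(f"animals with inconsistent sex: {bad}")

    ordered = [c for c in ALL_COLUMNS if c in df.columns]
    return df[ordered].reset_index(drop=True)


def load_table(path: str | Path, schema: Mapping[str, str] | None = None) -> FeatureTable:
    """Read a feature-table CSV and validate it.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``canonical name -> column name in the file`` for
        dialects whose headers differ from the canonical names.  Empty cells
        in the pitch column are read as missing.
    """
    # read as strings so identifier columns round-trip verbatim ("01" stays
    # "01"); validation coerces the numeric columns
    raw = pd.read_csv(path, dtype=str)
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [v for v in schema.values() if v not in raw.columns]
        if missing:
            raise SchemaError(f"schema maps to absent column(s): {missing}")
        raw = raw.rename(columns=rename)
    return FeatureTable(raw)


def write_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (canonical column order, NA as empty cell)."""
    df = table.data
    ordered = [c for c in ALL_COLUMNS if c in df.columns]
    df[ordered].to_csv(path, index=False, na_rep="")


@dataclass
class DesignReport:
    """Cell-level summary of the phase x condition x sex design."""

    cells: pd.DataFrame           # index (phase, condition); female/male/total/missing
    total_n: int
    absent_cells: list[tuple[str, str]] = field(default_factory=list)


def validate_design(table: FeatureTable) -> DesignReport:
    """Tabulate sample counts and pitch missingness per design cell.

    Mirrors the study's design table: one row per growth phase x distress
    condition with per-sex counts, total, and pitch-missing n and percent.
    Cells with zero rows (e.g. heat stress during farrowing, which the study
    never ran) are flagged as absent from the design.
    """
    df = table.data
    rows = []
    absent: list[tuple[str, str]] = []
    for phase in PHASE_LEVELS:
        for cond in CONDITION_LEVELS:
            sub = df[(df["phase"] == phase) & (df["condition"] == cond)]
            if len(sub) == 0:
                absent.append((phase, cond))
                continue
            n_female = int((sub["sex"] == "female").sum())
            n_male = int((sub["sex"] == "male").sum())
            total = len(sub)
            if "pitch" in sub.columns:
                n_missing = int(sub["pitch"].isna().sum())
            else:
                n_missing = 0
            rows.append(
                {
                    "phase": phase,
                    "condition": cond,
                    "female": n_female,
                    "male": n_male,
                    "total": total,
                    "pitch_missing_n": n_missing,
                    "pitch_missing_pct": round(100.0 * n_missing / total, 1),
                }
            )
    cells = pd.DataFrame(
        rows,
        columns=["phase", "condition", "female", "male", "total",
                 "pitch_missing_n", "pitch_missing_pct"],
    ).set_index(["phase", "condition"])
    return DesignReport(cells=cells, total_n=int(len(df)), absent_cells=absent)
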