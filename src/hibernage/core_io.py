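"""Readers and writers for sample tables, beta matrices and model artifacts.

The study's time axis is a 365-day "study year" that starts on 1 May (study
day 1) and ends on 30 April (study day 365), so that a single hibernation
falls inside one cycle. All downstream code works exclusively in study
day-of-year; calendar or 1-January-origin Julian days are converted at
ingest. Leap days are rejected rather than silently remapped, because every
periodic term downstream uses a 365-day cycle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SampleTable",
    "MethylationMatrix",
    "calendar_to_study_doy",
    "study_doy_to_calendar",
    "jday_to_study_doy",
    "read_sample_table",
    "write_sample_table",
    "read_beta_matrix",
    "write_beta_matrix",
    "write_artifact",
    "read_artifact",
]


class SchemaError(ValueError):
    """A required column is missing or an input file is malformed."""


class ValidationError(ValueError):
    """Row- or cell-level values violate a domain invariant."""


# days per month in a non-leap year
_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_CUM = np.concatenate([[0], np.cumsum(_MONTH_DAYS)])
# 30 April is day 120 of the calendar year; study day 1 is 1 May
_MAY1_OFFSET = 120


def calendar_to_study_doy(month: int, day_of_month: int) -> int:
    """Map a non-leap calendar date to the study day-of-year (1 = 1 May).

    Parameters
    ----------
    month, day_of_month : int
        Calendar month (1-12) and day. 29 February is rejected: the study
        year is a fixed 365-day cycle.
    """
    if not 1 <= month <= 12:
        raise ValidationError(f"month {month} outside 1-12")
    if not 1 <= day_of_month <= _MONTH_DAYS[month - 1]:
        raise ValidationError(f"invalid day {day_of_month} for month {month}")
    jan1_doy = int(_MONTH_CUM[month - 1]) + day_of_month
    return (jan1_doy - _MAY1_OFFSET - 1) % 365 + 1


def study_doy_to_calendar(doy: int) -> tuple[int, int]:
    """Inverse of :func:`calendar_to_study_doy`."""
    if not 1 <= doy <= 365:
        raise ValidationError(f"study doy {doy} outside 1-365")
    jan1_doy = (doy + _MAY1_OFFSET - 1) % 365 + 1
    month = int(np.searchsorted(_MONTH_CUM, jan1_doy, side="left"))
    return month, jan1_doy - int(_MONTH_CUM[month - 1])


def jday_to_study_doy(jday: Iterable[int] | int, origin: str = "jan1"):
    """Convert a day-of-year with the given origin to study doy.

    ``origin='jan1'`` treats the input as a calendar Julian day (1 = 1 Jan);
    ``origin='may1'`` means the input is already on the study origin and is
    returned unchanged (after range validation).
    """
    arr = np.asarray(jday, dtype=int)
    if np.any((arr < 1) | (arr > 365)):
        bad = arr[(arr < 1) | (arr > 365)]
        raise ValidationError(f"day-of-year values outside [1,365]: {bad[:5].tolist()}")
    if origin == "may1":
        out = arr
    elif origin == "jan1":
        out = (arr - _MAY1_OFFSET - 1) % 365 + 1
    else:
        raise ValueError(f"unknown doy origin {origin!r}")
    return out if np.ndim(jday) else int(out)


# canonical column order for the generic dialect
_CANONICAL = ["sample_id", "animal_id", "age", "doy"]
_OPTIONAL = ["epigenetic_state", "clock_age", "year", "birth_doy"]

_SUPP_MAP = {
    "Basename": "sample_id",
    "AnimalID": "animal_id",
    "Age": "age",
    "Trap_jday": "doy",
    "Epigenetic_state": "epigenetic_state",
    "EC_predicted": "clock_age",
}
_SUPP_REQUIRED = ["Basename", "AnimalID", "Age", "Trap_jday"]


@dataclass
class SampleTable:
    """One row per blood sample: identity, chronological age and study doy.

    Chronological age is in years from first natal-burrow emergence; ``doy``
    is the study day-of-year. ``epigenetic_state`` (pacemaker) and
    ``clock_age`` (elastic-net clock) are optional precomputed epigenetic
    ages; ``year`` is an optional study-year index used by longitudinal
    operations and carried through when present.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _CANONICAL if c not in self.df.columns]
        if missing:
            raise SchemaError(f"sample table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        bad_age = df.index[~(df["age"].astype(float) >= 0)].tolist()
        bad_doy = df.index[~df["doy"].astype(float).between(1, 365)].tolist()
        if bad_age or bad_doy:
            raise ValidationError(
                f"invalid rows: negative/unparseable age at {bad_age}, "
                f"doy outside [1,365] at {bad_doy}"
            )
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate sample ids: {dup}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def animal_ids(self) -> np.ndarray:
        return self.df["animal_id"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def doys(self) -> np.ndarray:
        return self.df["doy"].to_numpy(dtype=int)

    @property
    def n_animals(self) -> int:
        return self.df["animal_id"].nunique()

    def with_column(self, name: str, values) -> "SampleTable":
        df = self.df.copy()
        df[name] = np.asarray(values)
        return SampleTable(df)


def read_sample_table(
    path: str | Path,
    dialect: str = "generic",
    doy_origin: str = "jan1",
) -> SampleTable:
    """Read a sample table CSV.

    ``dialect='supplementary_data_1'`` accepts the study's supplementary
    column names verbatim (Basename, Age, AnimalID, Trap_jday, ...);
    Trap_jday is converted to study doy according to ``doy_origin``.
    ``dialect='generic'`` expects lowercase canonical names with ``doy``
    already on the study origin.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if dialect == "supplementary_data_1":
        missing = [c for c in _SUPP_REQUIRED if c not in raw.columns]
        if missing:
            raise SchemaError(f"supplementary_data_1 table missing columns: {missing}")
        df = raw.rename(columns=_SUPP_MAP)
        df = df[[c for c in _CANONICAL + _OPTIONAL if c in df.columns]]
        if len(df):
            df["doy"] = jday_to_study_doy(df["doy"].to_numpy(dtype=int), origin=doy_origin)
    elif dialect == "generic":
        missing = [c for c in _CANONICAL if c not in raw.columns]
        if missing:
            raise SchemaError(f"generic sample table missing columns: {missing}")
        # canonical columns first; extra columns (states, traits, ...) kept
        order = [c for c in _CANONICAL + _OPTIONAL if c in raw.columns]
        order += [c for c in raw.columns if c not in order]
        df = raw[order].copy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        if len(df):
            df["age"] = df["age"].astype(float)
            df["doy"] = df["doy"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"unparseable age/doy values: {exc}") from exc
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


@dataclass
class MethylationMatrix:
    """Normalized methylation beta values, sites in rows, samples in columns."""

    site_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.site_ids = list(self.site_ids)
        self.sample_ids = list(self.sample_ids)
        if self.beta.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta shape {self.beta.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            dup = pd.Series(self.site_ids)
            raise ValidationError(
                f"duplicate site ids: {dup[dup.duplicated()].tolist()[:5]}"
            )
        bad = np.argwhere((self.beta < 0) | (self.beta > 1) | ~np.isfinite(self.beta))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"beta value {self.beta[i, j]!r} outside [0,1] at site "
                f"{self.site_ids[i]!r}, sample {self.sample_ids[j]!r} "
                f"({len(bad)} offending cells)"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_sites(self, site_ids: Sequence[str]) -> "MethylationMatrix":
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in index]
        if missing:
            raise ValidationError(f"sites not in matrix: {missing[:10]}")
        rows = [index[s] for s in site_ids]
        return MethylationMatrix(list(site_ids), self.sample_ids, self.beta[rows])

    def subset_samples(self, col_index: Sequence[int]) -> "MethylationMatrix":
        cols = list(col_index)
        return MethylationMatrix(
            self.site_ids, [self.sample_ids[j] for j in cols], self.beta[:, cols]
        )


def read_beta_matrix(path: str | Path) -> MethylationMatrix:
    """Read a delimited beta matrix (first column site id, header sample ids).

    The delimiter is comma for ``.csv`` and tab otherwise.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"ragged or malformed beta matrix {path}: {exc}") from exc
    if df.isna().any().any():
        raise SchemaError(f"beta matrix {path} has missing/ragged cells")
    return MethylationMatrix(
        [str(s) for s in df.index], [str(s) for s in df.columns], df.to_numpy(float)
    )


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(
        matrix.beta, index=matrix.site_ids, columns=matrix.sample_ids
    ).to_csv(path, sep=sep, index_label="site_id")


def _config_hash(config) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_artifact(path: str | Path, kind: str, payload: dict, config: dict | None = None,
                   seed: int | None = None) -> None:
    """Serialize a model/result artifact as JSON with its provenance stamp."""
    doc = {
        "kind": kind,
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config or {}),
        "payload": payload,
    }

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=1, default=_default))


def read_artifact(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
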