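"""Calf-record data model, CSV I/O, inclusion rules and descriptive statistics.

One record per calf: herd and calf identifiers, age in days, the reference
serum IgG concentration by radial immunodiffusion (RID), and up to five
indirect measurements -- serum total protein by biochemistry analyzer
(``stp_ba``, g/L), serum albumin (``alb``, g/L), digital Brix refractometry
(``brix``, %), serum total protein by optical refractometry (``stp_op``,
g/L), and gamma-glutamyl transferase activity (``ggt``, IU/L). Any
measurement may be missing. Derived fields: calculated globulin
GLOB = STP_BA - ALB, the binary FTPI status (IgG below threshold), and the
age group used for GGT stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for calf CSV files
COLUMNS = ("herd_id", "calf_id", "age_days", "igg_rid", "stp_ba", "alb", "brix", "stp_op", "ggt")
#: all measured quantities (g/L, %, IU/L depending on the column)
MEASUREMENT_FIELDS = ("igg_rid", "stp_ba", "alb", "brix", "stp_op", "ggt")
#: indirect index tests evaluated against the RID-IgG reference
INDEX_TESTS = ("brix", "stp_op", "stp_ba", "glob", "ggt")

#: tokens (case-insensitive, after stripping) that silently denote missing
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: physiological serum Brix window (%); guards against fraction-vs-percent mixups
BRIX_RANGE = (0.0, 30.0)

FTPI_THRESHOLD_DEFAULT = 10.0  # g/L RID-IgG; positive iff strictly below
AGE_WINDOW_DEFAULT = (2, 6)  # inclusive days of age retained for analysis


@dataclass(frozen=True)
class CalfRecord:
    """A single calf's identifiers, age and measurement panel."""

    herd_id: str
    calf_id: str
    age_days: Optional[int] = None
    igg_rid: Optional[float] = None
    stp_ba: Optional[float] = None
    alb: Optional[float] = None
    brix: Optional[float] = None
    stp_op: Optional[float] = None
    ggt: Optional[float] = None


@dataclass
class Dataset:
    """An ordered collection of calf records with provenance.

    Backed by a :class:`pandas.DataFrame` using the canonical columns;
    missing values are NaN (measurements) or NA (age). Construction
    validates uniqueness of (herd_id, calf_id) and measurement invariants.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col in ("herd_id", "calf_id"):
                    raise ValueError(f"dataset is missing required column {col!r}")
                df[col] = pd.NA if col == "age_days" else np.nan
        df["herd_id"] = df["herd_id"].astype(str)
        df["calf_id"] = df["calf_id"].astype(str)
        df["age_days"] = df["age_days"].astype("Int64")
        for col in MEASUREMENT_FIELDS:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df = df.reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        dup = df.duplicated(subset=["herd_id", "calf_id"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (herd_id, calf_id) key: ({row['herd_id']!r}, {row['calf_id']!r})"
            )
        age = df["age_days"]
        if ((age.dropna() < 0)).any():
            raise ValueError("age_days must be non-negative")
        for col in MEASUREMENT_FIELDS:
            vals = df[col].to_numpy()
            present = ~np.isnan(vals)
            if np.isinf(vals[present]).any():
                raise ValueError(f"non-finite value in column {col!r}")
            if (vals[present] < 0).any():
                raise ValueError(f"negative value in column {col!r}")
        brix = df["brix"].dropna()
        lo, hi = BRIX_RANGE
        if ((brix <= lo) | (brix >= hi)).any():
            bad = brix[(brix <= lo) | (brix >= hi)].iloc[0]
            raise ValueError(
                f"brix value {bad} outside physiological range ({lo}, {hi}); "
                "check percent-vs-fraction units"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[CalfRecord]:
        """Iterate over rows as :class:`CalfRecord` objects."""
        for _, row in self.df.iterrows():
            yield CalfRecord(
                herd_id=row["herd_id"],
                calf_id=row["calf_id"],
                age_days=None if pd.isna(row["age_days"]) else int(row["age_days"]),
                **{
                    f: None if pd.isna(row[f]) else float(row[f])
                    for f in MEASUREMENT_FIELDS
                },
            )

    def with_provenance(self, note: str) -> "Dataset":
        prov = f"{self.provenance}; {note}" if self.provenance else note
        return Dataset(self.df, provenance=prov)


def _parse_numeric_column(raw: pd.Series, col: str) -> pd.Series:
    """Parse raw string tokens to floats; messy tokens become missing.

    Recognised missing tokens are silent; any other non-numeric token is
    coerced to missing with a logged warning (fail loudly only on
    structural errors).
    """
    out = np.full(len(raw), np.nan)
    for i, token in enumerate(raw):
        tok = str(token).strip()
        if tok.lower() in MISSING_TOKENS:
            continue
        try:
            out[i] = float(tok)
        except ValueError:
            logger.warning("non-numeric value %r in column %r (row %d) treated as missing", tok, col, i)
    return pd.Series(out, index=raw.index)


def read_dataset(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    provenance: Optional[str] = None,
) -> Dataset:
    """Read a calf cohort from a CSV file.

    ``column_map`` maps file header names to canonical column names for
    files with non-canonical headers. Empty cells, ``NA`` and ``NaN``
    (case-insensitive) denote missing; other non-numeric tokens become
    missing with a warning. Duplicate (herd, calf) keys are a fatal error.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    for required in ("herd_id", "calf_id"):
        if required not in raw.columns:
            raise ValueError(f"input file {path} lacks required column {required!r}")
    df = pd.DataFrame({"herd_id": raw["herd_id"].astype(str), "calf_id": raw["calf_id"].astype(str)})
    if "age_days" in raw.columns:
        age_float = _parse_numeric_column(raw["age_days"], "age_days")
        nonint = age_float.notna() & (age_float % 1 != 0)
        if nonint.any():
            logger.warning("non-integer age_days values treated as missing (%d rows)", int(nonint.sum()))
            age_float[nonint] = np.nan
        df["age_days"] = age_float.round().astype("Int64")
    for col in MEASUREMENT_FIELDS:
        if col in raw.columns:
            df[col] = _parse_numeric_column(raw[col], col)
    return Dataset(df, provenance=provenance or f"read from {path}")


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a cohort to CSV; missing values become empty cells.

    Floats are written with ``repr`` precision so a read round-trips
    bit-exactly.
    """
    ds.df.to_csv(path, index=False)


def apply_age_filter(
    ds: Dataset,
    min_age: int = AGE_WINDOW_DEFAULT[0],
    max_age: int = AGE_WINDOW_DEFAULT[1],
) -> Dataset:
    """Retain calves with known age inside the inclusive [min_age, max_age] window.

    Records removed because age is missing, below or above the window are
    counted in the provenance string (and in the log).
    """
    if min_age > max_age:
        raise ValueError("min_age must be <= max_age")
    age = ds.df["age_days"]
    missing = age.isna()
    younger = age.notna() & (age < min_age)
    older = age.notna() & (age > max_age)
    keep = ~(missing | younger | older)
    note = (
        f"age filter [{min_age},{max_age}] d: kept {int(keep.sum())} of {len(ds)} "
        f"(missing age: {int(missing.sum())}, younger: {int(younger.sum())}, older: {int(older.sum())})"
    )
    logger.info(note)
    out = Dataset(ds.df.loc[keep], provenance=ds.provenance)
    return out.with_provenance(note)


def derive_fields(ds: Dataset, ftpi_threshold: float = FTPI_THRESHOLD_DEFAULT) -> Dataset:
    """Add the derived columns ``glob``, ``ftpi_status`` and ``age_group``.

    GLOB = STP_BA - ALB, present only when both components are. FTPI is
    positive iff the reference IgG is strictly below ``ftpi_threshold``
    (IgG exactly at the threshold is negative). The age group is ``"2-3"``
    or ``"4-6"`` days, else ``"excluded"``.
    """
    df = ds.df.copy()
    df["glob"] = df["stp_ba"] - df["alb"]
    status = pd.Series(pd.NA, index=df.index, dtype="boolean")
    has_igg = df["igg_rid"].notna()
    status[has_igg] = df.loc[has_igg, "igg_rid"] < ftpi_threshold
    df["ftpi_status"] = status
    age = df["age_days"]
    group = pd.Series("excluded", index=df.index, dtype=object)
    group[age.notna() & (age >= 2) & (age <= 3)] = "2-3"
    group[age.notna() & (age >= 4) & (age <= 6)] = "4-6"
    df["age_group"] = group
    return Dataset(df, provenance=ds.provenance)


def describe(ds: Dataset, variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-variable complete-case descriptive statistics.

    Each variable is summarised on its own non-missing subset: count,
    mean, sample SD (n-1 denominator), and first/third quartiles under
    linear interpolation between order statistics (the numpy default).
    Variables with no non-missing values get n = 0 and NaN statistics.
    """
    if variables is None:
        variables = [c for c in MEASUREMENT_FIELDS + ("glob",) if c in ds.df.columns]
    rows = []
    for var in variables:
        if var not in ds.df.columns:
            raise KeyError(f"unknown variable {var!r}")
        vals = pd.to_numeric(ds.df[var], errors="coerce").dropna().to_numpy(dtype=float)
        if vals.size == 0:
            rows.append({"variable": var, "n": 0, "mean": np.nan, "sd": np.nan, "q1": np.nan, "q3": np.nan})
            continue
        rows.append(
            {
                "variable": var,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
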