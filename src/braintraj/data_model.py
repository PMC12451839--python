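"""Domain types and long-format table I/O shared by every pipeline stage.

The canonical in-memory container is :class:`LongitudinalDataset`, a thin
validated wrapper around a long-format :class:`pandas.DataFrame` with one row
per subject-visit-region volume record.  Missing visits are absent rows, not
sentinel values: the mixed models downstream tolerate unbalanced designs
natively.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "SEXES",
    "Observation",
    "LongitudinalDataset",
    "RescaleRecord",
    "SchemaError",
    "ParseError",
    "read_long_table",
    "write_long_table",
    "average_hemispheres",
    "rescale_volumes",
]

#: Closed vocabulary of region labels.
REGIONS = (
    "cortical_gm",
    "white_matter",
    "tbv",
    "hippocampus",
    "amygdala",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "thalamus",
    "etiv",
)

#: Closed vocabulary of sexes; female is the reference level everywhere.
SEXES = ("female", "male")

#: Required long-table columns (etiv is optional).
REQUIRED_COLUMNS = ("subject_id", "wave", "age", "sex", "region", "volume")
OPTIONAL_COLUMNS = ("euler", "software", "etiv")


class SchemaError(ValueError):
    """A required column is missing or mis-typed at the table level."""


class ParseError(ValueError):
    """A row-level value could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


@dataclasses.dataclass(frozen=True)
class Observation:
    """One subject-visit-region volume record."""

    subject_id: str
    wave: int
    age: float
    sex: str
    region: str
    volume: float
    euler: float | None = None
    software: str | None = None
    etiv: float | None = None

    def __post_init__(self):
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclasses.dataclass(frozen=True)
class RescaleRecord:
    """Records that a region's volumes were divided by ``divisor``."""

    region: str
    divisor: float

    def __post_init__(self):
        if self.divisor not in (1, 100):
            raise ValueError(f"divisor must be 1 or 100, got {self.divisor}")


class LongitudinalDataset:
    """Validated long-format cohort table.

    Parameters
    ----------
    frame
        Long-format table with at least the columns ``subject_id, wave, age,
        sex, region, volume``; ``euler``, ``software`` and ``etiv`` are
        carried when present, and unknown extra columns are kept as opaque
        covariates.
    metadata
        Free-form study metadata.  ``metadata["rescale"]`` maps region name
        to the divisor already applied (1 or 100).
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None,
                 validate: bool = True):
        self.frame = frame.reset_index(drop=True)
        self.metadata = dict(metadata or {})
        self.metadata.setdefault("units", "mm^3")
        self.metadata.setdefault("rescale", {})
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        bad_age = df.index[~(df["age"] > 0)].tolist()
        if bad_age:
            raise ParseError(f"nonpositive age at row(s) {bad_age}", bad_age[0])
        bad_vol = df.index[~(df["volume"] > 0)].tolist()
        if bad_vol:
            raise ParseError(f"nonpositive volume at row(s) {bad_vol}", bad_vol[0])
        bad_sex = df.index[~df["sex"].isin(SEXES)].tolist()
        if bad_sex:
            raise ParseError(f"unknown sex at row(s) {bad_sex}", bad_sex[0])
        bad_region = df.index[~df["region"].isin(REGIONS)].tolist()
        if bad_region:
            raise ParseError(f"unknown region at row(s) {bad_region}", bad_region[0])
        dup = df.duplicated(subset=["subject_id", "wave", "region"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ParseError(
                f"duplicate (subject, wave, region) at row(s) {rows}", rows[0])
        # within a subject (and region), ages strictly increase with wave
        for (sid, region), g in df.groupby(["subject_id", "region"], sort=False):
            g = g.sort_values("wave")
            if not g["age"].is_monotonic_increasing or g["age"].duplicated().any():
                raise ParseError(
                    f"ages not strictly increasing with wave for subject "
                    f"{sid!r}, region {region!r}")

    # -- convenience --------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    def region_frame(self, region: str) -> pd.DataFrame:
        """Rows for one region, sorted by subject then wave."""
        sub = self.frame[self.frame["region"] == region]
        if sub.empty:
            raise KeyError(f"region {region!r} not present in dataset")
        return sub.sort_values(["subject_id", "wave"]).reset_index(drop=True)

    def observations(self) -> list[Observation]:
        known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
        out = []
        for rec in self.frame.to_dict("records"):
            kw = {k: rec[k] for k in known if k in rec and pd.notna(rec[k])}
            kw["wave"] = int(kw["wave"])
            out.append(Observation(**kw))
        return out

    def copy(self) -> "LongitudinalDataset":
        import copy as _copy
        return LongitudinalDataset(self.frame.copy(),
                                   _copy.deepcopy(self.metadata),
                                   validate=False)

    def equals(self, other: "LongitudinalDataset") -> bool:
        a = self.frame.sort_values(["subject_id", "wave", "region"]).reset_index(drop=True)
        b = other.frame.sort_values(["subject_id", "wave", "region"]).reset_index(drop=True)
        if sorted(a.columns) != sorted(b.columns):
            return False
        return a[sorted(a.columns)].equals(b[sorted(b.columns)])

    def __repr__(self) -> str:
        return (f"<LongitudinalDataset: {self.n_obs} observations, "
                f"{self.n_subjects} subjects, regions={self.regions()}>")


# -- I/O --------------------------------------------------------------------

def read_long_table(path: str | Path, dialect: str | None = None,
                    column_map: Mapping[str, str] | None = None,
                    metadata: dict | None = None) -> LongitudinalDataset:
    """Read a long-format CSV/TSV cohort table.

    Parameters
    ----------
    path
        File path.  UTF-8, "." decimal separator, empty field = missing.
    dialect
        Field delimiter; inferred from the extension when ``None``
        (``.tsv`` → tab, otherwise comma).
    column_map
        Optional mapping from file column names to canonical names, e.g.
        ``{"sid": "subject_id"}``.

    Raises
    ------
    SchemaError
        If a required column is absent after renaming.
    ParseError
        If age/volume cells fail numeric parsing, with the 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect or ("\t" if path.suffix.lower() == ".tsv" else ",")
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str},
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in ("age", "volume"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            row = int(bad[0]) + 1  # 1-based data row, header excluded
            raise ParseError(
                f"{path.name}: non-numeric {col} {df.loc[bad[0], col]!r} "
                f"at data row {row}", row)
        df[col] = coerced
    for col in ("euler", "etiv"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["wave"] = pd.to_numeric(df["wave"], errors="raise").astype(int)
    return LongitudinalDataset(df, metadata=metadata)


def write_long_table(dataset: LongitudinalDataset, path: str | Path,
                     dialect: str | None = None) -> Path:
    """Write the dataset back to CSV/TSV (lossless for finite decimals)."""
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() == ".tsv" else ",")
    # 17 significant digits guarantees bit-for-bit float64 round-trips
    dataset.frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


# -- elementary operations --------------------------------------------------

def average_hemispheres(left, right):
    """Arithmetic mean of left/right hemisphere volumes (mm³).

    Subcortical regions are analysed as the across-hemisphere average.
    Symmetric and bounded between its arguments; both inputs must be > 0.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("hemisphere volumes must be positive")
    return (left + right) / 2.0


def rescale_volumes(dataset: LongitudinalDataset, regions, divisor: float
                    ) -> LongitudinalDataset:
    """Divide the named regions' volumes by ``divisor`` (typically 100).

    Large global volumes (cortical grey matter, white matter) are rescaled
    before model fitting to avoid optimizer conditioning problems; all
    reported parameter estimates for those regions are then on the rescaled
    scale.  Re-rescaling an already-rescaled region is refused.
    """
    if not divisor > 0:
        raise ValueError("divisor must be positive")
    if isinstance(regions, str):
        regions = [regions]
    out = dataset.copy()
    applied = out.metadata.setdefault("rescale", {})
    for region in regions:
        prior = applied.get(region, 1)
        undoes_prior = abs(prior * divisor - 1) < 1e-12 and prior != 1
        if divisor != 1 and prior != 1 and not undoes_prior:
            raise ValueError(
                f"region {region!r} already rescaled by {prior}; "
                "refusing to rescale twice")
        mask = out.frame["region"] == region
        out.frame.loc[mask, "volume"] = out.frame.loc[mask, "volume"] / divisor
        if undoes_prior:
            del applied[region]
        elif divisor != 1:
            applied[region] = divisor
    return out
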