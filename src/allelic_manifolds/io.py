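"""Measurement tables, on-disk formats, and run configuration.

The canonical on-disk format is a UTF-8 comma-delimited table with a
header row and columns::

    promoter_id, architecture, t_minus, t_plus
    [condition, cAMP_uM, replicate_sd, is_outlier]   (optional)

``t_minus`` / ``t_plus`` are the transcription rates measured without /
with the active transcription factor, in the arbitrary units of the
reporter assay.  ``architecture`` is a free-form label for the promoter
layout (e.g. the TF-site center "-61.5"); no arithmetic is ever done on
it.  Spreadsheet exports with different column names can be ingested by
passing a ``dialect`` mapping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MeasurementTable",
    "ParseError",
    "ConfigError",
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "dump_json_summary",
]

REQUIRED_COLUMNS = ("promoter_id", "architecture", "t_minus", "t_plus")
OPTIONAL_COLUMNS = ("condition", "cAMP_uM", "replicate_sd", "is_outlier")


class ParseError(ValueError):
    """A measurement file violates the schema; the message names the row."""


class ConfigError(ValueError):
    """A run configuration is malformed."""


class MeasurementTable:
    """Validated table of paired (t-, t+) observations per promoter variant.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the
    schema on construction: required columns present, rates positive and
    finite, (promoter_id, condition) unique.
    """

    def __init__(self, df: pd.DataFrame):
        self._df = _validate(df)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def from_arrays(
        cls,
        promoter_id,
        t_minus,
        t_plus,
        architecture: str = "",
        condition: str = "",
    ) -> "MeasurementTable":
        return cls(
            pd.DataFrame(
                {
                    "promoter_id": list(promoter_id),
                    "architecture": architecture,
                    "condition": condition,
                    "t_minus": np.asarray(t_minus, dtype=float),
                    "t_plus": np.asarray(t_plus, dtype=float),
                }
            )
        )

    @classmethod
    def from_csv(cls, path, dialect: Optional[Mapping[str, str]] = None) -> "MeasurementTable":
        return read_measurements(path, dialect=dialect)

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying data (copy; mutate-and-rewrap to edit)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def n_non_outlier(self) -> int:
        return int((~self._df["is_outlier"]).sum())

    @property
    def promoter_ids(self) -> list:
        return list(self._df["promoter_id"])

    @property
    def architectures(self) -> list:
        return sorted(self._df["architecture"].unique())

    def non_outliers(self) -> "MeasurementTable":
        return MeasurementTable(self._df[~self._df["is_outlier"]].reset_index(drop=True))

    def with_outliers(self, promoter_ids) -> "MeasurementTable":
        """Copy with ``is_outlier`` set (OR-ed) for the given promoters."""
        df = self._df.copy()
        df["is_outlier"] = df["is_outlier"] | df["promoter_id"].isin(list(promoter_ids))
        return MeasurementTable(df)

    def by_architecture(self) -> dict:
        return {
            arch: MeasurementTable(g.reset_index(drop=True))
            for arch, g in self._df.groupby("architecture", sort=True)
        }

    def by_concentration(self, column: str = "cAMP_uM") -> dict:
        if column not in self._df.columns:
            raise ParseError(f"column {column!r} required to split by concentration")
        return {
            float(c): MeasurementTable(g.reset_index(drop=True))
            for c, g in self._df.groupby(column, sort=True)
        }

    # -- output ------------------------------------------------------------
    def to_csv(self, path) -> None:
        write_measurements(self, path)

    def __repr__(self) -> str:
        archs = ", ".join(map(str, self.architectures))
        return f"MeasurementTable(n={self.n}, architectures=[{archs}])"


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    if "condition" not in df.columns:
        df["condition"] = ""
    if "is_outlier" not in df.columns:
        df["is_outlier"] = False
    if df["is_outlier"].dtype == object:
        df["is_outlier"] = df["is_outlier"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    df["is_outlier"] = df["is_outlier"].astype(bool)
    for col in ("cAMP_uM", "replicate_sd"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["promoter_id"] = df["promoter_id"].astype(str)
    df["architecture"] = df["architecture"].astype(str)
    df["condition"] = df["condition"].fillna("").astype(str)
    for col in ("t_minus", "t_plus"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            rows = df.loc[bad, "promoter_id"].tolist()
            raise ParseError(
                f"column {col!r} must be positive and numeric; offending promoter(s): {rows}"
            )
        df[col] = vals.astype(float)
    dup = df.duplicated(subset=["promoter_id", "condition"], keep=False)
    if dup.any():
        rows = df.loc[dup, "promoter_id"].unique().tolist()
        raise ParseError(f"duplicate (promoter_id, condition) key(s): {rows}")
    keep = [c for c in df.columns]
    return df[keep].reset_index(drop=True)


def read_measurements(path, dialect: Optional[Mapping[str, str]] = None) -> MeasurementTable:
    """Read a measurement CSV (or spreadsheet export) into a validated table.

    ``dialect`` maps file column names to canonical ones, e.g.
    ``{"Promoter": "promoter_id", "expression_no_cAMP": "t_minus"}``.
    ``.xlsx`` files are read through pandas/openpyxl when available.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    # read everything as text so labels like "+0.5" survive verbatim;
    # numeric columns are converted (and checked) during validation
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    if dialect:
        df = df.rename(columns=dict(dialect))
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path) -> None:
    df = table.df
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_FIELDS = None  # filled after class definition


@dataclass
class RunConfig:
    """One self-contained analysis run, serializable to YAML.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    mechanism: str = "repression"
    fixed: dict = field(default_factory=dict)  # e.g. {"tsat": 15.1, "F": 23.9}
    n_boot: int = 100
    seed: int = 0
    n_starts: int = 10
    outlier_threshold: float = 0.5
    regime_strictness: float = 1.0
    select_concentrations: int = 4
    input: Optional[str] = None
    output: Optional[str] = None

    def __post_init__(self) -> None:
        from .thermo import MECHANISMS

        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")
        if not all(isinstance(k, str) for k in self.fixed):
            raise ConfigError("fixed must map parameter names to numbers")
        self.fixed = {k: float(v) for k, v in self.fixed.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for logging."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# JSON summaries


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round_floats(x, sig) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(x, sig) for x in obj]
    return obj


def dump_json_summary(payload: dict, path) -> None:
    """Write a deterministic JSON summary (sorted keys, 12 significant digits).

    Identical inputs produce byte-identical files, so a summary is a
    reproducibility receipt for the run that made it.
    """
    body = {"schema_version": 1, **_round_floats(payload)}
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")
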