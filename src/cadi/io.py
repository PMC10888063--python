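"""CSV schemas, validated readers/writers and the run configuration.

All tabular interchange is UTF-8 CSV with a header row; dates are ISO-8601;
region identifiers are opaque strings matched exactly. Readers validate the
header against the declared schema, coerce dtypes, and report duplicate
keys and missing values with the offending CSV line numbers (header = line
1, first data row = line 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = ["SCHEMAS", "TableSchema", "read_table", "write_table", "RunConfig"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple          # (column, dtype) pairs; dtype in {str,int,float}
    key: tuple = ()         # columns forming the unique key, () = no key
    required: tuple = None  # columns that must be non-missing (default: all)

    @property
    def column_names(self) -> tuple:
        return tuple(c for c, _ in self.columns)


_COV = tuple((c, float) for c in
             ("DI", "CPI", "CGR", "IE", "ACP", "RHE", "RD", "RU", "gdp_pc"))

SCHEMAS: Mapping[str, TableSchema] = {s.name: s for s in [
    TableSchema("corpus",
                (("id", str), ("platform", str), ("date", str), ("text", str)),
                key=("id",)),
    TableSchema("trends",
                (("region", str), ("word", str), ("date", str),
                 ("value", float)),
                key=("region", "word", "date")),
    TableSchema("population",
                (("region", str), ("year", int), ("population", float)),
                key=("region", "year")),
    TableSchema("penetration",
                (("year", int), ("penetration", float)), key=("year",)),
    TableSchema("pod",
                (("word", str), ("alpha", float), ("frequency", int)),
                key=("word",)),
    TableSchema("covariates",
                (("region", str), ("year", int)) + _COV,
                key=("region", "year")),
    TableSchema("survey",
                (("region", str), ("weight", float), ("disorder", int))),
    TableSchema("cadi",
                (("region", str), ("year", int), ("cadi", float),
                 ("cadi_adjusted", float)),
                key=("region", "year"), required=("region", "year", "cadi")),
    TableSchema("severity",
                (("region", str), ("year", int), ("s", float)),
                key=("region", "year")),
]}


class SchemaError(ValueError):
    """Raised when a file does not match its declared table schema."""


def read_table(path, schema) -> pd.DataFrame:
    """Read and validate a CSV against a named or explicit schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{schema.name} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=[""], encoding="utf-8")

    expected = list(schema.column_names)
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"{path}: header mismatch for table '{schema.name}': expected "
            f"columns {expected}, found {list(df.columns)} "
            f"(missing {missing_cols})")
    df = df[expected]

    required = schema.required if schema.required is not None else expected
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: missing values in required column '{col}' "
                f"at line(s) {lines}")

    for col, dtype in schema.columns:
        if dtype is str:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: non-numeric values in column '{col}' at "
                f"line(s) {lines}")
        df[col] = coerced.astype(float if dtype is float else "Int64"
                                 if coerced.isna().any() else dtype)

    if schema.key:
        dup = df.duplicated(list(schema.key), keep=False)
        if dup.any():
            first = df.loc[dup, list(schema.key)].iloc[0].tolist()
            lines = [int(i) + 2 for i in df.index[dup][:5]]
            raise SchemaError(
                f"{path}: duplicated key {tuple(schema.key)} = "
                f"{tuple(first)} at line(s) {lines}")
    return df


def write_table(df: pd.DataFrame, path, schema=None) -> None:
    """Write a CSV in schema column order (full float precision)."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    out = df
    if schema is not None:
        cols = [c for c in schema.column_names if c in df.columns]
        out = df[cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, encoding="utf-8")


@dataclass
class RunConfig:
    """Configuration for the umbrella pipeline.

    Paths are optional: stages whose inputs are absent are generated
    synthetically (scenario section) or skipped. See docs/example_config.yaml
    for the on-disk layout; both JSON and YAML dialects are accepted.
    """

    out_dir: str = "cadi_output"
    seed: int = 0
    # inputs (None -> use the synthetic scenario)
    corpus: Optional[str] = None
    trends: Optional[str] = None
    population: Optional[str] = None
    penetration: Optional[str] = None
    covariates: Optional[str] = None
    survey: Optional[str] = None
    # index parameters
    tau: float = 40.0
    # dictionary parameters
    min_chars: int = 15
    min_char_len: int = 2
    min_frequency: int = 5
    embedding_dim: int = 100
    embedding_window: int = 5
    embedding_epochs: int = 20
    stopwords: Sequence[str] = ()
    alpha_threshold: Optional[float] = None
    top_k: Optional[int] = None
    # analysis parameters
    quantile: float = 0.5
    n_boot: int = 500
    survey_year: int = 2020
    subgroups: bool = True
    # synthetic scenario overrides (see synthetic.ScenarioConfig)
    scenario: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0.0 < self.tau <= 100.0:
            raise ValueError(f"tau must lie in (0, 100], got {self.tau}")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(
                f"quantile must lie in (0, 1), got {self.quantile}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(**data)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"config is missing required path(s): {missing}")
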