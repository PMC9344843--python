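"""Dataset container, delimited-table loading and model persistence.

The in-memory container is a thin wrapper over a numeric ``pandas.DataFrame``
with one designated target column -- the shape shared by all wide omics
tables this package targets (samples x features, p often >> n).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expr_core import SCHEMA_VERSION, FittedModel

__all__ = ["Dataset", "load_table", "save_models", "load_models", "sanitize_name"]

logger = logging.getLogger("sromics")


def sanitize_name(name: str) -> str:
    """Map non-alphanumeric characters to underscores for display/column use."""
    return re.sub(r"[^0-9A-Za-z_.]", "_", name.strip())


@dataclass
class Dataset:
    """A samples x features numeric table with a designated target column."""

    frame: pd.DataFrame
    target: str
    provenance: str = ""
    original_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cols = list(self.frame.columns)
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        if dupes:
            raise ValidationError(f"duplicate column names: {', '.join(map(str, dupes))}")
        if self.target not in cols:
            raise ValidationError(f"target column {self.target!r} not found")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("all dataset columns must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValidationError("dataset contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.target]

    @property
    def n_features(self) -> int:
        return len(self.frame.columns) - 1

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.target].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise ValidationError(f"missing feature column {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def subset(self, rows: Sequence[int]) -> "Dataset":
        return Dataset(
            frame=self.frame.iloc[list(rows)].reset_index(drop=True),
            target=self.target,
            provenance=self.provenance,
            original_names=dict(self.original_names),
        )

    def drop_features(self, names: Sequence[str]) -> "Dataset":
        return Dataset(
            frame=self.frame.drop(columns=list(names)),
            target=self.target,
            provenance=self.provenance,
            original_names=dict(self.original_names),
        )

    def shape_str(self) -> str:
        return f"{self.n_samples} samples x {self.n_features} features"


def _sniff_delimiter(first_line: str) -> str:
    try:
        return csv.Sniffer().sniff(first_line, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_table(path: str | Path, target: str, delimiter: str | None = None) -> Dataset:
    """Load a delimited text table (CSV/TSV, header row) into a Dataset.

    Rows with missing values are dropped (count logged).  Column names are
    sanitised for display; original headers are preserved in
    ``Dataset.original_names`` keyed by the sanitised name.
    """
    path = Path(path)
    with open(path, "r", newline="") as fh:
        first_line = fh.readline().rstrip("\r\n")
    if not first_line:
        raise ValidationError(f"{path} is empty")
    sep = delimiter or _sniff_delimiter(first_line)
    raw_names = next(csv.reader([first_line], delimiter=sep))
    dupes = sorted({n for n in raw_names if raw_names.count(n) > 1})
    if dupes:
        raise ValidationError(f"duplicate header names: {', '.join(dupes)}")

    df = pd.read_csv(path, sep=sep)
    original: dict[str, str] = {}
    renames: dict[str, str] = {}
    for name in df.columns:
        clean = sanitize_name(str(name))
        if clean != name:
            renames[name] = clean
        original[clean] = str(name)
    if renames:
        df = df.rename(columns=renames)
    clean_target = sanitize_name(target)
    if clean_target not in df.columns:
        raise ValidationError(f"target column {target!r} not found in {path}")

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().all() and not df[col].isna().all():
            raise ValidationError(f"column {original.get(col, col)!r} is non-numeric")
        df[col] = coerced
    n_before = len(df)
    df = df.dropna(axis=0).reset_index(drop=True)
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d row(s) with missing values from %s", dropped, path)
    if len(df) == 0:
        raise ValidationError(f"no usable rows in {path} after dropping missing values")
    return Dataset(
        frame=df.astype(float),
        target=clean_target,
        provenance=str(path),
        original_names=original,
    )


def save_models(models: Sequence[FittedModel], path: str | Path) -> None:
    """Write a ranked model list as a JSON document (bit-exact parameters)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "models": [m.to_dict() for m in models],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_models(path: str | Path) -> list[FittedModel]:
    doc = json.loads(Path(path).read_text())
    found = doc.get("schema_version")
    if found != SCHEMA_VERSION:
        raise ValidationError(
            f"model file schema mismatch: expected {SCHEMA_VERSION!r}, found {found!r}"
        )
    return [FittedModel.from_dict(d) for d in doc["models"]]
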