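"""Tabular I/O for the diabetes-screening schema.

The canonical layout is the Pima-Indians-Diabetes table: eight continuous
physiological measurements followed by a binary outcome column (1 =
diabetic, 0 = control).  Several of the measurement columns use a literal
``0`` as a sentinel for "not measured" — a serum insulin of zero is not a
physiological value — so masking zeros as missing is provided as an
explicit, separate step rather than being baked into the reader.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PIMA_FEATURES",
    "PIMA_LABEL",
    "DEFAULT_MISSING_COLUMNS",
    "FeatureTable",
    "SummaryStats",
    "load_feature_table",
    "write_feature_table",
    "mask_zeros_as_missing",
    "summarize",
]

#: Canonical feature order: pregnancy count, 2-h plasma glucose (mg/dL),
#: diastolic blood pressure (mm Hg), triceps skinfold (mm), 2-h serum
#: insulin (uU/mL), body-mass index (kg/m^2), diabetes pedigree function
#: (dimensionless), age (years).
PIMA_FEATURES: tuple[str, ...] = (
    "pregnancies",
    "glucose",
    "blood_pressure",
    "skin_thickness",
    "insulin",
    "bmi",
    "pedigree",
    "age",
)

PIMA_LABEL = "outcome"

#: Columns where a zero entry encodes a missing measurement.  A pregnancy
#: count of zero is a perfectly valid value and is deliberately excluded.
DEFAULT_MISSING_COLUMNS: tuple[str, ...] = (
    "glucose",
    "blood_pressure",
    "skin_thickness",
    "insulin",
    "bmi",
)


@dataclass(frozen=True)
class FeatureTable:
    """Records-by-features matrix with a missingness mask and binary labels.

    Parameters
    ----------
    values : (m, n) float array
        The measurements.  Masked cells keep their raw (sentinel) value;
        imputation never happens here.
    feature_names : tuple of str
        Unique column names, length n.
    missing_mask : (m, n) bool array
        True where a cell is considered missing.
    labels : (m,) int array or None
        Binary outcomes, 1 = diabetic, 0 = control.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        object.__setattr__(self, "values", values)
        names = tuple(self.feature_names)
        if len(names) != values.shape[1]:
            raise ValueError(
                f"{len(names)} feature names for {values.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "feature_names", names)
        mask = self.missing_mask
        if mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("missing_mask shape must match values shape")
        object.__setattr__(self, "missing_mask", mask)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (values.shape[0],):
                raise ValueError("labels must have one entry per record")
            if not np.isin(labels, (0, 1)).all():
                raise ValueError("labels must be binary (0/1)")
            object.__setattr__(self, "labels", labels.astype(int))

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown column {name!r}") from None

    def take(self, rows: np.ndarray) -> "FeatureTable":
        """Row subset (used for train/test splits and cluster submatrices)."""
        return FeatureTable(
            self.values[rows],
            self.feature_names,
            self.missing_mask[rows],
            None if self.labels is None else self.labels[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        if self.labels is not None:
            frame[PIMA_LABEL] = self.labels
        return frame


@dataclass(frozen=True)
class SummaryStats:
    """Per-column observed-cell moments plus class and missingness counts."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray  # NaN marks "undefined" (< 2 observed cells)
    class_counts: dict[int, int]
    missing_counts: np.ndarray
    n_records: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.means,
                "sd": self.sds,
                "n_missing": self.missing_counts,
            },
            index=list(self.feature_names),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="feature")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_records": self.n_records,
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
            "features": {
                name: {
                    "mean": self.means[j],
                    "sd": None if math.isnan(self.sds[j]) else self.sds[j],
                    "n_missing": int(self.missing_counts[j]),
                }
                for j, name in enumerate(self.feature_names)
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _parse_row(row: Sequence[str], row_number: int, n_fields: int) -> list[float]:
    if len(row) != n_fields:
        raise ValueError(
            f"row {row_number}: expected {n_fields} fields, got {len(row)}"
        )
    out = []
    for k, cell in enumerate(row):
        try:
            out.append(float(cell))
        except ValueError:
            raise ValueError(
                f"row {row_number}, field {k + 1}: non-numeric value {cell!r}"
            ) from None
    return out


def _looks_numeric(row: Sequence[str]) -> bool:
    for cell in row:
        try:
            float(cell)
        except ValueError:
            return False
    return True


def load_feature_table(
    path: str | Path,
    feature_names: Sequence[str] = PIMA_FEATURES,
    label_name: str | None = PIMA_LABEL,
) -> FeatureTable:
    """Read a CSV file in the canonical schema.

    The file holds one record per row: the features in ``feature_names``
    order, then (if ``label_name`` is given) the binary outcome.  An
    optional header row is detected by its first row being non-numeric.
    The returned mask is all-false; zeros-as-missing masking is applied
    separately by :func:`mask_zeros_as_missing`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_fields = len(feature_names) + (1 if label_name is not None else 0)
    rows: list[list[float]] = []
    labels: list[int] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle)
        for lineno, raw in enumerate(reader, start=1):
            if not raw or all(not cell.strip() for cell in raw):
                continue
            if lineno == 1 and not _looks_numeric(raw):
                continue  # header row
            parsed = _parse_row(raw, lineno, n_fields)
            if label_name is not None:
                label = parsed.pop()
                if label not in (0.0, 1.0):
                    raise ValueError(
                        f"row {lineno}: label must be 0 or 1, got {label}"
                    )
                labels.append(int(label))
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no records")
    values = np.array(rows, dtype=float)
    return FeatureTable(
        values,
        tuple(feature_names),
        None,
        np.array(labels, dtype=int) if label_name is not None else None,
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, header: bool = True
) -> None:
    """Write the canonical CSV (features then label).

    Uses :func:`repr` formatting for floats so that a write→load round
    trip is bit-identical for finite values.
    """
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        if header:
            names = list(table.feature_names)
            if table.labels is not None:
                names.append(PIMA_LABEL)
            writer.writerow(names)
        for i in range(table.m):
            row = [repr(float(v)) for v in table.values[i]]
            if table.labels is not None:
                row.append(str(int(table.labels[i])))
            writer.writerow(row)


def mask_zeros_as_missing(
    table: FeatureTable,
    columns: Iterable[str] = DEFAULT_MISSING_COLUMNS,
) -> FeatureTable:
    """Mark zero entries of the designated columns as missing.

    Values are left untouched; only the mask changes, so the operation is
    idempotent.
    """
    mask = table.missing_mask.copy()
    for name in columns:
        j = table.column_index(name)
        mask[:, j] |= table.values[:, j] == 0
    return replace(table, missing_mask=mask)


def summarize(table: FeatureTable) -> SummaryStats:
    """Observed-cell mean and sample SD per column, plus count summaries.

    Columns with fewer than two observed cells get an undefined (NaN) SD.
    """
    if table.m < 2:
        raise ValueError("need at least 2 records to summarize")
    means = np.empty(table.n)
    sds = np.empty(table.n)
    observed = ~table.missing_mask
    for j in range(table.n):
        col = table.values[observed[:, j], j]
        if col.size == 0:
            means[j] = np.nan
            sds[j] = np.nan
        elif col.size == 1:
            means[j] = col[0]
            sds[j] = np.nan
        else:
            means[j] = col.mean()
            sds[j] = col.std(ddof=1)
    if table.labels is None:
        class_counts: dict[int, int] = {}
    else:
        uniq, counts = np.unique(table.labels, return_counts=True)
        class_counts = {int(u): int(c) for u, c in zip(uniq, counts)}
    return SummaryStats(
        feature_names=table.feature_names,
        means=means,
        sds=sds,
        class_counts=class_counts,
        missing_counts=table.missing_mask.sum(axis=0),
        n_records=table.m,
    )
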