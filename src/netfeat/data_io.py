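"""Tabular input/output for expression matrices and phenotype tables.

All files are tab-separated UTF-8 with '.' decimals. An expression matrix
has gene ids in the first column and patient ids in the header row; a
phenotype table has columns ``patient_id``, ``outcome``, ``cohort`` with
outcome spelled ``good``/``poor`` (case-insensitive). Gene ids are opaque
strings; no probe-id parsing is attempted.

Inputs are assumed already log-normalized and mean-centered upstream; this
module validates but never transforms values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_POOR = 1
OUTCOME_GOOD = 0

_OUTCOME_CODES = {"good": OUTCOME_GOOD, "poor": OUTCOME_POOR}


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, missing labels...)."""


class ParseError(ValueError):
    """A file cell could not be parsed; the message carries coordinates."""


@dataclass
class ExpressionDataset:
    """A genes x patients log-expression matrix with optional outcome labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with patient ids as columns. All
        entries must be finite floats (unitless log-scale expression).
    outcome
        Per-patient binary label aligned to ``values.columns``
        (poor = 1, good = 0), or None before phenotype joining.
    cohort
        Per-patient cohort id aligned to ``values.columns``, or None.
    """

    values: pd.DataFrame
    outcome: Optional[pd.Series] = None
    cohort: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        for name, labels in (("gene", idx), ("patient", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise ValidationError(
                    f"duplicate {name} id(s): {sorted(set(map(str, dup)))}"
                )
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if arr.size and not np.all(np.isfinite(arr)):
            g, p = map(int, np.argwhere(~np.isfinite(arr))[0])
            raise ValidationError(
                f"non-finite expression value at gene {idx[g]!r}, patient {cols[p]!r}; "
                "missing values must be resolved upstream"
            )
        for name, series in (("outcome", self.outcome), ("cohort", self.cohort)):
            if series is not None and not series.index.equals(cols):
                raise ValidationError(f"{name} is not aligned with patient ids")

    # -- accessors ----------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def has_labels(self) -> bool:
        return self.outcome is not None and self.cohort is not None

    def subset_patients(self, patient_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given patients, preserving the requested order."""
        missing = [p for p in patient_ids if p not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown patient id(s): {missing}")
        return ExpressionDataset(
            values=self.values.loc[:, list(patient_ids)],
            outcome=None if self.outcome is None else self.outcome.loc[list(patient_ids)],
            cohort=None if self.cohort is None else self.cohort.loc[list(patient_ids)],
        )

    def cohorts(self) -> dict[str, "ExpressionDataset"]:
        """Split into per-cohort datasets (requires joined phenotype)."""
        if self.cohort is None:
            raise ValidationError("cohort labels not joined")
        out = {}
        for name in pd.unique(self.cohort):
            ids = list(self.cohort.index[self.cohort == name])
            out[str(name)] = self.subset_patients(ids)
        return out


def check_centering(dataset: ExpressionDataset, tolerance: float = 0.05) -> float:
    """Warn (never error) if the global mean deviates from 0 beyond tolerance.

    Returns the global mean so callers can log it.
    """
    mean = float(dataset.values.to_numpy().mean()) if dataset.values.size else 0.0
    if abs(mean) > tolerance:
        warnings.warn(
            f"global expression mean {mean:.4g} deviates from 0 by more than "
            f"{tolerance}; inputs are expected to be mean-centered upstream",
            UserWarning,
            stacklevel=2,
        )
    return mean


# -- expression matrix ------------------------------------------------------


def read_expression(path: str | Path, centering_tolerance: float = 0.05) -> ExpressionDataset:
    """Read a genes x patients TSV (first column gene ids, header patients).

    Row and column order are preserved from the file. Duplicate ids raise
    :class:`ValidationError`; a non-numeric cell raises :class:`ParseError`
    naming the offending gene row and patient column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, p = map(int, np.argwhere(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric cell {raw.iat[g, p]!r} at gene {raw.index[g]!r} "
            f"(row {g + 2}), patient {raw.columns[p]!r} (column {p + 2}) in {path}"
        )
    dataset = ExpressionDataset(values=numeric.astype(float))
    check_centering(dataset, centering_tolerance)
    return dataset


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the value matrix as TSV with a ``gene_id`` first column."""
    out = dataset.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# -- phenotype table --------------------------------------------------------


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns patient_id, outcome, cohort.

    Outcome is normalized to lower case and must be 'good' or 'poor';
    each patient may appear only once.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "outcome", "cohort"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"phenotype table missing column(s): {sorted(missing)}")
    table = table.loc[:, ["patient_id", "outcome", "cohort"]].copy()
    table["outcome"] = table["outcome"].str.strip().str.lower()
    bad = sorted(set(table["outcome"]) - set(_OUTCOME_CODES))
    if bad:
        raise ValidationError(f"outcome labels must be good/poor, found: {bad}")
    dup = table["patient_id"][table["patient_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate patient id(s) in phenotype: {sorted(set(dup))}")
    return table


def write_phenotype(dataset: ExpressionDataset, path: str | Path) -> None:
    if not dataset.has_labels():
        raise ValidationError("dataset has no phenotype to write")
    inv = {v: k for k, v in _OUTCOME_CODES.items()}
    pd.DataFrame(
        {
            "patient_id": dataset.patient_ids,
            "outcome": [inv[int(o)] for o in dataset.outcome],
            "cohort": list(dataset.cohort),
        }
    ).to_csv(path, sep="\t", index=False)


def join_phenotype(dataset: ExpressionDataset, phenotype: pd.DataFrame) -> ExpressionDataset:
    """Attach outcome and cohort labels to a dataset, aligned by patient id.

    Every matrix patient must appear in the phenotype table; phenotype rows
    for patients absent from the matrix are ignored (their count is logged).
    Alignment is by id, so phenotype row order is irrelevant.
    """
    table = phenotype.set_index("patient_id")
    matrix_patients = pd.Index(dataset.patient_ids)
    missing = [p for p in matrix_patients if p not in table.index]
    if missing:
        raise ValidationError(f"patient(s) missing from phenotype table: {missing}")
    extra = len(table.index.difference(matrix_patients))
    if extra:
        logger.info("ignoring %d phenotype rows for patients not in the matrix", extra)
    aligned = table.loc[matrix_patients]
    outcome = aligned["outcome"].str.strip().str.lower().map(_OUTCOME_CODES)
    if outcome.isna().any():
        bad = sorted(set(aligned["outcome"][outcome.isna()]))
        raise ValidationError(f"outcome labels must be good/poor, found: {bad}")
    return ExpressionDataset(
        values=dataset.values,
        outcome=outcome.astype(np.int8).rename("outcome"),
        cohort=aligned["cohort"].astype(str).rename("cohort"),
    )


__all__ = [
    "ExpressionDataset",
    "ValidationError",
    "ParseError",
    "OUTCOME_POOR",
    "OUTCOME_GOOD",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "join_phenotype",
    "check_centering",
]
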