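"""Trial data container and delimited-text I/O.

``TrialData`` holds one row per participant: an arm label, and the numeric
joint vector (covariates, repeated effectiveness measures, repeated or single
total costs) with missing values encoded as NaN.  The missingness mask is
derived from NaN: mask true ⇔ value absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import DataValidationError, SchemaError, VariableSchema

#: Missing-value spellings accepted on input (Stata-dialect "." included).
NA_VALUES = ["", "NA", ".", "NaN", "nan"]


@dataclass
class TrialData:
    """Wide-format participant-level data for a two-endpoint trial.

    Attributes
    ----------
    ids : ndarray
        Participant identifiers (row order preserved from the source file).
    arms : ndarray of str
        Arm label per participant; exactly two distinct labels.
    values : ndarray, shape (n, schema.dim)
        Numeric matrix in joint-vector order; NaN marks a missing cell.
    schema : VariableSchema
    """

    ids: np.ndarray
    arms: np.ndarray
    values: np.ndarray
    schema: VariableSchema

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.arms = np.asarray(self.arms, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.arms.shape != (n,) or self.values.shape != (n, self.schema.dim):
            raise DataValidationError("ids, arms and values have inconsistent shapes")
        labels = self.arm_labels
        if len(labels) != 2:
            raise DataValidationError(
                f"expected exactly two arm labels, found {list(labels)}"
            )
        ref = self.schema.reference_arm
        if ref is not None and ref not in labels:
            raise DataValidationError(
                f"reference arm {ref!r} not among arm labels {list(labels)}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness mask; true ⇔ value absent."""
        return np.isnan(self.values)

    @property
    def arm_labels(self) -> tuple:
        """Distinct arm labels, reference arm (if declared) first."""
        labels = sorted(set(self.arms))
        ref = self.schema.reference_arm
        if ref is not None and ref in labels:
            labels.remove(ref)
            labels.insert(0, ref)
        return tuple(labels)

    def arm_rows(self, arm) -> np.ndarray:
        return np.flatnonzero(self.arms == arm)

    def copy(self) -> "TrialData":
        return TrialData(self.ids.copy(), self.arms.copy(), self.values.copy(), self.schema)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.columns))
        df.insert(0, self.schema.arm, self.arms)
        id_col = self.schema.id_col or "id"
        df.insert(0, id_col, self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schema: VariableSchema) -> "TrialData":
        missing_cols = [c for c in (schema.arm, *schema.columns) if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"columns named in schema absent from data: {missing_cols}")
        arms = df[schema.arm]
        if arms.isna().any():
            bad = df.index[arms.isna()][0]
            raise DataValidationError(f"missing arm label at row {bad}")
        values = np.empty((len(df), schema.dim))
        for j, col in enumerate(schema.columns):
            try:
                values[:, j] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()][0]
                raise DataValidationError(
                    f"non-numeric value {df[col].loc[bad]!r} in column {col!r}, row {bad}"
                ) from None
        if schema.id_col is not None:
            if schema.id_col not in df.columns:
                raise SchemaError(f"id column {schema.id_col!r} absent from data")
            ids = df[schema.id_col].to_numpy()
        else:
            ids = np.arange(len(df))
        return cls(ids, arms.astype(str).to_numpy(), values, schema)


def read_trial(path, schema: VariableSchema) -> TrialData:
    """Read a wide-format CSV into :class:`TrialData`.

    Empty cells, ``NA`` and ``.`` are treated as missing. Row order is
    preserved. Raises :class:`SchemaError` if a schema column is absent and
    :class:`DataValidationError` for non-numeric outcome cells (naming the
    row and column) or missing arm labels.
    """
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False, skipinitialspace=True)
    return TrialData.from_frame(df, schema)


def write_trial(data: TrialData, path) -> None:
    """Write :class:`TrialData` back to CSV (missing cells left empty)."""
    data.to_frame().to_csv(path, index=False, na_rep="")


def impute_baseline_mean(data: TrialData, variable: str) -> TrialData:
    """Replace missing entries of a baseline variable by its observed mean.

    Mirrors the common practice of mean-imputing an isolated missing
    baseline measurement so that covariates are fully observed before the
    multivariate-normal model is fitted. All other cells are unchanged.
    """
    cols = data.schema.columns
    if variable not in cols:
        raise SchemaError(f"unknown variable {variable!r}")
    j = cols.index(variable)
    out = data.copy()
    col = out.values[:, j]
    miss = np.isnan(col)
    if miss.all():
        raise DataValidationError(f"variable {variable!r} has no observed values")
    if miss.any():
        col[miss] = col[~miss].mean()
    return out
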