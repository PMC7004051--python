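"""Missingness-pattern classification.

Each missing outcome cell is classified, within its endpoint, as either

* dropout-missing — every later measurement of the same endpoint is also
  missing (monotone tail), or
* interim-missing — the measurement is missing but the endpoint is observed
  again at a later time point.

The distinction matters because MNAR pattern-mixture assumptions are
typically framed for dropout, while interim gaps are often more plausibly
missing at random.  Classification depends only on the missingness mask,
never on the values, and is tracked per endpoint: cost and quality-of-life
patterns may differ for the same participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialData
from .schema import COST, EFFECT, DataValidationError, VariableSchema

OBSERVED_MARK = "✓"
MISSING_MARK = "✘"


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant classification of missing outcome cells.

    ``dropout_index`` maps endpoint name to the index (within the endpoint's
    own time ordering) of the last observed measurement, or ``-1`` when the
    endpoint was never observed.  ``dropout_missing`` and ``interim_missing``
    hold joint-vector column indices; they are disjoint and together cover
    every missing outcome cell.
    """

    dropout_index: dict
    dropout_missing: frozenset
    interim_missing: frozenset

    @property
    def missing(self) -> frozenset:
        return self.dropout_missing | self.interim_missing

    @property
    def is_complete(self) -> bool:
        return not self.missing


@dataclass
class MissingnessProfile:
    """Classification for every participant plus the pattern-frequency table."""

    participants: list
    pattern_table: pd.DataFrame
    schema: VariableSchema = field(repr=False)

    def __getitem__(self, i: int) -> ParticipantProfile:
        return self.participants[i]

    def __len__(self) -> int:
        return len(self.participants)


def _classify_row(mask_row: np.ndarray, schema: VariableSchema) -> ParticipantProfile:
    dropout_index: dict = {}
    drop: set = set()
    interim: set = set()
    for endpoint in (EFFECT, COST):
        idx = schema.endpoint_indices(endpoint)
        m = mask_row[list(idx)]
        observed = np.flatnonzero(~m)
        dropout_index[endpoint] = int(observed[-1]) if observed.size else -1
        for local_j in np.flatnonzero(m):
            if m[local_j:].all():  # all later same-endpoint times missing too
                drop.add(idx[local_j])
            else:
                interim.add(idx[local_j])
    return ParticipantProfile(dropout_index, frozenset(drop), frozenset(interim))


def _signature(mask_row: np.ndarray, schema: VariableSchema) -> str:
    marks = [
        MISSING_MARK if mask_row[j] else OBSERVED_MARK for j in schema.outcome_indices
    ]
    return "".join(marks)


def classify_missingness(data: TrialData, schema: VariableSchema | None = None) -> MissingnessProfile:
    """Classify every missing outcome cell and tabulate pattern frequencies.

    Returns a :class:`MissingnessProfile` whose ``pattern_table`` counts
    participants per observed/missing signature (one ✓/✘ mark per outcome
    column in joint order), per arm and in total.  Complete data yield empty
    dropout/interim sets for every participant.
    """
    schema = schema or data.schema
    mask = data.mask
    participants = [_classify_row(mask[i], schema) for i in range(data.n)]
    signatures = [_signature(mask[i], schema) for i in range(data.n)]
    table = pd.DataFrame({"pattern": signatures, "arm": data.arms})
    counts = (
        table.groupby(["pattern", "arm"]).size().unstack(fill_value=0).astype(int)
    )
    counts.columns = [str(c) for c in counts.columns]
    counts["total"] = counts.sum(axis=1)
    counts = counts.sort_values("total", ascending=False)
    return MissingnessProfile(participants, counts, schema)


def pattern_percentages(pattern_table: pd.DataFrame) -> pd.DataFrame:
    """Append one-decimal percentage columns to a pattern-count table.

    Percentages are 100·count/N per arm and overall, where N is the column
    total, so they sum to 100 up to rounding.
    """
    out = pattern_table.copy()
    for col in list(pattern_table.columns):
        n = pattern_table[col].sum()
        if n == 0:
            raise DataValidationError(f"pattern table column {col!r} has zero total")
        out[f"{col}_pct"] = (100.0 * pattern_table[col] / n).round(1)
    return out
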