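"""Variable schema for joint cost/effectiveness trial data.

The imputation model works on a fixed-order joint vector per participant:

    [covariates | effectiveness by time | costs by time]

All covariance partitions in the package index into this order.  The two
endpoints (effectiveness, e.g. EQ-5D utility scores, and costs) may have
different numbers of assessment times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


class SchemaError(ValueError):
    """A schema is internally inconsistent or does not match the data."""


class DataValidationError(ValueError):
    """Participant-level data violate a schema contract."""


EFFECT = "effect"
COST = "cost"


@dataclass(frozen=True)
class VariableSchema:
    """Column naming and ordering contract for a two-endpoint trial.

    Parameters
    ----------
    effect_vars, effect_times
        Effectiveness (quality-of-life) column names and their assessment
        times in years, e.g. ``("qol_0", "qol_6", "qol_12")`` at
        ``(0.0, 0.5, 1.0)``. Times must be strictly increasing.
    cost_vars, cost_times
        Cost column names and times. A single total-cost variable is treated
        as one "time point" at its stated assessment time.
    covariates
        Fully observed baseline columns prepended to the joint vector.
    arm
        Name of the treatment-arm column (two distinct labels expected).
    reference_arm
        Arm label used as the reference for J2R/CIR; must be one of the
        observed labels.
    id_col
        Optional participant-identifier column; if absent, row order is the
        identifier.
    """

    effect_vars: tuple[str, ...]
    effect_times: tuple[float, ...]
    cost_vars: tuple[str, ...]
    cost_times: tuple[float, ...]
    covariates: tuple[str, ...] = ()
    arm: str = "arm"
    reference_arm: str | None = None
    id_col: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_vars", tuple(self.effect_vars))
        object.__setattr__(self, "effect_times", tuple(float(t) for t in self.effect_times))
        object.__setattr__(self, "cost_vars", tuple(self.cost_vars))
        object.__setattr__(self, "cost_times", tuple(float(t) for t in self.cost_times))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if len(self.effect_vars) != len(self.effect_times):
            raise SchemaError("effect_vars and effect_times differ in length")
        if len(self.cost_vars) != len(self.cost_times):
            raise SchemaError("cost_vars and cost_times differ in length")
        if not self.effect_vars:
            raise SchemaError("at least one effectiveness variable is required")
        if not self.cost_vars:
            raise SchemaError("at least one cost variable is required")
        for times, label in ((self.effect_times, EFFECT), (self.cost_times, COST)):
            if any(b <= a for a, b in zip(times, times[1:])):
                raise SchemaError(f"{label} assessment times must be strictly increasing")
        names = list(self.covariates) + list(self.effect_vars) + list(self.cost_vars)
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if self.arm in names:
            raise SchemaError("arm column cannot also be an outcome/covariate")

    # ---- index bookkeeping over the joint vector ------------------------

    @property
    def columns(self) -> tuple[str, ...]:
        """All numeric columns in joint-vector order."""
        return self.covariates + self.effect_vars + self.cost_vars

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def dim(self) -> int:
        return len(self.columns)

    @property
    def outcome_dim(self) -> int:
        """J* = Je + Jc."""
        return len(self.effect_vars) + len(self.cost_vars)

    @property
    def effect_indices(self) -> tuple[int, ...]:
        k = self.n_covariates
        return tuple(range(k, k + len(self.effect_vars)))

    @property
    def cost_indices(self) -> tuple[int, ...]:
        k = self.n_covariates + len(self.effect_vars)
        return tuple(range(k, k + len(self.cost_vars)))

    @property
    def outcome_indices(self) -> tuple[int, ...]:
        return self.effect_indices + self.cost_indices

    def endpoint_indices(self, endpoint: str) -> tuple[int, ...]:
        if endpoint == EFFECT:
            return self.effect_indices
        if endpoint == COST:
            return self.cost_indices
        raise SchemaError(f"unknown endpoint {endpoint!r}")

    def endpoint_times(self, endpoint: str) -> tuple[float, ...]:
        if endpoint == EFFECT:
            return self.effect_times
        if endpoint == COST:
            return self.cost_times
        raise SchemaError(f"unknown endpoint {endpoint!r}")

    def endpoint_of(self, joint_index: int) -> str:
        """Endpoint name for an outcome column of the joint vector."""
        if joint_index in self.effect_indices:
            return EFFECT
        if joint_index in self.cost_indices:
            return COST
        raise SchemaError(f"index {joint_index} is not an outcome column")

    def has_baseline(self, endpoint: str) -> bool:
        """Whether the endpoint includes a measurement at time zero."""
        times = self.endpoint_times(endpoint)
        return bool(times) and times[0] == 0.0

    # ---- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "effect_vars": list(self.effect_vars),
            "effect_times": list(self.effect_times),
            "cost_vars": list(self.cost_vars),
            "cost_times": list(self.cost_times),
            "covariates": list(self.covariates),
            "arm": self.arm,
            "reference_arm": self.reference_arm,
            "id_col": self.id_col,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "VariableSchema":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise SchemaError(f"schema file {path} does not contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
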