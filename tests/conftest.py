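"""Shared fixtures: small schemas, toy trials, and one full-size suite run."""

from __future__ import annotations

import time

import numpy as np
import pytest
from hypothesis import settings

import rbcea as rb

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_schema() -> rb.VariableSchema:
    """Three quality-of-life times plus one total cost, no extra covariates."""
    return rb.VariableSchema(
        effect_vars=("qol_0", "qol_6", "qol_12"),
        effect_times=(0.0, 0.5, 1.0),
        cost_vars=("cost_total",),
        cost_times=(1.0,),
        arm="arm",
        reference_arm="control",
    )


def make_complete_trial(schema: rb.VariableSchema, n_per_arm: int = 30, seed: int = 0,
                        labels=("control", "active")) -> rb.TrialData:
    rng = np.random.default_rng(seed)
    rows, arms = [], []
    base = {labels[0]: np.array([0.5, 0.55, 0.56, 800.0]),
            labels[1]: np.array([0.55, 0.66, 0.64, 1800.0])}
    cov = np.diag([0.09, 0.1, 0.12, 500.0**2])
    cov[:3, :3] += 0.04  # positive utility tracking over time
    for lab in labels:
        rows.append(rng.multivariate_normal(base[lab], cov, size=n_per_arm))
        arms.extend([lab] * n_per_arm)
    values = np.vstack(rows)
    return rb.TrialData(np.arange(len(arms)), np.array(arms, dtype=object), values, schema)


@pytest.fixture()
def complete_trial(toy_schema) -> rb.TrialData:
    return make_complete_trial(toy_schema, n_per_arm=30, seed=3)


def random_pd(rng: np.random.Generator, d: int, scale: float = 1.0) -> np.ndarray:
    a = rng.standard_normal((d, d + 2))
    return scale * (a @ a.T / (d + 2) + 0.05 * np.eye(d))


@pytest.fixture(scope="session")
def preset_suite():
    """One full-size sensitivity-suite run on the calibrated preset.

    m=100 imputations with the default sampler settings, shared across the
    end-to-end, directional-sensitivity and variance-anchoring checks.
    """
    config = rb.cobalt_preset()
    masked, truth = rb.generate_trial(config, seed=11)
    t0 = time.time()
    results = rb.run_sensitivity_suite(
        masked, scenarios=list(rb.SCENARIOS), seed=23
    )
    elapsed = time.time() - t0
    return {"config": config, "data": masked, "truth": truth,
            "results": results, "elapsed": elapsed}
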