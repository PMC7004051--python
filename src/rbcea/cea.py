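"""Cost-effectiveness analysis of multiply-imputed trial data.

Per completed copy: QALYs by the trapezoidal area-under-the-curve of the
utility scores, arm differences in QALYs and costs from the
seemingly-unrelated-regressions system (with identical regressors this is
per-outcome OLS plus the residual cross-covariance), then Rubin's rules to
pool estimates and their 2×2 covariance across copies.  The pooled
quantities yield the ICER and, through the incremental-net-benefit normal
approximation, the cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialData
from .impute import ImputedDatasets, impute
from .posterior import SamplerSettings
from .reference import (
    INTERIM_DROPOUT,
    INTERIM_MAR,
    Assumption,
    EndpointAssumptions,
)
from .schema import DataValidationError, VariableSchema

#: Default willingness-to-pay grid: £0–50,000 per QALY in £500 steps.
DEFAULT_WTP_GRID = tuple(range(0, 50001, 500))
DEFAULT_WTP = 20000.0


def qaly_auc(qol, times) -> float:
    """Quality-adjusted life-years by trapezoidal area under the curve.

    Linear change in utility is assumed between assessment times (in
    years).  Requires a complete utility vector: QALYs are only computed on
    completed (post-imputation) copies.
    """
    qol = np.asarray(qol, dtype=float)
    times = np.asarray(times, dtype=float)
    if qol.shape != times.shape:
        raise ValueError("qol and times differ in length")
    if np.isnan(qol).any():
        raise DataValidationError("missing utility value; QALYs require completed data")
    return float(np.trapezoid(qol, times))


def participant_outcomes(dataset: TrialData, schema: VariableSchema | None = None):
    """Per-participant (QALY, total cost) from one completed copy."""
    schema = schema or dataset.schema
    e_idx = list(schema.effect_indices)
    if dataset.mask[:, e_idx + list(schema.cost_indices)].any():
        raise DataValidationError("dataset still contains missing outcome cells")
    times = np.asarray(schema.effect_times)
    qalys = np.trapezoid(dataset.values[:, e_idx], times, axis=1)
    costs = dataset.values[:, list(schema.cost_indices)].sum(axis=1)
    return qalys, costs


@dataclass(frozen=True)
class IncrementalEstimate:
    """Arm contrasts from one completed copy (treatment minus control)."""

    delta_e: float
    delta_c: float
    cov: np.ndarray  # 2×2 covariance of (delta_e, delta_c)
    arm_summary: dict  # arm → {name: (mean, var_of_mean)}


def estimate_incrementals(
    dataset: TrialData, schema: VariableSchema | None = None
) -> IncrementalEstimate:
    """Unadjusted between-arm differences in QALYs and costs.

    The point estimates are differences of arm means.  Their joint 2×2
    covariance comes from the seemingly-unrelated-regressions system for
    QALYs and costs on an intercept and the arm indicator; with identical
    regressors the coefficients coincide with per-outcome OLS, and

        cov(Δe, Δc) = (1/n₀ + 1/n₁) · σ̂_ec

    with σ̂_ec the residual cross-covariance (n − 2 denominator).
    """
    schema = schema or dataset.schema
    labels = dataset.arm_labels  # control/reference first
    if len(labels) != 2:
        raise DataValidationError("incremental estimation requires exactly two arms")
    qalys, costs = participant_outcomes(dataset, schema)
    control, treat = labels
    i0 = dataset.arm_rows(control)
    i1 = dataset.arm_rows(treat)
    n0, n1 = len(i0), len(i1)
    delta_e = qalys[i1].mean() - qalys[i0].mean()
    delta_c = costs[i1].mean() - costs[i0].mean()
    resid_e = np.concatenate([qalys[i0] - qalys[i0].mean(), qalys[i1] - qalys[i1].mean()])
    resid_c = np.concatenate([costs[i0] - costs[i0].mean(), costs[i1] - costs[i1].mean()])
    n = n0 + n1
    sigma = np.empty((2, 2))
    sigma[0, 0] = resid_e @ resid_e / (n - 2)
    sigma[1, 1] = resid_c @ resid_c / (n - 2)
    sigma[0, 1] = sigma[1, 0] = resid_e @ resid_c / (n - 2)
    cov = (1.0 / n0 + 1.0 / n1) * sigma

    summary: dict = {}
    for arm, rows in ((control, i0), (treat, i1)):
        entries = {}
        for name, j in zip(schema.effect_vars, schema.effect_indices):
            col = dataset.values[rows, j]
            entries[name] = (col.mean(), col.var(ddof=1) / len(rows))
        entries["qaly"] = (qalys[rows].mean(), qalys[rows].var(ddof=1) / len(rows))
        entries["cost"] = (costs[rows].mean(), costs[rows].var(ddof=1) / len(rows))
        summary[arm] = entries
    return IncrementalEstimate(float(delta_e), float(delta_c), cov, summary)


@dataclass(frozen=True)
class RubinPooled:
    """Rubin's-rules pooling of one scalar across m imputed copies.

    total = within + (1 + 1/m)·between; the degrees of freedom follow
    ν = (m−1)(1 + W/((1+1/m)B))², with the normal limit when B = 0.
    """

    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.total)


def rubin_pool(estimates, variances, alpha: float = 0.05) -> RubinPooled:
    """Pool m point estimates and their within-copy variances."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = q.size
    if m < 2:
        raise ValueError("Rubin's rules require at least 2 imputations")
    qbar = q.mean()
    w = u.mean()
    b = q.var(ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = math.inf
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    half = crit * math.sqrt(t)
    return RubinPooled(float(qbar), float(w), float(b), float(t), float(df),
                       float(qbar - half), float(qbar + half), m)


def rubin_pool_matrix(estimates, covariances):
    """Multivariate Rubin pooling: mean vector and W̄ + (1+1/m)B matrix."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(covariances, dtype=float)
    m, k = q.shape
    if m < 2 or u.shape != (m, k, k):
        raise ValueError("need m >= 2 aligned estimate vectors and covariance matrices")
    qbar = q.mean(axis=0)
    w = u.mean(axis=0)
    centred = q - qbar
    b = centred.T @ centred / (m - 1)
    return qbar, w + (1.0 + 1.0 / m) * b


def icer(delta_c: float, delta_e: float) -> float:
    """Incremental cost-effectiveness ratio Δc/Δe (currency per QALY).

    Undefined (NaN) when Δe = 0.  A negative value indicates a dominance
    quadrant (one arm cheaper and more effective, or dearer and less
    effective) and should be interpreted with the CEAC rather than alone.
    """
    if delta_e == 0:
        return math.nan
    return delta_c / delta_e


def ceac(delta_e, delta_c, cov, wtp_grid=DEFAULT_WTP_GRID) -> np.ndarray:
    """Probability cost-effective over a willingness-to-pay grid.

    For each λ the incremental net benefit is INB(λ) = λΔe − Δc with
    variance λ²v_e + v_c − 2λ·cov(Δe, Δc); the probability is the standard
    normal CDF of INB/√var(INB).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be the pooled 2x2 covariance of (delta_e, delta_c)")
    v_e, v_c, c = cov[0, 0], cov[1, 1], cov[0, 1]
    tol = 1e-12 * max(1.0, abs(v_e), abs(v_c))
    if v_e < -tol or v_c < -tol or v_e * v_c - c * c < -tol * max(1.0, v_e * v_c):
        raise ValueError("pooled covariance is not positive semi-definite")
    lam = np.asarray(wtp_grid, dtype=float)
    inb = lam * delta_e - delta_c
    var = np.maximum(lam**2 * v_e + v_c - 2.0 * lam * c, 0.0)
    probs = np.where(var > 0, stats.norm.cdf(inb / np.sqrt(np.where(var > 0, var, 1.0))),
                     np.where(inb > 0, 1.0, np.where(inb < 0, 0.0, 0.5)))
    return probs


@dataclass
class CeaResult:
    """Pooled cost-effectiveness summary for one missing-data scenario."""

    scenario: str
    assumptions: EndpointAssumptions
    arm_summary: dict  # arm → {name: RubinPooled}
    delta_qaly: RubinPooled
    delta_cost: RubinPooled
    pooled_cov: np.ndarray
    icer: float
    wtp_grid: tuple
    ceac: np.ndarray
    wtp: float
    prob_cost_effective: float
    m: int

    def row(self) -> dict:
        return {
            "scenario": self.scenario,
            "delta_qaly": self.delta_qaly.estimate,
            "delta_qaly_low": self.delta_qaly.ci_low,
            "delta_qaly_high": self.delta_qaly.ci_high,
            "delta_cost": self.delta_cost.estimate,
            "delta_cost_low": self.delta_cost.ci_low,
            "delta_cost_high": self.delta_cost.ci_high,
            "icer": self.icer,
            "prob_cost_effective": self.prob_cost_effective,
        }


def analyse_imputed(
    imputed: ImputedDatasets,
    schema: VariableSchema | None = None,
    wtp_grid=DEFAULT_WTP_GRID,
    wtp: float = DEFAULT_WTP,
    scenario: str = "",
) -> CeaResult:
    """Estimate per copy, pool with Rubin's rules, and summarise."""
    if imputed.m < 2:
        raise ValueError("need at least 2 imputed copies")
    schema = schema or imputed[0].schema
    per_copy = [estimate_incrementals(ds, schema) for ds in imputed]
    est = np.array([[e.delta_e, e.delta_c] for e in per_copy])
    covs = np.array([e.cov for e in per_copy])
    _, pooled_cov = rubin_pool_matrix(est, covs)
    dq = rubin_pool(est[:, 0], covs[:, 0, 0])
    dc = rubin_pool(est[:, 1], covs[:, 1, 1])
    arms = list(per_copy[0].arm_summary)
    arm_summary = {}
    for arm in arms:
        names = per_copy[0].arm_summary[arm]
        arm_summary[arm] = {
            name: rubin_pool(
                [e.arm_summary[arm][name][0] for e in per_copy],
                [e.arm_summary[arm][name][1] for e in per_copy],
            )
            for name in names
        }
    probs = ceac(dq.estimate, dc.estimate, pooled_cov, wtp_grid)
    p_at = float(ceac(dq.estimate, dc.estimate, pooled_cov, [wtp])[0])
    return CeaResult(
        scenario=scenario or _scenario_label(imputed.assumptions),
        assumptions=imputed.assumptions,
        arm_summary=arm_summary,
        delta_qaly=dq,
        delta_cost=dc,
        pooled_cov=pooled_cov,
        icer=icer(dc.estimate, dq.estimate),
        wtp_grid=tuple(wtp_grid),
        ceac=probs,
        wtp=wtp,
        prob_cost_effective=p_at,
        m=imputed.m,
    )


def _scenario_label(ea: EndpointAssumptions) -> str:
    return f"{ea.effect.value}/{ea.cost.value}/{ea.interim}"


#: Named sensitivity scenarios: effectiveness assumption, cost assumption,
#: interim policy.  "J2R-MAR" keeps costs MAR while quality of life jumps to
#: reference; "BMCF" applies baseline-mean-carried-forward to quality of life
#: with costs and interim values MAR.
SCENARIOS: dict = {
    "MAR": EndpointAssumptions(Assumption.MAR, Assumption.MAR, INTERIM_MAR),
    "J2R": EndpointAssumptions(Assumption.J2R, Assumption.J2R, INTERIM_MAR),
    "J2R-interim": EndpointAssumptions(Assumption.J2R, Assumption.J2R, INTERIM_DROPOUT),
    "J2R-MAR": EndpointAssumptions(Assumption.J2R, Assumption.MAR, INTERIM_MAR),
    "BMCF": EndpointAssumptions(Assumption.BMCF, Assumption.MAR, INTERIM_MAR),
}


def resolve_scenario(name: str) -> tuple:
    """Map a scenario name to (canonical name, EndpointAssumptions)."""
    key = str(name).strip().replace(" ", "-").lower()
    for canon, ea in SCENARIOS.items():
        if canon.lower() == key:
            return canon, ea
    raise ValueError(f"unknown scenario {name!r}; valid: {list(SCENARIOS)}")


def run_sensitivity_suite(
    data: TrialData,
    schema: VariableSchema | None = None,
    scenarios=tuple(SCENARIOS),
    settings: SamplerSettings | None = None,
    seed: int | None = None,
    wtp_grid=DEFAULT_WTP_GRID,
    wtp: float = DEFAULT_WTP,
) -> dict:
    """Run the full sensitivity analysis: one CeaResult per scenario.

    The per-arm posterior draws and the per-(participant, copy) imputation
    substreams are shared across scenarios, so differences between rows
    reflect the missing-data assumptions rather than Monte-Carlo noise.
    """
    from .impute import ReferenceBasedImputer  # local import keeps module load light

    schema = schema or data.schema
    settings = settings or SamplerSettings()
    resolved = [resolve_scenario(s) for s in scenarios]
    fitter = ReferenceBasedImputer(
        schema,
        assumptions=SCENARIOS["MAR"],
        n_imputations=settings.n_imputations,
        burn_in=settings.burn_in,
        thinning=settings.thinning,
        ridge=settings.ridge,
        random_state=seed,
    )
    fitter.fit(data)
    results = {}
    for name, ea in resolved:
        imputed = impute(data, schema, ea, fitter.draws_, seed=fitter._seed_,
                         profile=fitter.profile_)
        results[name] = analyse_imputed(imputed, schema, wtp_grid, wtp, scenario=name)
    return results


def results_table(results: dict) -> pd.DataFrame:
    """Sensitivity-suite summary, one row per scenario."""
    return pd.DataFrame([r.row() for r in results.values()])
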