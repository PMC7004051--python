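"""Assumption-specific joint distributions for pattern-mixture imputation.

Given one posterior draw per arm and one participant's missingness profile,
these builders assemble the joint multivariate normal from which the missing
block is imputed.  Five options are supported:

* MAR  — randomised-arm parameters throughout (the standard MI default).
* J2R  — jump to reference: post-dropout means switch to the reference arm;
  the covariance keeps the randomised-arm law for the pre-dropout block and
  the reference-arm conditional law of the post-dropout block given it.
* CIR  — copy increments in reference: post-dropout means continue from the
  value at dropout along the reference arm's mean increments; covariance as
  under J2R.
* LMCF — last mean carried forward: post-dropout means frozen at the
  randomised arm's mean at the dropout time; randomised-arm covariance.
* BMCF — baseline mean carried forward: post-dropout means revert to the
  randomised arm's baseline mean; randomised-arm covariance.

Cost and effectiveness endpoints may carry different assumptions (one of
them MAR), and interim-missing values can be kept MAR while dropout values
are treated as MNAR: the missing cells split into a MAR block and an MNAR
block, the marginal over everything except the MNAR block stays the
randomised-arm draw, and the conditional of the MNAR block given the rest
follows the chosen option.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .patterns import ParticipantProfile
from .posterior import PosteriorDraw, ensure_pd
from .schema import COST, EFFECT, VariableSchema


class Assumption(str, Enum):
    """Missing-data assumption for one endpoint."""

    MAR = "MAR"
    J2R = "J2R"
    CIR = "CIR"
    LMCF = "LMCF"
    BMCF = "BMCF"

    @classmethod
    def parse(cls, name) -> "Assumption":
        if isinstance(name, cls):
            return name
        try:
            return cls[str(name).upper()]
        except KeyError:
            raise ValueError(
                f"unknown assumption {name!r}; valid: {[a.value for a in cls]}"
            ) from None

    @property
    def needs_reference(self) -> bool:
        return self in (Assumption.J2R, Assumption.CIR)


#: Assumptions whose covariance splices the reference-arm conditional law.
_REFERENCE_COV = (Assumption.J2R, Assumption.CIR)

INTERIM_MAR = "treat-as-MAR"
INTERIM_DROPOUT = "treat-as-dropout"


@dataclass(frozen=True)
class EndpointAssumptions:
    """Per-endpoint assumptions plus the interim-missing policy.

    Both endpoints may share one MNAR family, or one endpoint may be MAR
    while the other is MNAR; two *different* MNAR families at once are not
    supported.  ``interim`` chooses whether interim-missing values stay MAR
    or are folded into the MNAR block of their endpoint.
    """

    effect: Assumption = Assumption.MAR
    cost: Assumption = Assumption.MAR
    interim: str = INTERIM_MAR

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect", Assumption.parse(self.effect))
        object.__setattr__(self, "cost", Assumption.parse(self.cost))
        if self.interim not in (INTERIM_MAR, INTERIM_DROPOUT):
            raise ValueError(
                f"interim policy must be {INTERIM_MAR!r} or {INTERIM_DROPOUT!r}"
            )
        non_mar = {a for a in (self.effect, self.cost) if a is not Assumption.MAR}
        if len(non_mar) > 1:
            raise ValueError(
                "endpoints must share one MNAR family or one must be MAR; "
                f"got {self.effect.value}/{self.cost.value}"
            )

    def for_endpoint(self, endpoint: str) -> Assumption:
        return self.effect if endpoint == EFFECT else self.cost

    @property
    def needs_reference(self) -> bool:
        return self.effect.needs_reference or self.cost.needs_reference


@dataclass(frozen=True)
class PatternJoint:
    """Assumption-specific joint MVN for one participant's full vector."""

    mean: np.ndarray
    cov: np.ndarray
    observed: tuple
    mar_missing: tuple
    mnar_missing: tuple


def _mnar_indices(
    assumption: Assumption,
    profile: ParticipantProfile,
    schema: VariableSchema,
    endpoint: str,
    interim_policy: str,
) -> set:
    """Joint-vector indices of the endpoint's MNAR-classified missing cells."""
    if assumption is Assumption.MAR:
        return set()
    ep = set(schema.endpoint_indices(endpoint))
    out = set(profile.dropout_missing & ep)
    if interim_policy == INTERIM_DROPOUT:
        out |= set(profile.interim_missing & ep)
    return out


def _endpoint_fallback(assumption: Assumption, schema: VariableSchema, endpoint: str) -> bool:
    """Carry-back options need a baseline measurement on the endpoint.

    BMCF on an endpoint with no time-zero measurement (e.g. a single
    total-cost variable) has no baseline mean to revert to and falls back
    to MAR for that endpoint.
    """
    return assumption is Assumption.BMCF and not schema.has_baseline(endpoint)


def build_mean(
    assumption,
    mu_rand: np.ndarray,
    mu_ref: np.ndarray | None,
    profile: ParticipantProfile,
    schema: VariableSchema,
    interim_policy: str = INTERIM_MAR,
) -> np.ndarray:
    """Mean vector of the pattern joint under a single assumption.

    Covariate entries always keep randomised-arm values (they are
    pre-randomisation quantities).  Within each endpoint, for an
    MNAR-classified missing entry at time index j with anchor a (the last
    same-endpoint index before j outside the MNAR block):

    * J2R:  μ_ref[j]
    * CIR:  μ_rand[a] + (μ_ref[j] − μ_ref[a]);  μ_ref[j] when no anchor
    * LMCF: μ_rand[a];  μ_rand[j] (MAR fallback) when no anchor
    * BMCF: μ_rand at the endpoint's baseline index; MAR fallback when the
      endpoint has no baseline measurement

    Everything else is μ_rand.
    """
    assumption = Assumption.parse(assumption)
    if assumption.needs_reference and mu_ref is None:
        raise ValueError(f"{assumption.value} requires a reference-arm draw")
    mu = np.array(mu_rand, dtype=float)
    if assumption is Assumption.MAR:
        return mu
    for endpoint in (EFFECT, COST):
        if _endpoint_fallback(assumption, schema, endpoint):
            continue
        idx = schema.endpoint_indices(endpoint)
        mnar = _mnar_indices(assumption, profile, schema, endpoint, interim_policy)
        if not mnar:
            continue
        mnar_local = {idx.index(j) for j in mnar}
        for local_j in sorted(mnar_local):
            j = idx[local_j]
            anchors = [k for k in range(local_j) if k not in mnar_local]
            a = anchors[-1] if anchors else None
            if assumption is Assumption.J2R:
                mu[j] = mu_ref[j]
            elif assumption is Assumption.CIR:
                if a is None:
                    mu[j] = mu_ref[j]
                else:
                    mu[j] = mu_rand[idx[a]] + (mu_ref[j] - mu_ref[idx[a]])
            elif assumption is Assumption.LMCF:
                if a is not None:
                    mu[j] = mu_rand[idx[a]]
            elif assumption is Assumption.BMCF:
                mu[j] = mu_rand[idx[0]]
    return mu


def build_covariance_j2r_cir(
    cov_rand: np.ndarray,
    cov_ref: np.ndarray,
    pre_indices,
    post_indices,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Spliced covariance for J2R/CIR.

    With P the pre-dropout (non-MNAR) block and Q the MNAR block, the joint
    keeps the randomised-arm marginal on P and the reference-arm conditional
    law of Q given P:

        Σ̃_PP = Σ_rand,PP
        B     = Σ_ref,QP Σ_ref,PP⁻¹
        Σ̃_QP = B Σ_rand,PP
        Σ̃_QQ = Σ_ref,QQ − B (Σ_ref,PP − Σ_rand,PP) Bᵀ

    Blocks are returned in the original index positions; the result is
    symmetrized.  An empty P returns Σ_ref; an empty Q returns Σ_rand.
    """
    P = np.asarray(list(pre_indices), dtype=int)
    Q = np.asarray(list(post_indices), dtype=int)
    d = cov_rand.shape[0]
    if cov_rand.shape != (d, d) or cov_ref.shape != (d, d):
        raise ValueError("covariance matrices must be square and same-dimensional")
    if np.intersect1d(P, Q).size:
        raise ValueError("pre and post index sets overlap")
    if P.size + Q.size != d:
        raise ValueError("pre ∪ post must partition the joint vector")
    if Q.size == 0:
        return _symmetrize(cov_rand)
    if P.size == 0:
        return _symmetrize(cov_ref)
    ref_PP = cov_ref[np.ix_(P, P)]
    try:
        B = np.linalg.solve(ref_PP, cov_ref[np.ix_(P, Q)]).T
    except np.linalg.LinAlgError:
        ref_PP = ensure_pd(ref_PP, max(ridge, 1e-8))
        B = np.linalg.solve(ref_PP, cov_ref[np.ix_(P, Q)]).T
    rand_PP = cov_rand[np.ix_(P, P)]
    out = np.empty((d, d))
    out[np.ix_(P, P)] = rand_PP
    QP = B @ rand_PP
    out[np.ix_(Q, P)] = QP
    out[np.ix_(P, Q)] = QP.T
    out[np.ix_(Q, Q)] = cov_ref[np.ix_(Q, Q)] - B @ (ref_PP - rand_PP) @ B.T
    return _symmetrize(out)


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a, dtype=float) + np.asarray(a, dtype=float).T) / 2.0


def build_joint(
    endpoint_assumptions: EndpointAssumptions,
    draw_rand: PosteriorDraw,
    draw_ref: PosteriorDraw | None,
    profile: ParticipantProfile,
    schema: VariableSchema,
) -> PatternJoint:
    """Compose the participant's pattern-specific joint distribution.

    Missing cells are split into a MAR block (endpoints under MAR, plus
    interim-missing cells under the treat-as-MAR policy) and an MNAR block.
    The marginal over observed ∪ MAR ∪ covariates is exactly the
    randomised-arm draw; the conditional of the MNAR block given the rest
    follows the chosen option — means per :func:`build_mean`, covariance per
    :func:`build_covariance_j2r_cir` for J2R/CIR and the randomised-arm
    covariance unchanged for MAR/LMCF/BMCF.
    """
    ea = endpoint_assumptions
    if ea.needs_reference and draw_ref is None:
        raise ValueError("J2R/CIR require a reference-arm draw")

    mnar: set = set()
    mu = np.array(draw_rand.mean, dtype=float)
    mu_ref = None if draw_ref is None else draw_ref.mean
    for endpoint in (EFFECT, COST):
        assumption = ea.for_endpoint(endpoint)
        if assumption is Assumption.MAR or _endpoint_fallback(assumption, schema, endpoint):
            continue
        ep_mnar = _mnar_indices(assumption, profile, schema, endpoint, ea.interim)
        mnar |= ep_mnar
        mu_ep = build_mean(
            assumption, draw_rand.mean, mu_ref, profile, schema, interim_policy=ea.interim
        )
        for j in ep_mnar:
            mu[j] = mu_ep[j]

    reference_cov = any(
        ea.for_endpoint(ep) in _REFERENCE_COV
        and _mnar_indices(ea.for_endpoint(ep), profile, schema, ep, ea.interim)
        for ep in (EFFECT, COST)
    )
    if mnar and reference_cov:
        P = [j for j in range(schema.dim) if j not in mnar]
        cov = build_covariance_j2r_cir(draw_rand.cov, draw_ref.cov, P, sorted(mnar))
    else:
        cov = _symmetrize(draw_rand.cov)

    all_missing = set(profile.missing)
    mar = tuple(sorted(all_missing - mnar))
    observed = tuple(j for j in range(schema.dim) if j not in all_missing)
    return PatternJoint(mu, cov, observed, mar, tuple(sorted(mnar)))
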