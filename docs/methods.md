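# Methods

## Setting and estimands

`rbcea` targets two-arm randomised trials with a within-trial
cost-effectiveness analysis: health-related quality of life (utility
scores) measured at fixed times, costs measured repeatedly or as a single
total, and appreciable missingness in both. The quantities of interest are
the between-arm differences in QALYs and costs, their joint uncertainty,
the ICER, and the cost-effectiveness acceptability curve. The package's
purpose is *sensitivity analysis*: quantifying how those conclusions move
when the missing data are assumed missing-not-at-random in specific,
qualitatively framed ways, rather than missing at random.

## Imputation model

Within each arm, the joint vector
[covariates | effectiveness by time | costs by time] is modelled as
multivariate normal. Covariates (age, sex, symptom scores, baseline
utility) sit inside the vector so the imputation conditions on them; binary
covariates enter as 0/1 columns, which MVN imputation handles adequately
for conditioning purposes. Normality of costs is a simplification: MVN
imputation is known to be robust when the downstream estimators (here,
arm means) are approximately normal, which holds at the trial sizes this
package targets (hundreds per arm) but should not be trusted in very small
trials.

### Posterior sampler

The MAR fit is a data-augmentation Gibbs sampler under the Jeffreys prior
p(μ, Σ) ∝ |Σ|^−(d+1)/2:

1. **Initialisation** — complete-case mean and covariance; if fewer than
   d + 2 complete cases, available-case means and a ridge-regularised
   diagonal covariance.
2. **I-step** — missing cells redrawn from their conditional normal given
   the current (μ, Σ), vectorised over rows sharing a missingness pattern.
3. **P-step** — Σ ~ inverse-Wishart(n − 1, S) on the completed data's
   centred scatter S, then μ ~ N(ȳ, Σ/n).

Defaults: m = 100 retained draws, burn-in 500, thinning 100 — chosen so
retained draws are nearly independent while a full two-arm fit stays under
half a minute at n ≈ 500, d ≈ 4–8. All three are exposed in
`SamplerSettings` and on the estimators. With no missing data the
stationary distribution is the conjugate closed form (Σ | Y ~ IW(n−1, S),
μ | Σ, Y ~ N(ȳ, Σ/n)); the tests verify the first two moments against it.
One retained draw feeds exactly one imputed dataset; the k-th draws of the
two arms are paired by index.

The controlled-imputation literature does not fix a prior or sampler
schedule; the Jeffreys prior matches common practice in reference-based
imputation tooling and is the package's own documented default.

### Pattern classification

Missing outcome cells are classified per endpoint: *dropout-missing* when
every later same-endpoint measurement is also missing, *interim-missing*
otherwise. Classification uses only the missingness mask. Dropout time is
tracked per endpoint because cost and effectiveness patterns can differ
(a participant may return questionnaires but have no cost record). A
single total-cost variable is one "time point"; its dropout state is its
own observed/missing state. A missing baseline measurement is treated as
covariate-like and mean-imputed (`impute_baseline_mean`) rather than
modelled, mirroring how such isolated baseline gaps are handled in
practice.

### Reference-based options

Five options are implemented (MAR, J2R, CIR, LMCF, BMCF; see README for
the mean rules and the J2R/CIR covariance splice). Implementation details
that are genuinely choices:

- **Mixed MAR/MNAR blocks.** When endpoints carry different assumptions,
  or interim cells are kept MAR, the joint is defined by composition: the
  marginal over (observed ∪ MAR-missing ∪ covariates) is the
  randomised-arm draw, and the conditional of the MNAR block given
  everything else follows the chosen option (means from the mean rules,
  covariance from the splice with P = everything else). This composition
  uniquely determines the joint.
- **Anchoring of carry-forward rules.** The post-dropout mean rules anchor
  each MNAR cell at the last same-endpoint index outside the MNAR block
  (for monotone dropout this is the dropout time). Under the
  treat-as-dropout interim policy, a carried-forward mean therefore comes
  from the last non-MNAR time before the gap, per missing variable.
- **Endpoints without a baseline.** BMCF needs a time-zero mean; an
  endpoint with no baseline measure (the usual single total-cost variable)
  falls back to MAR, matching how the BMCF scenario is used in practice
  (utilities revert to baseline, costs stay MAR). Similarly LMCF with no
  earlier observation to anchor on falls back to the randomised-arm mean.
- **Reference-arm reduction.** For J2R/CIR, a participant whose randomised
  arm *is* the reference arm gets exactly the MAR joint (verified to
  1e−10). LMCF/BMCF never consult the reference arm, so they are invariant
  to the reference label but intentionally different from MAR even in the
  reference arm — that is their definition.
- **Covariates never switch** to reference-arm parameters: they are
  pre-randomisation quantities.

### Drawing the missing values

Missing cells are drawn sequentially, one variable at a time, each from
its exact univariate conditional given the observed cells and the cells
already drawn — an exact factorisation of the joint conditional normal,
valid in any order. The order is fixed: MAR-classified cells first, with
the cost endpoint before the effectiveness endpoint, then MNAR cells; and
every (participant, copy) pair owns a named random substream keyed by a
stable hash of the participant id. Consequences:

- results are invariant to row order in the input file;
- re-running with the same master seed is bit-reproducible;
- sensitivity scenarios under a shared seed reuse identical deviates for
  cells whose conditional law the scenario does not alter. In particular a
  scenario with MAR costs produces *bit-identical* cost imputations
  whether the effectiveness endpoint is MAR or jump-to-reference (the cost
  cells are MAR-classified in both, drawn first given the observed data
  only, from the same randomised-arm marginal). Scenario contrasts in the
  suite therefore reflect the assumptions themselves, not Monte-Carlo
  noise.

## Analysis pipeline

QALYs are the trapezoidal area under each participant's utility curve
(linear change between assessments, one-year horizon, no discounting).
Between-arm differences in QALYs and costs are unadjusted differences of
means; their joint 2×2 covariance is the seemingly-unrelated-regressions
covariance, which with identical regressors reduces to per-outcome OLS
plus the residual cross-covariance scaled by (1/n₀ + 1/n₁) (n − 2
denominator). Rubin's rules pool estimates and covariances across copies;
confidence intervals use the t distribution with
ν = (m−1)(1 + W/((1+1/m)B))² degrees of freedom, with the normal limit
when B = 0. The CEAC uses the pooled-coefficient normal approximation
Φ(INB/√var INB) rather than per-copy bootstrap — deterministic, fast, and
consistent with the SUR formulation; pooled coefficients (not averaged
per-copy probabilities) are the documented route. Default
willingness-to-pay grid: 0–50,000 in steps of 500, with 20,000 as the
reporting threshold.

Named scenarios map to per-endpoint assumptions: `MAR`; `J2R` (both
endpoints, interim MAR); `J2R-interim` (interim utilities also J2R);
`J2R-MAR` (utilities J2R, costs MAR); `BMCF` (utilities BMCF, costs and
interim MAR). Two *different* MNAR families at once (e.g. J2R utilities
with LMCF costs) are rejected by validation — the composition that defines
the mixed joint is only worked out for one MNAR family plus MAR.

## Synthetic-data generator

The generator emulates the structure of a two-arm pragmatic depression
trial: ~235 participants per arm; utilities at baseline, 6 and 12 months;
one total-cost variable; six missingness patterns. The preset
(`cobalt_preset`) uses the published per-arm observed means and SDs as the
complete-data truth — usual care utilities (0.502, 0.542, 0.555), active
arm (0.547, 0.662, 0.637); costs £799 (SD 725) vs £1,803 (SD 1,115) — and
calibrates an MAR dropout mechanism (logistic in the previous utility,
slope −2 per utility unit) so expected pattern frequencies approximate the
published ones: ≈78.5% completers, ≈9% with no follow-up, small interim
and cost-only-missing fractions. Intercepts are solved deterministically
from the marginal rates by quadrature and root-finding; the calibration
matches marginal rates and ignores selection over time, so realised
pattern frequencies land within a couple of percentage points of the
targets, not on them.

Choices the published tables do not determine, fixed once here: the
correlation structure (utility autocorrelations 0.55/0.45/0.65,
utility–cost correlation −0.15) and the cost-missingness coupling
(probability 1 given effectiveness dropout, 0.75 given an interim gap,
19/387 otherwise). Baseline utility serves as the key covariate inside the
MVN vector; age/sex/symptom covariates are not emulated (no published
moments, and they would only add nuisance dimensions).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: the real trial's covariance structure (not
published), non-normal skewed costs (utilities and costs are exactly MVN
unless the optional zero-truncation/clipping flags are set, which trade
moment fidelity for realism), item-level cost components, and
covariate-driven missingness beyond the utility path. An optional
`post_dropout="j2r"` mode rewrites treated dropouts' unobserved cells from
the reference-arm conditional law, creating a truth under which the J2R
analysis is correctly specified; the tests use it to verify the
directional claim that J2R is then less biased than MAR.

## Numerical choices

- Covariances are symmetrised after every construction; a Cholesky failure
  triggers a ridge of 1e−8·trace(Σ)/d on the diagonal, escalated up to
  five times before erroring.
- Conditional variances are clamped at zero against roundoff.
- Posterior draws validate symmetry and eigenvalues ≥ −1e−8·λ_max.
- The sampler requires every variable observed at least twice per arm and
  n > d; violations raise errors naming the variable.
- ICER with Δe = 0 is reported as NaN (undefined), and negative ICERs are
  left to the CEAC for quadrant interpretation.
- Missing-value spellings accepted on input: empty string, `NA`, `.`
  (Stata dialect), `NaN`.

## Problem sizes used in the checks

The test suite verifies the conditional-normal algebra on 10³ random 4-d
cases plus sampling oracles at 1–2×10⁵ draws; the covariance splice
against a two-stage sampling oracle at 10⁵ draws (3 Monte-Carlo-SE
tolerance); the post-dropout mean rules over 10⁴ imputed copies of a
single participant; MAR unbiasedness under MCAR over 80 replicates of a
300-per-arm trial with m = 8 imputations (3 MC SEs); and one full-size
five-scenario suite at m = 100 with the default sampler schedule. These
sizes are the package's chosen verification scale; tolerances follow from
the Monte-Carlo standard errors at those sizes.

## Known limitations

- One MNAR family at a time (plus MAR on the other endpoint).
- Continuous outcomes only; no binary or time-to-event effectiveness.
- The information-anchoring property of Rubin's rules with reference-based
  imputation is checked only empirically (pooled-variance ratio within
  [0.5, 2] on synthetic data), not proven.
- No covariate-adjusted CEA, discounting, or value-of-information output.
- The CEAC normal approximation can misbehave when Δe is near zero with
  heavy tails; nonparametric bootstrap is a known alternative and is not
  implemented.
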