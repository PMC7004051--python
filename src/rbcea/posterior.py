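"""Per-arm multivariate-normal posterior via data augmentation.

Each treatment arm is modelled separately: the joint vector (covariates and
both endpoints) is assumed multivariate normal, and the missing cells are
assumed missing at random at this stage.  A data-augmentation Gibbs sampler
alternates

1. imputation of the missing cells from their conditional normal given the
   current (μ, Σ), and
2. a draw of Σ from its inverse-Wishart full conditional and of μ from its
   normal full conditional on the completed data, under the Jeffreys prior
   p(μ, Σ) ∝ |Σ|^-(d+1)/2.

With no missing data the stationary distribution is the conjugate
normal–inverse-Wishart posterior: Σ | Y ~ IW(n−1, S) with S the centred
scatter matrix, μ | Σ, Y ~ N(ȳ, Σ/n).  Retained draws (after burn-in, one
every ``thinning`` iterations) feed the reference-based imputation step:
one retained draw per imputed dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import TrialData
from .schema import DataValidationError, VariableSchema


@dataclass(frozen=True)
class SamplerSettings:
    """Monte-Carlo settings for the posterior sampler.

    ``n_imputations`` (m) retained draws, each separated by ``thinning``
    Gibbs iterations after ``burn_in`` discarded ones.  The defaults
    (m=100, burn-in 500, thinning 100) give near-independent retained draws
    at desk scale; m matches common multiple-imputation practice for
    cost-effectiveness analyses.
    """

    n_imputations: int = 100
    burn_in: int = 500
    thinning: int = 100
    ridge: float = 1e-8
    prior: str = "jeffreys"

    def __post_init__(self) -> None:
        if self.n_imputations < 2:
            raise ValueError("n_imputations must be at least 2")
        if self.burn_in < 0 or self.thinning < 1:
            raise ValueError("burn_in must be >= 0 and thinning >= 1")
        if self.prior != "jeffreys":
            raise ValueError(f"unsupported prior {self.prior!r}")


@dataclass(frozen=True)
class PosteriorDraw:
    """One retained draw of the per-arm MVN parameters."""

    arm: str
    mean: np.ndarray
    cov: np.ndarray
    index: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        d = mean.shape[0]
        if cov.shape != (d, d):
            raise ValueError("mean/cov dimension mismatch")
        if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
            raise ValueError("covariance draw is not symmetric")
        w = np.linalg.eigvalsh(cov)
        if w[0] < -1e-8 * max(w[-1], 1e-300):
            raise ValueError("covariance draw has a significantly negative eigenvalue")


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def ensure_pd(cov: np.ndarray, ridge_scale: float = 1e-8) -> np.ndarray:
    """Symmetrize and, if a Cholesky factorisation fails, add a ridge.

    The ridge is ``ridge_scale · trace(Σ)/d`` on the diagonal, escalated a
    few times before giving up.
    """
    cov = _symmetrize(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    base = ridge_scale * max(np.trace(cov) / d, 1e-300)
    for k in range(6):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            cov = cov + np.eye(d) * base * (10.0**k)
    raise np.linalg.LinAlgError("covariance not positive definite after ridge repair")


class MvnPosteriorGibbs:
    """Posterior sampler for a multivariate normal with missing cells.

    scikit-learn style estimator: construct with settings, ``fit`` on an
    (n, d) array with NaN for missing entries, then read ``mean_draws_``
    (m, d) and ``cov_draws_`` (m, d, d).

    Parameters
    ----------
    n_draws : int
        Number of retained posterior draws (m).
    burn_in, thinning : int
        Discarded initial iterations and spacing between retained draws.
    ridge : float
        Relative ridge used to repair near-singular covariance matrices.
    random_state : int, Generator, SeedSequence or None
        Source of randomness; the draw sequence is reproducible given it.
    """

    def __init__(
        self,
        n_draws: int = 100,
        burn_in: int = 500,
        thinning: int = 100,
        ridge: float = 1e-8,
        random_state=None,
    ):
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.thinning = thinning
        self.ridge = ridge
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_draws": self.n_draws,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "ridge": self.ridge,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "MvnPosteriorGibbs":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------

    def fit(self, X, y=None, column_names=None) -> "MvnPosteriorGibbs":
        """Run the data-augmentation sampler on an (n, d) array with NaNs."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = X.shape
        names = list(column_names) if column_names is not None else [f"x{j}" for j in range(d)]
        n_obs = (~np.isnan(X)).sum(axis=0)
        thin_cols = [names[j] for j in np.flatnonzero(n_obs < 2)]
        if thin_cols:
            raise DataValidationError(
                f"variables observed for fewer than 2 participants: {thin_cols}"
            )
        if n - 1 < d:
            raise DataValidationError(
                f"n={n} rows cannot identify a {d}-dimensional covariance (need n > d)"
            )
        settings = SamplerSettings(
            n_imputations=self.n_draws,
            burn_in=self.burn_in,
            thinning=self.thinning,
            ridge=self.ridge,
        )
        rng = np.random.default_rng(self.random_state)
        means, covs = _run_gibbs(X, settings, rng)
        self.n_features_in_ = d
        self.feature_names_in_ = names
        self.mean_draws_ = means
        self.cov_draws_ = covs
        return self


def _pattern_groups(mask: np.ndarray) -> list:
    """Group row indices by identical missingness signature (with any NaN)."""
    groups: dict = {}
    for i in np.flatnonzero(mask.any(axis=1)):
        groups.setdefault(mask[i].tobytes(), []).append(i)
    out = []
    for rows in groups.values():
        rows = np.asarray(rows)
        out.append((rows, np.flatnonzero(mask[rows[0]])))
    return out


def _initial_params(X: np.ndarray, ridge: float) -> tuple:
    mask = np.isnan(X)
    complete = ~mask.any(axis=1)
    d = X.shape[1]
    if complete.sum() >= d + 2:
        mu = X[complete].mean(axis=0)
        cov = np.cov(X[complete], rowvar=False)
    else:  # fallback: available-case means, ridge-regularised diagonal covariance
        mu = np.nanmean(X, axis=0)
        var = np.nanvar(X, axis=0, ddof=1)
        cov = np.diag(np.where(var > 0, var, 1.0))
    return mu, ensure_pd(cov, max(ridge, 1e-6))


def _run_gibbs(X: np.ndarray, settings: SamplerSettings, rng: np.random.Generator):
    n, d = X.shape
    mask = np.isnan(X)
    groups = _pattern_groups(mask)
    mu, cov = _initial_params(X, settings.ridge)
    Xc = X.copy()
    for rows, miss in groups:  # start from conditional means
        obs = np.setdiff1d(np.arange(d), miss)
        cm, _ = _group_conditional(mu, cov, obs, miss, Xc[np.ix_(rows, obs)])
        Xc[np.ix_(rows, miss)] = cm

    m = settings.n_imputations
    total = settings.burn_in + m * settings.thinning
    means = np.empty((m, d))
    covs = np.empty((m, d, d))
    kept = 0
    for it in range(total):
        # I-step: redraw missing cells given current (mu, cov)
        for rows, miss in groups:
            obs = np.setdiff1d(np.arange(d), miss)
            cm, cc = _group_conditional(mu, cov, obs, miss, Xc[np.ix_(rows, obs)])
            L = np.linalg.cholesky(ensure_pd(cc, settings.ridge))
            z = rng.standard_normal((len(rows), len(miss)))
            Xc[np.ix_(rows, miss)] = cm + z @ L.T
        # P-step: (Σ, μ) from the Jeffreys-prior full conditionals
        ybar = Xc.mean(axis=0)
        centred = Xc - ybar
        S = centred.T @ centred
        cov = stats.invwishart.rvs(df=n - 1, scale=ensure_pd(S, settings.ridge), random_state=rng)
        cov = ensure_pd(np.atleast_2d(cov), settings.ridge)
        Lmu = np.linalg.cholesky(cov / n)
        mu = ybar + Lmu @ rng.standard_normal(d)
        if it >= settings.burn_in and (it - settings.burn_in + 1) % settings.thinning == 0:
            means[kept] = mu
            covs[kept] = cov
            kept += 1
    assert kept == m
    return means, covs


def _group_conditional(mu, cov, obs, miss, y_obs):
    """Conditional mean rows and covariance of the missing block given observed."""
    if obs.size == 0:
        cm = np.broadcast_to(mu[miss], (y_obs.shape[0], len(miss))).copy()
        return cm, cov[np.ix_(miss, miss)]
    A = np.linalg.solve(cov[np.ix_(obs, obs)], cov[np.ix_(obs, miss)]).T
    cm = mu[miss] + (y_obs - mu[obs]) @ A.T
    cc = cov[np.ix_(miss, miss)] - A @ cov[np.ix_(obs, miss)]
    return cm, cc


def fit_mvn_posterior(
    data: TrialData,
    arm,
    schema: VariableSchema | None = None,
    settings: SamplerSettings | None = None,
    random_state=None,
) -> list:
    """Fit the MAR multivariate-normal model to one arm and return draws.

    Thin wrapper over :class:`MvnPosteriorGibbs` producing a list of
    :class:`PosteriorDraw`.  Arms are fitted independently — rows of the
    other arm never enter.
    """
    schema = schema or data.schema
    settings = settings or SamplerSettings()
    rows = data.arm_rows(arm)
    if rows.size == 0:
        raise DataValidationError(f"no participants in arm {arm!r}")
    est = MvnPosteriorGibbs(
        n_draws=settings.n_imputations,
        burn_in=settings.burn_in,
        thinning=settings.thinning,
        ridge=settings.ridge,
        random_state=random_state,
    )
    est.fit(data.values[rows], column_names=schema.columns)
    return [
        PosteriorDraw(str(arm), est.mean_draws_[k], est.cov_draws_[k], k)
        for k in range(settings.n_imputations)
    ]
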