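"""Gibbs sampler for the Gaussian log-linear allometry.

Model:  y_i = alpha + b x_i + e_i,  e_i ~ N(0, sigma^2), with
x = ln(D^2 H), y = ln W, prior (alpha, b) ~ N2(mu_b, Sigma_b) and
sigma^2 ~ InvGamma(v/2, v*V/2) (the scalar inverse-Wishart).

Both full conditionals are exact and conjugate, so the sampler
alternates

    (alpha, b) | sigma^2, y  ~  N2(m, P^-1),
        P = Sigma_b^-1 + X'X / sigma^2,
        m = P^-1 (Sigma_b^-1 mu_b + X'y / sigma^2)

    sigma^2 | alpha, b, y  ~  InvGamma((v + n)/2, (v V + RSS)/2)

with X the n x 2 design [1, x] and RSS the residual sum of squares at
the current coefficients.  The coefficient block is updated jointly,
which is exact here and cuts autocorrelation relative to
scalar-at-a-time updates.  The chain starts at the least-squares
solution; the first ``burn_in`` iterations are discarded and the rest
thinned by ``thin``.  Identical seed, data and config give bitwise
identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import LogRegressionData
from .priors import PriorSpec
from .summaries import FitSummary, summarize_chain


class GibbsError(RuntimeError):
    """Numerical failure or invalid configuration in the sampler."""


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.

    Defaults follow the study protocol: 25 000 iterations thinned by 3,
    with the first 5 000 iterations discarded as burn-in.
    """

    n_iter: int = 25_000
    thin: int = 3
    burn_in: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise GibbsError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.n_iter <= self.burn_in:
            raise GibbsError(
                f"n_iter ({self.n_iter}) must exceed burn_in ({self.burn_in})"
            )
        if self.thin < 1:
            raise GibbsError(f"thin must be >= 1, got {self.thin}")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorDraws:
    """Thinned post-burn-in draws of (alpha, b, sigma2)."""

    alpha: np.ndarray
    b: np.ndarray
    sigma2: np.ndarray
    config: McmcConfig
    prior: PriorSpec

    def __post_init__(self) -> None:
        n = self.alpha.size
        if not (self.b.size == n == self.sigma2.size):
            raise GibbsError("draw vectors must have equal length")
        if np.any(self.sigma2 <= 0):
            raise GibbsError("all sigma2 draws must be > 0")

    def __len__(self) -> int:
        return int(self.alpha.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(len(self)),
                "alpha": self.alpha,
                "b": self.b,
                "sigma2": self.sigma2,
            }
        )


def _ols_start(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = y.size
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    return beta, max(s2, 1e-12)


def gibbs_sample(
    data: LogRegressionData,
    prior: PriorSpec,
    config: McmcConfig | None = None,
    fixed_sigma2: float | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler.

    Parameters
    ----------
    data : LogRegressionData
        Log-scale observations for one component.
    prior : PriorSpec
        Coefficient and variance prior.
    config : McmcConfig, optional
        Chain settings; study-protocol defaults if omitted.
    fixed_sigma2 : float, optional
        Hold the residual variance at this value instead of sampling it.
        With sigma^2 fixed the coefficient draws are iid from the exact
        conjugate normal posterior, which is useful for validation.
    """
    if config is None:
        config = McmcConfig()
    if fixed_sigma2 is not None and not fixed_sigma2 > 0:
        raise GibbsError(f"fixed_sigma2 must be > 0, got {fixed_sigma2}")

    X = data.design_matrix()
    y = data.y
    n = data.n
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    try:
        Sigma_inv = np.linalg.inv(prior.Sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - PriorSpec guards
        raise GibbsError("prior covariance is singular") from exc
    Sigma_inv_mu = Sigma_inv @ prior.mu

    rng = np.random.default_rng(config.seed)
    beta, s2_start = _ols_start(X, y)
    sig2 = fixed_sigma2 if fixed_sigma2 is not None else s2_start

    shape = (prior.v + n) / 2.0
    vV = prior.v * prior.V

    kept = config.n_kept
    alpha_d = np.empty(kept)
    b_d = np.empty(kept)
    sig2_d = np.empty(kept)
    k = 0

    for it in range(config.n_iter):
        # (alpha, b) | sigma2
        P = Sigma_inv + XtX / sig2
        try:
            L = np.linalg.cholesky(P)
        except np.linalg.LinAlgError as exc:
            raise GibbsError(
                "conditional coefficient precision is not positive definite"
            ) from exc
        rhs = Sigma_inv_mu + Xty / sig2
        # m = P^-1 rhs via the Cholesky factor; draw = m + L^-T z
        m = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
        z = rng.standard_normal(2)
        beta = m + np.linalg.solve(L.T, z)

        # sigma2 | (alpha, b)
        if fixed_sigma2 is None:
            rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
            rss = max(rss, 0.0)
            sig2 = (vV + rss) / 2.0 / rng.gamma(shape)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            alpha_d[k] = beta[0]
            b_d[k] = beta[1]
            sig2_d[k] = sig2
            k += 1

    return PosteriorDraws(
        alpha=alpha_d[:k], b=b_d[:k], sigma2=sig2_d[:k], config=config, prior=prior
    )


def conjugate_posterior(
    data: LogRegressionData, prior: PriorSpec, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form N2 posterior of (alpha, b) with sigma^2 known.

    Returns (mean, covariance).  This is the analytic target the sampler
    must match when ``fixed_sigma2`` is used; it is computed directly
    from the normal-normal conjugacy, independent of the sampling path.
    """
    X = data.design_matrix()
    Sigma_inv = np.linalg.inv(prior.Sigma)
    P = Sigma_inv + X.T @ X / sigma2
    cov = np.linalg.inv(P)
    mean = cov @ (Sigma_inv @ prior.mu + X.T @ data.y / sigma2)
    return mean, cov


def summarize(
    draws: PosteriorDraws,
    level: float = 0.95,
    component: str = "total",
    method: str | None = None,
) -> FitSummary:
    """Posterior-mean point estimates with equal-tailed credible intervals."""
    if method is None:
        method = (
            "bayes_informative"
            if draws.prior.kind == "informative"
            else "bayes_noninformative"
        )
    return summarize_chain(
        alpha=draws.alpha,
        b=draws.b,
        sigma2=draws.sigma2,
        level=level,
        component=component,
        method=method,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics

@dataclass(frozen=True)
class ChainDiagnostics:
    """Per-parameter effective sample size and Geweke z-score."""

    ess: dict[str, float]
    geweke_z: dict[str, float]
    flagged: list[str]

    @property
    def ok(self) -> bool:
        return not self.flagged


def _geweke_z(chain: np.ndarray, first: float = 0.10, last: float = 0.50) -> float:
    """Geweke convergence z: compare means of the first 10% and last 50%.

    Segment-mean standard errors use the ESS-deflated sample variance so
    autocorrelation within each segment is accounted for.
    """
    import arviz as az

    n = chain.size
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    if np.var(a) == 0 and np.var(b) == 0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf

    def se(seg: np.ndarray) -> float:
        ess = float(az.ess(np.asarray(seg)[None, :]))
        ess = max(ess, 1.0)
        return float(np.var(seg, ddof=1) / ess)

    denom = np.sqrt(se(a) + se(b))
    if denom == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / denom)


def convergence_diagnostics(draws: PosteriorDraws) -> ChainDiagnostics:
    """ESS and Geweke z for alpha, b and sigma2; flags |z| > 2 or degenerate."""
    import arviz as az

    if len(draws) < 100:
        raise GibbsError(f"chain too short for diagnostics ({len(draws)} < 100)")
    ess: dict[str, float] = {}
    gz: dict[str, float] = {}
    flagged: list[str] = []
    for name, chain in (
        ("alpha", draws.alpha),
        ("b", draws.b),
        ("sigma2", draws.sigma2),
    ):
        if np.var(chain) == 0:
            ess[name] = 0.0
            gz[name] = np.nan
            flagged.append(name)
            continue
        ess[name] = float(az.ess(np.asarray(chain)[None, :]))
        gz[name] = _geweke_z(chain)
        if not np.isfinite(gz[name]) or abs(gz[name]) > 2.0:
            flagged.append(name)
    return ChainDiagnostics(ess=ess, geweke_z=gz, flagged=flagged)
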