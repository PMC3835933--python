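"""Shared fit-summary container for Bayesian and least-squares fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METHODS = ("bayes_informative", "bayes_noninformative", "mls")


@dataclass(frozen=True)
class FitSummary:
    """Point estimates and 95% (by default) intervals for one fit.

    ``method`` is one of ``bayes_informative``, ``bayes_noninformative``
    or ``mls``; intervals are credible (equal-tailed posterior
    quantiles) for the Bayesian methods and t-based confidence intervals
    for least squares.
    """

    component: str
    method: str
    alpha_hat: float
    b_hat: float
    alpha_interval: tuple[float, float]
    b_interval: tuple[float, float]
    sigma2_hat: float
    level: float = 0.95

    def __post_init__(self) -> None:
        for est, (lo, hi), name in (
            (self.alpha_hat, self.alpha_interval, "alpha"),
            (self.b_hat, self.b_interval, "b"),
        ):
            if not lo <= hi:
                raise ValueError(f"{name} interval bounds reversed: ({lo}, {hi})")
            if not (lo - 1e-12 <= est <= hi + 1e-12):
                raise ValueError(
                    f"{name} point estimate {est} outside interval ({lo}, {hi})"
                )
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def params(self):
        from .core import AllometricParams

        return AllometricParams(
            alpha=self.alpha_hat,
            b=self.b_hat,
            sigma2=self.sigma2_hat if self.sigma2_hat > 0 else None,
        )

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "method": self.method,
            "alpha": {
                "estimate": self.alpha_hat,
                "lower": self.alpha_interval[0],
                "upper": self.alpha_interval[1],
            },
            "b": {
                "estimate": self.b_hat,
                "lower": self.b_interval[0],
                "upper": self.b_interval[1],
            },
            "sigma2": self.sigma2_hat,
            "level": self.level,
        }


def summarize_chain(
    alpha: np.ndarray,
    b: np.ndarray,
    sigma2: np.ndarray,
    level: float = 0.95,
    component: str = "total",
    method: str = "bayes_noninformative",
) -> FitSummary:
    """Posterior mean + equal-tailed quantile interval for each parameter.

    Quantiles use the linear-interpolation convention (numpy default).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if alpha.size == 0:
        raise ValueError("empty chain")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    a_lo, a_hi = np.quantile(alpha, [lo_q, hi_q])
    b_lo, b_hi = np.quantile(b, [lo_q, hi_q])
    return FitSummary(
        component=component,
        method=method,
        alpha_hat=float(np.mean(alpha)),
        b_hat=float(np.mean(b)),
        alpha_interval=(float(a_lo), float(a_hi)),
        b_interval=(float(b_lo), float(b_hi)),
        sigma2_hat=float(np.mean(sigma2)),
        level=level,
    )
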