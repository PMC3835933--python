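"""Least-squares baseline fit of the log-linear allometry.

The classical comparator: ordinary least squares of ln W on ln(D^2 H)
with t-based confidence intervals (appropriate at the small sample
sizes typical of destructive biomass studies).  Delegates the fit to
statsmodels OLS and repackages it into the shared FitSummary.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .core import LogRegressionData
from .summaries import FitSummary


class FitError(ValueError):
    """Singular design or invalid request."""


def ols_fit(
    data: LogRegressionData,
    level: float = 0.95,
    component: str = "total",
) -> FitSummary:
    """Fit by OLS; sigma2_hat is the unbiased RSS/(n-2) estimate."""
    if not 0 < level < 1:
        raise FitError(f"level must be in (0, 1), got {level}")
    if np.ptp(data.x) == 0:
        raise FitError("singular design: x is constant")
    X = sm.add_constant(data.x)
    res = sm.OLS(data.y, X).fit()
    ci = res.conf_int(alpha=1 - level)
    return FitSummary(
        component=component,
        method="mls",
        alpha_hat=float(res.params[0]),
        b_hat=float(res.params[1]),
        alpha_interval=(float(ci[0, 0]), float(ci[0, 1])),
        b_interval=(float(ci[1, 0]), float(ci[1, 1])),
        sigma2_hat=float(res.mse_resid) if data.n > 2 else 0.0,
        level=level,
    )
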