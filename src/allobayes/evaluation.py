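"""Model evaluation on the measurement (kg) scale.

Three criteria, all computed on back-transformed predictions:

    MD   = (1/n) sum (y_i - yhat_i)          mean deviation
    MAD  = (1/n) sum |y_i - yhat_i|          mean absolute deviation
    RMSE = sqrt((1/n) sum (y_i - yhat_i)^2)  root mean squared error

The sign convention is observed minus predicted, so positive MD means
the model under-predicts.  Smaller is better for all three.

Also the additivity check: total biomass predicted by summing the four
component models (AT) versus the directly fitted total model (DT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SUM_COMPONENTS, AllometryError, TreeRecord, predict_biomass
from .summaries import FitSummary


@dataclass(frozen=True)
class EvalStats:
    """MD / MAD / RMSE (kg) for one model on one dataset."""

    component: str
    method: str
    MD: float
    MAD: float
    RMSE: float
    n: int


def evaluate(
    observed: np.ndarray,
    predicted: np.ndarray,
    component: str = "total",
    method: str = "mls",
) -> EvalStats:
    """Compute the three deviation criteria on the kg scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError(
            f"observed and predicted must be equal-length vectors, "
            f"got shapes {obs.shape} and {pred.shape}"
        )
    if obs.size < 1:
        raise ValueError("need at least one observation")
    if np.any(obs <= 0):
        raise ValueError("observed biomass must be > 0")
    dev = obs - pred
    return EvalStats(
        component=component,
        method=method,
        MD=float(np.mean(dev)),
        MAD=float(np.mean(np.abs(dev))),
        RMSE=float(np.sqrt(np.mean(dev**2))),
        n=int(obs.size),
    )


def stats_table(stats: list[EvalStats]) -> pd.DataFrame:
    """Wide table: rows = method, columns = component x {MD, MAD, RMSE}."""
    df = pd.DataFrame([s.__dict__ for s in stats])
    wide = df.pivot(index="method", columns="component", values=["MD", "MAD", "RMSE"])
    wide.columns = [f"{comp}_{metric}" for metric, comp in wide.columns]
    return wide.sort_index(axis=1)


@dataclass(frozen=True)
class AdditivityReport:
    """Per-tree AT vs DT total-biomass predictions and their agreement.

    AT sums the four component-model predictions per tree; DT applies
    the directly fitted total model.  ``correlation`` is the Pearson
    correlation of the two series, ``mean_bias`` the mean of AT - DT (kg)
    and ``relative_bias`` that bias divided by the mean DT prediction.
    """

    at: np.ndarray
    dt: np.ndarray
    correlation: float
    mean_bias: float
    relative_bias: float


def additivity_compare(
    component_fits: dict[str, FitSummary],
    total_fit: FitSummary,
    trees: list[TreeRecord],
    correction: str = "none",
) -> AdditivityReport:
    """Compare summed-component (AT) and direct-total (DT) predictions."""
    missing = [c for c in SUM_COMPONENTS if c not in component_fits]
    if missing:
        raise AllometryError(f"missing component fits: {missing}")
    if not trees:
        raise AllometryError("no trees to predict on")
    D = np.array([t.D for t in trees])
    H = np.array([t.H for t in trees])
    at = np.zeros(len(trees))
    for comp in SUM_COMPONENTS:
        at += predict_biomass(component_fits[comp].params(), D, H, correction)
    dt = np.asarray(predict_biomass(total_fit.params(), D, H, correction))
    if np.std(at) == 0 or np.std(dt) == 0:
        corr = 1.0 if np.allclose(at, dt) else np.nan
    else:
        corr = float(np.corrcoef(at, dt)[0, 1])
    bias = float(np.mean(at - dt))
    return AdditivityReport(
        at=at,
        dt=dt,
        correlation=corr,
        mean_bias=bias,
        relative_bias=bias / float(np.mean(dt)),
    )
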