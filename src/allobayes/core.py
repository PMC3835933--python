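"""Allometric model core: domain records, log-scale transforms, prediction.

The model is the single-predictor allometry

    ln W = alpha + b * ln(D^2 H) + e,    e ~ N(0, sigma^2)

with diameter at breast height D in cm, total height H in m and dry
biomass W in kg.  D^2*H is the usual volume proxy; on the log scale the
power law is a simple linear regression, which also tames the
heteroscedasticity of raw biomass.

Units are fixed (cm / m / kg) and never auto-detected.  Component labels
form a closed vocabulary: stem, branch, foliage, root, total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of biomass component labels.
COMPONENTS: tuple[str, ...] = ("stem", "branch", "foliage", "root", "total")

#: The four structural components whose masses sum to the total.
SUM_COMPONENTS: tuple[str, ...] = ("stem", "branch", "foliage", "root")

#: Relative tolerance used when checking that recorded total biomass
#: equals the component sum (measurement/rounding slack, not model error).
ADDITIVITY_RTOL = 1e-6


class AllometryError(ValueError):
    """Invalid tree record, component request, or model parameterization."""


@dataclass(frozen=True)
class AllometricParams:
    """Coefficients of the log-linear allometry.

    Parameters
    ----------
    alpha : float
        Log-scale intercept (for W in kg).
    b : float
        Log-scale slope on ln(D^2 H).
    sigma2 : float, optional
        Residual variance on the log scale; required for the
        Baskerville back-transformation correction.
    """

    alpha: float
    b: float
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.b)):
            raise AllometryError("alpha and b must be finite")
        if self.sigma2 is not None and not self.sigma2 > 0:
            raise AllometryError(f"sigma2 must be > 0, got {self.sigma2}")


@dataclass(frozen=True)
class TreeRecord:
    """One destructively sampled tree.

    ``biomass`` maps component labels to dry mass in kg; at least one
    component must be present.  If all four structural components and the
    total are recorded, the total is checked against their sum and a
    warning is emitted on disagreement (the record is kept as measured).
    """

    tree_id: str
    age: int
    D: float
    H: float
    biomass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise AllometryError(f"tree {self.tree_id}: D must be > 0, got {self.D}")
        if not self.H > 0:
            raise AllometryError(f"tree {self.tree_id}: H must be > 0, got {self.H}")
        if not self.biomass:
            raise AllometryError(f"tree {self.tree_id}: no biomass components")
        for comp, w in self.biomass.items():
            if comp not in COMPONENTS:
                raise AllometryError(
                    f"tree {self.tree_id}: unknown component {comp!r}; "
                    f"expected one of {COMPONENTS}"
                )
            if not w > 0:
                raise AllometryError(
                    f"tree {self.tree_id}: biomass[{comp!r}] must be > 0, got {w}"
                )
        if all(c in self.biomass for c in COMPONENTS):
            total = self.biomass["total"]
            sum_ = sum(self.biomass[c] for c in SUM_COMPONENTS)
            if not math.isclose(total, sum_, rel_tol=ADDITIVITY_RTOL, abs_tol=1e-9):
                warnings.warn(
                    f"tree {self.tree_id}: recorded total {total:g} kg differs "
                    f"from component sum {sum_:g} kg",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class LogRegressionData:
    """Paired (x, y) = (ln(D^2 H), ln W) observations for one component."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise AllometryError("x and y must be 1-d arrays of equal length")
        if x.size < 3:
            raise AllometryError(f"need at least 3 observations, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise AllometryError("x and y must be finite")

    @property
    def n(self) -> int:
        return int(self.x.size)

    def design_matrix(self) -> np.ndarray:
        """The n x 2 design [1, x]."""
        return np.column_stack([np.ones(self.n), self.x])


def to_log_data(trees: list[TreeRecord], component: str) -> LogRegressionData:
    """Assemble the log-scale regression data for one biomass component.

    x_i = ln(D_i^2 * H_i) with D in cm and H in m exactly as recorded;
    y_i = ln(W_i) with W in kg.  Tree order is preserved.
    """
    if component not in COMPONENTS:
        raise AllometryError(f"unknown component {component!r}")
    xs, ys = [], []
    for t in trees:
        if component not in t.biomass:
            raise AllometryError(
                f"tree {t.tree_id}: component {component!r} missing"
            )
        xs.append(math.log(t.D**2 * t.H))
        ys.append(math.log(t.biomass[component]))
    return LogRegressionData(np.array(xs), np.array(ys))


def predict_biomass(
    params: AllometricParams,
    D: float | np.ndarray,
    H: float | np.ndarray,
    correction: str = "none",
) -> float | np.ndarray:
    """Predict biomass (kg) on the measurement scale.

    ``correction="baskerville"`` multiplies the naive back-transform
    exp(alpha + b ln(D^2 H)) by exp(sigma2/2), the lognormal mean
    correction; it requires ``params.sigma2``.  The default is no
    correction, i.e. the median-unbiased plug-in back-transform.
    """
    D = np.asarray(D, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(D <= 0) or np.any(H <= 0):
        raise AllometryError("D and H must be > 0")
    if correction not in ("none", "baskerville"):
        raise AllometryError(f"unknown correction {correction!r}")
    log_pred = params.alpha + params.b * np.log(D**2 * H)
    pred = np.exp(log_pred)
    if correction == "baskerville":
        if params.sigma2 is None:
            raise AllometryError("baskerville correction requires sigma2")
        pred = pred * math.exp(params.sigma2 / 2.0)
    return pred if pred.ndim else float(pred)


# ---------------------------------------------------------------------------
# CSV dialect: tree_id, age, D_cm, H_m, stem_kg, ..., total_kg

_CSV_COLS = ["tree_id", "age", "D_cm", "H_m"] + [f"{c}_kg" for c in COMPONENTS]


def trees_to_frame(trees: list[TreeRecord]) -> pd.DataFrame:
    rows = []
    for t in trees:
        row = {"tree_id": t.tree_id, "age": t.age, "D_cm": t.D, "H_m": t.H}
        for c in COMPONENTS:
            row[f"{c}_kg"] = t.biomass.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLS)


def frame_to_trees(df: pd.DataFrame) -> list[TreeRecord]:
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise AllometryError(f"tree table missing columns: {missing}")
    trees = []
    for _, row in df.iterrows():
        biomass = {
            c: float(row[f"{c}_kg"])
            for c in COMPONENTS
            if pd.notna(row[f"{c}_kg"])
        }
        trees.append(
            TreeRecord(
                tree_id=str(row["tree_id"]),
                age=int(row["age"]),
                D=float(row["D_cm"]),
                H=float(row["H_m"]),
                biomass=biomass,
            )
        )
    return trees


def write_trees_csv(trees: list[TreeRecord], path) -> None:
    trees_to_frame(trees).to_csv(path, index=False)


def read_trees_csv(path) -> list[TreeRecord]:
    return frame_to_trees(pd.read_csv(path))
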