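"""Prior construction for the log-linear allometry coefficients.

An informative bivariate-normal prior on (alpha, b) is elicited from a
compilation of published allometric equations for the same species and
predictor form: the prior mean is the sample mean of the reported
(alpha, b) pairs and the prior covariance their unbiased (n-1) sample
covariance.  Published slope/intercept pairs are strongly negatively
correlated (a steeper slope pairs with a lower intercept), and the
elicited covariance carries that correlation into the posterior.

The non-informative alternative puts independent N(0, 1000) priors on
both coefficients, flat over any plausible allometry.  In both cases the
residual variance gets a scalar inverse-Wishart(V=1, v=0.001) prior,
read as inverse-gamma(v/2, v*V/2) in one dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import COMPONENTS, AllometryError


class PriorError(ValueError):
    """Invalid or degenerate prior construction."""


@dataclass(frozen=True)
class EquationRecord:
    """One published allometric parameter pair for a component."""

    source_id: str
    component: str
    alpha: float
    b: float

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise PriorError(
                f"unknown component {self.component!r}; expected one of {COMPONENTS}"
            )
        if not (np.isfinite(self.alpha) and np.isfinite(self.b)):
            raise PriorError(f"{self.source_id}: alpha and b must be finite")


@dataclass(frozen=True)
class PriorSpec:
    """Bivariate-normal prior on (alpha, b) plus residual-variance scalars.

    Attributes
    ----------
    mu : (2,) array
        Prior mean (mu_alpha, mu_b).
    Sigma : (2, 2) array
        Prior covariance; symmetric positive definite.
    V, v : float
        Scale and degrees of freedom of the scalar inverse-Wishart prior
        on sigma^2, i.e. sigma^2 ~ InvGamma(v/2, v*V/2).
    kind : str
        "informative" or "non_informative".
    """

    mu: np.ndarray
    Sigma: np.ndarray
    V: float = 1.0
    v: float = 0.001
    kind: str = "informative"

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        Sigma = np.asarray(self.Sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "Sigma", Sigma)
        if mu.shape != (2,):
            raise PriorError(f"mu must be length-2, got shape {mu.shape}")
        if Sigma.shape != (2, 2):
            raise PriorError(f"Sigma must be 2x2, got shape {Sigma.shape}")
        if not np.allclose(Sigma, Sigma.T, rtol=1e-10, atol=1e-12):
            raise PriorError("Sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(Sigma)
        if np.min(eigvals) <= 0:
            raise PriorError(f"Sigma must be positive definite (eigvals {eigvals})")
        if not self.V > 0 or not self.v > 0:
            raise PriorError("V and v must be > 0")
        if self.kind not in ("informative", "non_informative"):
            raise PriorError(f"unknown prior kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu": self.mu.tolist(),
                "Sigma": self.Sigma.tolist(),
                "V": self.V,
                "v": self.v,
                "kind": self.kind,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PriorSpec":
        d = json.loads(text)
        return cls(
            mu=np.array(d["mu"]),
            Sigma=np.array(d["Sigma"]),
            V=float(d["V"]),
            v=float(d["v"]),
            kind=d["kind"],
        )


def fit_bivariate_prior(
    records: list[EquationRecord], component: str
) -> PriorSpec:
    """Elicit the informative prior for one component from literature pairs.

    Uses the sample mean and the unbiased (n-1 denominator) sample
    covariance of the (alpha, b) pairs reported for ``component``.
    Requires at least 3 pairs so the covariance has positive degrees of
    freedom; a degenerate (singular) covariance is an error.
    """
    if component not in COMPONENTS:
        raise AllometryError(f"unknown component {component!r}")
    pairs = np.array(
        [(r.alpha, r.b) for r in records if r.component == component], dtype=float
    )
    if len(pairs) < 3:
        raise PriorError(
            f"need at least 3 literature equations for {component!r}, "
            f"got {len(pairs)}"
        )
    mu = pairs.mean(axis=0)
    Sigma = np.cov(pairs, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(Sigma, tol=1e-12) < 2 or np.min(
        np.linalg.eigvalsh(Sigma)
    ) <= 0:
        raise PriorError(
            f"degenerate covariance for component {component!r}: "
            "literature (alpha, b) pairs are collinear or identical"
        )
    return PriorSpec(mu=mu, Sigma=Sigma, V=1.0, v=0.001, kind="informative")


def noninformative_prior() -> PriorSpec:
    """Independent N(0, 1000) priors on alpha and b; same variance scalars."""
    return PriorSpec(
        mu=np.zeros(2),
        Sigma=np.diag([1000.0, 1000.0]),
        V=1.0,
        v=0.001,
        kind="non_informative",
    )


def prior_correlation(spec: PriorSpec) -> float:
    """Prior correlation between alpha and b: Sigma_12 / sqrt(S_11 S_22)."""
    S = spec.Sigma
    return float(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))


# ---------------------------------------------------------------------------
# CSV dialect: source_id, component, alpha, b

def equations_to_frame(records: list[EquationRecord]):
    import pandas as pd

    return pd.DataFrame(
        [(r.source_id, r.component, r.alpha, r.b) for r in records],
        columns=["source_id", "component", "alpha", "b"],
    )


def frame_to_equations(df) -> list[EquationRecord]:
    needed = ["source_id", "component", "alpha", "b"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PriorError(f"equation table missing columns: {missing}")
    return [
        EquationRecord(
            source_id=str(row["source_id"]),
            component=str(row["component"]),
            alpha=float(row["alpha"]),
            b=float(row["b"]),
        )
        for _, row in df.iterrows()
    ]


def write_equations_csv(records: list[EquationRecord], path) -> None:
    equations_to_frame(records).to_csv(path, index=False)


def read_equations_csv(path) -> list[EquationRecord]:
    import pandas as pd

    return frame_to_equations(pd.read_csv(path))
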