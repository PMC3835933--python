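"""Synthetic tree datasets and literature-equation sets.

Real destructive-sampling campaigns are small and stratified by stand
age; the generator emulates that design.  The default configuration
mirrors a 39-tree sample from three plantation age cohorts (7, 16 and
28 years) with the diameter and height ranges observed in each, and a
lognormal multiplicative error around a true per-component allometry
ln W = alpha + b ln(D^2 H) + e.  Component masses are generated
independently and the total is their exact sum, so additivity holds in
truth and any slippage downstream is attributable to the fitted models.

Height given diameter follows a log-linear trend drawn through the
cohort range endpoints plus Gaussian noise on the log scale — a
modelling choice for the generator, not an estimate of any real stand.

The literature generator draws (alpha, b) pairs from a bivariate normal
with a negative correlation, matching the robust empirical pattern that
published allometries trade intercept against slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SUM_COMPONENTS, AllometricParams, TreeRecord
from .priors import EquationRecord


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


#: Default age cohorts: (age yr, (D min, D max) cm, (H min, H max) m, share).
DEFAULT_COHORTS: tuple[tuple[int, tuple[float, float], tuple[float, float], float], ...] = (
    (7, (5.7, 16.3), (4.9, 9.3), 9 / 39),
    (16, (5.6, 22.5), (5.9, 14.8), 14 / 39),
    (28, (8.7, 28.0), (10.3, 22.7), 16 / 39),
)

#: Default true allometries per structural component (log-scale
#: intercept/slope typical of published conifer equations; residual
#: sd 0.2 on the log scale).
DEFAULT_TRUE_PARAMS: dict[str, AllometricParams] = {
    "stem": AllometricParams(-3.8205, 0.9270, 0.04),
    "branch": AllometricParams(-5.8277, 0.9136, 0.04),
    "foliage": AllometricParams(-5.4356, 0.8798, 0.04),
    "root": AllometricParams(-4.1500, 0.8117, 0.04),
}

# Fixed per-purpose stream keys: adding a component never perturbs the
# draws of another.
_STREAM_KEYS = {
    "structure": 0,
    "stem": 1,
    "branch": 2,
    "foliage": 3,
    "root": 4,
    "total": 5,
}


@dataclass(frozen=True)
class TreeSimConfig:
    """Configuration of the synthetic destructive sample."""

    n_trees: int = 39
    cohorts: tuple = DEFAULT_COHORTS
    true_params: dict[str, AllometricParams] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PARAMS)
    )
    hd_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise SimConfigError(f"n_trees must be >= 1, got {self.n_trees}")
        if not self.cohorts:
            raise SimConfigError("need at least one cohort")
        props = []
        for age, (dlo, dhi), (hlo, hhi), prop in self.cohorts:
            if not (0 < dlo <= dhi and 0 < hlo <= hhi):
                raise SimConfigError(
                    f"cohort {age}: ranges must be positive and ordered"
                )
            if prop <= 0:
                raise SimConfigError(f"cohort {age}: proportion must be > 0")
            props.append(prop)
        if not math.isclose(sum(props), 1.0, rel_tol=1e-9):
            raise SimConfigError(f"cohort proportions must sum to 1, got {sum(props)}")
        if not self.true_params:
            raise SimConfigError("true_params must not be empty")
        for comp, p in self.true_params.items():
            if comp not in _STREAM_KEYS or comp == "structure":
                raise SimConfigError(f"unknown component {comp!r} in true_params")
            if p.sigma2 is None or not p.sigma2 >= 0:
                raise SimConfigError(f"true_params[{comp!r}] needs sigma2 >= 0")
        if self.hd_noise < 0:
            raise SimConfigError(f"hd_noise must be >= 0, got {self.hd_noise}")


def _component_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAM_KEYS[key])))


def _cohort_counts(n: int, props: list[float]) -> list[int]:
    """Largest-remainder apportionment of n trees over cohorts."""
    raw = [n * p for p in props]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_trees(config: TreeSimConfig) -> list[TreeRecord]:
    """Draw a synthetic destructive sample.

    Diameters are uniform within each cohort's range; log-height follows
    the log-linear trend through the cohort's (D, H) range endpoints
    plus N(0, hd_noise^2), clipped back into the height range.  Each
    structural component gets lognormal error around its true allometry;
    the recorded total is the exact component sum.  Deterministic under
    ``config.seed``.
    """
    rng = _component_rng(config.seed, "structure")
    props = [c[3] for c in config.cohorts]
    counts = _cohort_counts(config.n_trees, props)

    ages, Ds, Hs = [], [], []
    for (age, (dlo, dhi), (hlo, hhi), _), k in zip(config.cohorts, counts):
        D = rng.uniform(dlo, dhi, size=k)
        if dhi > dlo:
            slope = math.log(hhi / hlo) / math.log(dhi / dlo)
        else:
            slope = 0.0
        intercept = math.log(hlo) - slope * math.log(dlo)
        lnH = intercept + slope * np.log(D) + rng.normal(0, config.hd_noise, size=k)
        H = np.clip(np.exp(lnH), hlo, hhi)
        ages.extend([age] * k)
        Ds.append(D)
        Hs.append(H)
    D = np.concatenate(Ds)
    H = np.concatenate(Hs)
    x = np.log(D**2 * H)
    n = config.n_trees

    masses: dict[str, np.ndarray] = {}
    for comp, p in config.true_params.items():
        if comp == "total":
            continue
        crng = _component_rng(config.seed, comp)
        eps = crng.normal(0.0, math.sqrt(p.sigma2), size=n) if p.sigma2 > 0 else 0.0
        masses[comp] = np.exp(p.alpha + p.b * x + eps)
    if all(c in masses for c in SUM_COMPONENTS):
        masses["total"] = sum(masses[c] for c in SUM_COMPONENTS)
    elif "total" in config.true_params:
        p = config.true_params["total"]
        crng = _component_rng(config.seed, "total")
        eps = crng.normal(0.0, math.sqrt(p.sigma2), size=n) if p.sigma2 > 0 else 0.0
        masses["total"] = np.exp(p.alpha + p.b * x + eps)

    return [
        TreeRecord(
            tree_id=f"t{i + 1:03d}",
            age=int(ages[i]),
            D=float(D[i]),
            H=float(H[i]),
            biomass={c: float(m[i]) for c, m in masses.items()},
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class LitSimConfig:
    """Configuration of the synthetic literature-equation compilation."""

    n_equations: int = 32
    mu_true: tuple[float, float] = (-3.8205, 0.9270)
    Sigma_true: np.ndarray = field(
        default_factory=lambda: _corr_cov(0.8, 0.08, -0.9)
    )
    component: str = "stem"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_equations < 1:
            raise SimConfigError(f"n_equations must be >= 1, got {self.n_equations}")
        S = np.asarray(self.Sigma_true, dtype=float)
        object.__setattr__(self, "Sigma_true", S)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise SimConfigError("Sigma_true must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(S)) <= 0:
            raise SimConfigError("Sigma_true must be positive definite")
        rho = S[0, 1] / math.sqrt(S[0, 0] * S[1, 1])
        if rho > 0:
            raise SimConfigError(
                f"alpha-b correlation must be in (-1, 0], got {rho:.3f}"
            )


def _corr_cov(sd_a: float, sd_b: float, rho: float) -> np.ndarray:
    return np.array(
        [
            [sd_a**2, rho * sd_a * sd_b],
            [rho * sd_a * sd_b, sd_b**2],
        ]
    )


def generate_literature(config: LitSimConfig) -> list[EquationRecord]:
    """Draw synthetic published (alpha, b) pairs; deterministic under seed."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 97)))
    pairs = rng.multivariate_normal(
        np.asarray(config.mu_true, dtype=float), config.Sigma_true,
        size=config.n_equations,
    )
    return [
        EquationRecord(
            source_id=f"pub{i + 1:04d}",
            component=config.component,
            alpha=float(a),
            b=float(b),
        )
        for i, (a, b) in enumerate(pairs)
    ]
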