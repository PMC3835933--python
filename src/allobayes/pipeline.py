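"""End-to-end orchestration: fit all components by all three methods,
evaluate on the kg scale, and run the additivity comparison.

Outputs go to a result directory:

    fits.json          component x method parameter estimates + intervals
    evaluation.csv     MD/MAD/RMSE per component x method
    additivity.json    AT-vs-DT report per method
    draws_<comp>_<method>.csv   thinned MCMC chains
    manifest.json      config, seed and input checksums for reruns
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    COMPONENTS,
    SUM_COMPONENTS,
    TreeRecord,
    predict_biomass,
    read_trees_csv,
    to_log_data,
)
from .evaluation import AdditivityReport, EvalStats, additivity_compare, evaluate, stats_table
from .gibbs import McmcConfig, PosteriorDraws, gibbs_sample, summarize
from .ols import ols_fit
from .priors import (
    EquationRecord,
    PriorError,
    fit_bivariate_prior,
    noninformative_prior,
    read_equations_csv,
)
from .summaries import FitSummary

log = logging.getLogger("allobayes")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, keyed by (component, method)."""

    fits: dict[tuple[str, str], FitSummary]
    stats: list[EvalStats]
    additivity: dict[str, AdditivityReport]
    draws: dict[tuple[str, str], PosteriorDraws] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def fit_all(
    trees: list[TreeRecord],
    equations: list[EquationRecord],
    mcmc: McmcConfig,
    level: float = 0.95,
) -> tuple[dict[tuple[str, str], FitSummary], dict[tuple[str, str], PosteriorDraws]]:
    """Fit every available component with mls / non-informative /
    informative Bayes.  Components with no literature equations skip the
    informative fit with a logged warning.  Each chain gets a distinct
    seed derived from the base seed so chains are independent."""
    fits: dict[tuple[str, str], FitSummary] = {}
    draws: dict[tuple[str, str], PosteriorDraws] = {}
    nonin = noninformative_prior()
    for ci, comp in enumerate(COMPONENTS):
        if any(comp not in t.biomass for t in trees):
            log.warning("component %s missing from some trees; skipped", comp)
            continue
        data = to_log_data(trees, comp)
        t0 = time.perf_counter()
        fits[(comp, "mls")] = ols_fit(data, level=level, component=comp)

        cfg_n = McmcConfig(
            n_iter=mcmc.n_iter, thin=mcmc.thin, burn_in=mcmc.burn_in,
            seed=mcmc.seed + 2 * ci,
        )
        d = gibbs_sample(data, nonin, cfg_n)
        draws[(comp, "bayes_noninformative")] = d
        fits[(comp, "bayes_noninformative")] = summarize(d, level=level, component=comp)

        try:
            prior = fit_bivariate_prior(equations, comp)
        except PriorError as exc:
            log.warning("no informative prior for %s: %s", comp, exc)
        else:
            cfg_i = McmcConfig(
                n_iter=mcmc.n_iter, thin=mcmc.thin, burn_in=mcmc.burn_in,
                seed=mcmc.seed + 2 * ci + 1,
            )
            d = gibbs_sample(data, prior, cfg_i)
            draws[(comp, "bayes_informative")] = d
            fits[(comp, "bayes_informative")] = summarize(
                d, level=level, component=comp
            )
        log.info(
            "fitted %s (n=%d) in %.2fs", comp, data.n, time.perf_counter() - t0
        )
    return fits, draws


def evaluate_all(
    trees: list[TreeRecord],
    fits: dict[tuple[str, str], FitSummary],
    correction: str = "none",
) -> list[EvalStats]:
    """In-sample MD/MAD/RMSE on back-transformed predictions.

    Predictions plug the point estimates into the allometry (not the
    posterior predictive), matching how single-number estimates are
    used in practice."""
    stats = []
    for (comp, method), fs in sorted(fits.items()):
        sub = [t for t in trees if comp in t.biomass]
        obs = np.array([t.biomass[comp] for t in sub])
        D = np.array([t.D for t in sub])
        H = np.array([t.H for t in sub])
        pred = predict_biomass(fs.params(), D, H, correction)
        stats.append(evaluate(obs, pred, component=comp, method=method))
    return stats


def run_pipeline(
    tree_csv: str | Path,
    equations_csv: str | Path,
    out_dir: str | Path,
    mcmc: McmcConfig | None = None,
    level: float = 0.95,
    correction: str = "none",
    save_draws: bool = False,
) -> PipelineResult:
    """Run the full workflow from CSV inputs to result files."""
    mcmc = mcmc or McmcConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees = read_trees_csv(tree_csv)
    equations = read_equations_csv(equations_csv)
    log.info("loaded %d trees, %d literature equations", len(trees), len(equations))

    fits, draws = fit_all(trees, equations, mcmc, level=level)
    stats = evaluate_all(trees, fits, correction=correction)

    additivity: dict[str, AdditivityReport] = {}
    methods = sorted({m for (_, m) in fits})
    for method in methods:
        comp_fits = {
            c: fits[(c, method)] for c in SUM_COMPONENTS if (c, method) in fits
        }
        if len(comp_fits) == len(SUM_COMPONENTS) and ("total", method) in fits:
            additivity[method] = additivity_compare(
                comp_fits, fits[("total", method)], trees, correction=correction
            )

    # --- write outputs
    fits_json = [fs.to_dict() for _, fs in sorted(fits.items())]
    (out / "fits.json").write_text(json.dumps(fits_json, indent=2, sort_keys=True))
    stats_table(stats).to_csv(out / "evaluation.csv")
    (out / "additivity.json").write_text(
        json.dumps(
            {
                m: {
                    "correlation": r.correlation,
                    "mean_bias_kg": r.mean_bias,
                    "relative_bias": r.relative_bias,
                    "n": int(r.at.size),
                }
                for m, r in sorted(additivity.items())
            },
            indent=2,
            sort_keys=True,
        )
    )
    if save_draws:
        for (comp, method), d in sorted(draws.items()):
            d.to_frame().to_csv(out / f"draws_{comp}_{method}.csv", index=False)

    manifest = {
        "inputs": {
            "tree_csv": {"path": str(tree_csv), "sha256": _sha256(Path(tree_csv))},
            "equations_csv": {
                "path": str(equations_csv),
                "sha256": _sha256(Path(equations_csv)),
            },
        },
        "mcmc": {
            "n_iter": mcmc.n_iter,
            "thin": mcmc.thin,
            "burn_in": mcmc.burn_in,
            "seed": mcmc.seed,
        },
        "level": level,
        "correction": correction,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote results to %s", out)
    return PipelineResult(fits=fits, stats=stats, additivity=additivity, draws=draws)


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> PipelineResult:
    """Re-run the pipeline exactly as recorded in a manifest."""
    m = json.loads(Path(manifest_path).read_text())
    mcmc = McmcConfig(**m["mcmc"])
    return run_pipeline(
        m["inputs"]["tree_csv"]["path"],
        m["inputs"]["equations_csv"]["path"],
        out_dir,
        mcmc=mcmc,
        level=m["level"],
        correction=m["correction"],
    )
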