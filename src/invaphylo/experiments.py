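"""Replicated simulation experiments: recovery, calibration, mediation.

These are the standard validation studies run on the synthetic generator:

* :func:`pipeline_relatedness_fit` — one full pipeline pass (classify →
  clean → metrics → records → GLMM) on a generated database, returning the
  fitted relatedness coefficient with its Wald interval;
* :func:`run_pipeline_battery` — that pass replicated over seeds, for
  sign-recovery and null-calibration (type-I error) summaries;
* :func:`run_glmm_coverage_battery` — replicated fits on records drawn
  directly from the Bernoulli mixed model, isolating estimator coverage
  from community-assembly selection effects;
* :func:`run_sem_battery` — replicated piecewise path-model fits on
  path-model draws, checking that products of standardized paths recover
  the programmed indirect effects.

Each battery derives per-replicate seeds from a base seed and returns a
tidy DataFrame, one row per replicate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classification import Scope, classify_nonnatives
from .inference import ModelSpec, SEMConfig, fit_occurrence_glmm, fit_sem
from .phylometrics import cophenetic_distances, prune_to_database
from .record_builder import build_records, clean_database, standardize_records
from .synthetic_data import (
    GeneratorConfig,
    simulate_database,
    simulate_glmm_records,
    simulate_sem_records,
)


def _rep_seed(base_seed: int, i: int) -> int:
    return int((base_seed + 7_919 * (i + 1)) % 2**31)


def pipeline_relatedness_fit(
    config: GeneratorConfig,
    scope: Scope = Scope.COUNTRY,
    predictor: str = "mpd",
    groups: tuple[str, ...] = ("exotic", "translocated"),
) -> dict:
    """Generate one database and fit the occurrence GLMM on its records.

    Exotic and translocated tables are concatenated and re-standardized
    jointly, matching the generator's single establishment model across
    both introduction modes.
    """
    db, tree, truth = simulate_database(config)
    assignment = classify_nonnatives(db, scope)
    cleaned, _ = clean_database(db, assignment, tree)
    assignment = classify_nonnatives(cleaned, scope)
    pruned, _ = prune_to_database(tree, cleaned)
    D = cophenetic_distances(pruned)
    parts = []
    for group in groups:
        try:
            parts.append(build_records(cleaned, assignment, D, group))
        except ValueError:
            continue  # group absent in this replicate
    table = standardize_records(pd.concat(parts, ignore_index=True))
    term = f"{predictor}_z"
    fit = fit_occurrence_glmm(table, ModelSpec(predictors=[term]))
    i = fit.mixed.terms.index(term)
    lo, hi = fit.mixed.wald_interval(term)
    return {
        "estimate": float(fit.mixed.beta[i]),
        "lower": float(lo),
        "upper": float(hi),
        "p": float(fit.mixed.pvalues[i]),
        "n": int(fit.n),
        "r2_marginal": float(fit.r2_marginal),
        "r2_conditional": float(fit.r2_conditional),
        "converged": bool(fit.converged),
        "truth": float(config.beta_relatedness),
    }


def run_pipeline_battery(
    n_reps: int,
    base_seed: int,
    config: GeneratorConfig | None = None,
    scope: Scope = Scope.COUNTRY,
    predictor: str = "mpd",
) -> pd.DataFrame:
    """Replicate the end-to-end pipeline fit over seeded generator runs."""
    config = config or GeneratorConfig()
    rows = []
    for i in range(n_reps):
        cfg = replace(config, seed=_rep_seed(base_seed, i))
        row = pipeline_relatedness_fit(cfg, scope=scope, predictor=predictor)
        row["seed"] = cfg.seed
        rows.append(row)
    return pd.DataFrame(rows)


def run_glmm_coverage_battery(
    n_reps: int,
    base_seed: int,
    beta_relatedness: float = -0.5,
    **sim_kwargs,
) -> pd.DataFrame:
    """Replicated GLMM fits on direct draws from the Bernoulli mixed model."""
    rows = []
    for i in range(n_reps):
        seed = _rep_seed(base_seed, i)
        records = simulate_glmm_records(
            seed, beta={"mpd_z": beta_relatedness}, **sim_kwargs
        )
        fit = fit_occurrence_glmm(records, ModelSpec(predictors=["mpd_z"]))
        k = fit.mixed.terms.index("mpd_z")
        lo, hi = fit.mixed.wald_interval("mpd_z")
        rows.append(
            {
                "seed": seed,
                "estimate": float(fit.mixed.beta[k]),
                "lower": float(lo),
                "upper": float(hi),
                "p": float(fit.mixed.pvalues[k]),
                "covered": bool(lo <= beta_relatedness <= hi),
                "converged": bool(fit.converged),
                "truth": beta_relatedness,
            }
        )
    return pd.DataFrame(rows)


def run_sem_battery(
    n_reps: int,
    base_seed: int,
    **sim_kwargs,
) -> pd.DataFrame:
    """Replicated piecewise path-model fits on path-model draws."""
    rows = []
    for i in range(n_reps):
        seed = _rep_seed(base_seed, i)
        table, truth = simulate_sem_records(seed, **sim_kwargs)
        sem = fit_sem(table, SEMConfig(diversity="mpd"))
        eff = sem.indirect_effects["native_richness_z"]
        rows.append(
            {
                "seed": seed,
                "indirect_richness": float(eff["estimate"]),
                "lower": float(eff["lower"]),
                "upper": float(eff["upper"]),
                "covered": bool(
                    eff["lower"] <= truth["indirect_richness"] <= eff["upper"]
                ),
                "truth": float(truth["indirect_richness"]),
            }
        )
    return pd.DataFrame(rows)


def summarize_battery(battery: pd.DataFrame, truth: float | None = None) -> dict:
    """Headline rates of a battery: sign recovery, coverage, rejection."""
    out = {
        "n_reps": int(len(battery)),
        "mean_estimate": float(battery.filter(regex="estimate|indirect").iloc[:, 0].mean()),
        "rejection_rate": float((battery["p"] < 0.05).mean()) if "p" in battery else None,
    }
    est = battery.filter(regex="estimate|indirect").iloc[:, 0]
    if truth is not None:
        out["sign_recovery_rate"] = float((np.sign(est) == np.sign(truth)).mean())
        out["coverage"] = float(
            ((battery["lower"] <= truth) & (battery["upper"] >= truth)).mean()
        )
    return out
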