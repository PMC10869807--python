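"""Occurrence models: binomial GLMMs, Nakagawa R², VIF, and mediation.

The central model is a Bernoulli mixed model for establishment,

    g(p_ib) = beta0 + beta1 * relatedness_z + ... + u_species + u_country + u_basin,

with a logit link by default and a cloglog link when successes are rare.
Random intercepts for species and for basin nested in country absorb the
non-independence of the many records contributed by one species and by one
basin; single-country fits use species and basin only.

Variance explained is decomposed following Nakagawa & Schielzeth into a
marginal R² (fixed effects) and a conditional R² (fixed plus random), using
the link-specific distribution variance (π²/3 for logit, π²/6 for cloglog).

The mediation analysis re-expresses the path diagram relating native
richness, native phylogenetic diversity, nonnative–native relatedness, and
occurrence as two piecewise component models sharing the random-effect
structure: a Gaussian model for relatedness and a Bernoulli model for
presence.  Indirect effects are products of standardized paths through
relatedness; their intervals use the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import CLOGLOG, LOGIT, MixedModelFit, add_intercept, fit_mixed_model

#: link-specific distribution variance of the latent residual
DISTRIBUTION_VARIANCE = {LOGIT: math.pi**2 / 3.0, CLOGLOG: math.pi**2 / 6.0}

RELATEDNESS_PREDICTORS = ("mpd_z", "mntd_z")


@dataclass
class ModelSpec:
    """Fixed and random structure of one occurrence model."""

    predictors: list[str]
    link: str = LOGIT
    random_effects: tuple[str, ...] = ("species", "country", "basin")

    def __post_init__(self) -> None:
        n_rel = sum(p in RELATEDNESS_PREDICTORS for p in self.predictors)
        if n_rel != 1:
            raise ValueError(
                "exactly one relatedness predictor (mpd_z or mntd_z) per fit; "
                f"got {self.predictors}"
            )
        if self.link not in (LOGIT, CLOGLOG):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass
class ModelFit:
    """A fitted occurrence model with its variance decomposition."""

    spec: ModelSpec
    mixed: MixedModelFit
    r2_marginal: float
    r2_conditional: float

    @property
    def coefficients(self) -> pd.DataFrame:
        return self.mixed.coef_table()

    @property
    def n(self) -> int:
        return self.mixed.n

    @property
    def converged(self) -> bool:
        return self.mixed.converged

    def manifest(self) -> dict:
        return {
            "predictors": list(self.spec.predictors),
            "link": self.mixed.link,
            "n": int(self.mixed.n),
            "loglik": float(self.mixed.loglik),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "random_sd": {k: float(v) for k, v in self.mixed.sd.items()},
            "converged": bool(self.mixed.converged),
        }


def _random_groups(records: pd.DataFrame, names: tuple[str, ...]) -> dict:
    groups = {}
    for name in names:
        if name == "basin":
            # basin ids are globally unique, which encodes nesting in country
            groups["basin"] = records["basin_id"].to_numpy()
        else:
            groups[name] = records[name].to_numpy()
    return groups


def fit_occurrence_glmm(records: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit presence ~ predictors with the spec's random intercepts.

    Rows with NaN in any predictor are dropped (logged in diagnostics).
    """
    cols = list(spec.predictors)
    use = records.dropna(subset=cols)
    n_dropped = len(records) - len(use)
    y = use["presence"].to_numpy(dtype=float)
    X = add_intercept(use[cols])
    groups = _random_groups(use, spec.random_effects)
    mixed = fit_mixed_model(y, X, groups, family="binomial", link=spec.link)
    mixed.diagnostics["rows_dropped_nan"] = n_dropped
    r2m, r2c = r2_nakagawa(mixed)
    return ModelFit(spec=spec, mixed=mixed, r2_marginal=r2m, r2_conditional=r2c)


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R² for a mixed model.

    R²_marginal = σ²_f / (σ²_f + Σ σ²_u + σ²_d) and
    R²_conditional = (σ²_f + Σ σ²_u) / (σ²_f + Σ σ²_u + σ²_d), where σ²_f is
    the variance of the fixed-effect linear predictor across the data and
    σ²_d is the link-specific distribution variance (the Gaussian residual
    variance for a Gaussian response).
    """
    if fit.fixed_linpred is None:
        raise ValueError("model has not been fitted")
    sigma2_f = float(np.var(fit.fixed_linpred, ddof=1)) if fit.n > 1 else 0.0
    sigma2_u = float(sum(fit.variance_components.values()))
    if fit.family == "gaussian":
        sigma2_d = float(fit.sigma) ** 2
    else:
        sigma2_d = DISTRIBUTION_VARIANCE[fit.link]
    total = sigma2_f + sigma2_u + sigma2_d
    return sigma2_f / total, (sigma2_f + sigma2_u) / total


def r2_nakagawa_components(
    sigma2_fixed: float, sigma2_random: float, link: str = LOGIT
) -> tuple[float, float]:
    """Closed-form Nakagawa R² from hand-set variance components."""
    sigma2_d = DISTRIBUTION_VARIANCE[link]
    total = sigma2_fixed + sigma2_random + sigma2_d
    return sigma2_fixed / total, (sigma2_fixed + sigma2_random) / total


def vif(records: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factors: VIF_k = 1 / (1 − R²_k).

    R²_k comes from the OLS regression (with intercept) of predictor k on
    the remaining predictors.  Exact collinearity yields ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    use = records.dropna(subset=predictors)
    out = {}
    for k in predictors:
        yk = use[k].to_numpy(dtype=float)
        if np.std(yk) == 0:
            raise ValueError(f"predictor {k!r} is constant")
        others = [p for p in predictors if p != k]
        Xk = np.column_stack(
            [np.ones(len(use))] + [use[p].to_numpy(dtype=float) for p in others]
        )
        coef, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yk - yk.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        out[k] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def choose_link(records: pd.DataFrame, threshold: float = 0.10) -> str:
    """Pick cloglog when successes are rare, logit otherwise.

    The asymmetric cloglog link mitigates bias when the response contains
    far more zeros than ones.  The observed success fraction and the
    decision are returned via the module logger-free contract: callers log
    them from the manifest.
    """
    frac = float(records["presence"].mean())
    return CLOGLOG if frac < threshold else LOGIT


# --------------------------------------------------------------------------
# piecewise structural equation model


@dataclass
class SEMFit:
    """Piecewise path model: predictors → relatedness → presence.

    ``paths`` holds every standardized path with its 95% interval;
    ``direct_effects`` are the paths into presence; ``indirect_effects`` are
    products of the path into relatedness and the relatedness → presence
    path, with delta-method intervals.
    """

    diversity_metric: str
    relatedness_var: str
    paths: pd.DataFrame
    direct_effects: dict[str, dict]
    indirect_effects: dict[str, dict]
    component_fits: dict[str, ModelFit | MixedModelFit] = field(default_factory=dict)
    r2_conditional: dict[str, float] = field(default_factory=dict)
    n: int = 0
    rows_dropped: int = 0


@dataclass
class SEMConfig:
    """Pairing of diversity index with the matching relatedness metric."""

    diversity: str = "mpd"  # 'mpd' -> native_mpd_z & mpd_z; 'mntd' analogous
    link: str = LOGIT

    def __post_init__(self) -> None:
        if self.diversity not in ("mpd", "mntd"):
            raise ValueError("diversity must be 'mpd' or 'mntd'")


def fit_sem(
    records: pd.DataFrame,
    config: SEMConfig,
    *,
    interval: str = "delta",
    n_draws: int = 2000,
    seed: int = 0,
) -> SEMFit:
    """Fit the two component models and assemble direct/indirect effects.

    Component (i): relatedness_z ~ richness_z + native_diversity_z
    (Gaussian); component (ii): presence ~ relatedness_z + richness_z +
    native_diversity_z (Bernoulli).  Both share random intercepts for
    species, country, and basin.  Rows lacking the diversity covariates
    (basins with fewer than two natives) are dropped and counted.

    ``interval`` selects the uncertainty method for indirect effects:
    ``"delta"`` (first-order, default) or ``"montecarlo"`` (seeded draws
    from the asymptotic distribution of each path; percentile interval of
    the products, second-order accurate for products near zero).
    """
    if interval not in ("delta", "montecarlo"):
        raise ValueError(f"unknown interval method {interval!r}")
    rel = f"{config.diversity}_z"
    div = f"native_{config.diversity}_z"
    rich = "native_richness_z"
    for col in (rel, div, rich):
        if col not in records.columns:
            raise ValueError(f"records table lacks required column {col!r}")
    use = records.dropna(subset=[rel, div, rich])
    dropped = len(records) - len(use)
    if use.empty:
        raise ValueError("no rows left after dropping undefined diversity values")

    groups = _random_groups(use, ("species", "country", "basin"))

    # (i) Gaussian mediator model
    Xg = add_intercept(use[[rich, div]])
    med = fit_mixed_model(
        use[rel].to_numpy(dtype=float), Xg, groups, family="gaussian"
    )
    # (ii) Bernoulli outcome model
    Xb = add_intercept(use[[rel, rich, div]])
    out = fit_mixed_model(
        use["presence"].to_numpy(dtype=float),
        Xb,
        groups,
        family="binomial",
        link=config.link,
    )

    def row(fit: MixedModelFit, term: str, response: str) -> dict:
        i = fit.terms.index(term)
        lo, hi = fit.wald_interval(term)
        return {
            "from": term,
            "to": response,
            "estimate": float(fit.beta[i]),
            "se": float(fit.se[i]),
            "lower": float(lo),
            "upper": float(hi),
            "p": float(fit.pvalues[i]),
        }

    paths = pd.DataFrame(
        [
            row(med, rich, rel),
            row(med, div, rel),
            row(out, rel, "presence"),
            row(out, rich, "presence"),
            row(out, div, "presence"),
        ]
    )

    direct = {
        t: {
            "estimate": float(out.beta[out.terms.index(t)]),
            "lower": out.wald_interval(t)[0],
            "upper": out.wald_interval(t)[1],
        }
        for t in (rel, rich, div)
    }

    b_rel = float(out.beta[out.terms.index(rel)])
    se_rel = float(out.se[out.terms.index(rel)])
    rng = np.random.default_rng(seed)
    indirect = {}
    for t in (rich, div):
        a = float(med.beta[med.terms.index(t)])
        se_a = float(med.se[med.terms.index(t)])
        est = a * b_rel
        # delta-method SE of the product of two (independent-component) paths
        se = math.sqrt(a * a * se_rel * se_rel + b_rel * b_rel * se_a * se_a)
        if interval == "montecarlo":
            prods = rng.normal(a, se_a, n_draws) * rng.normal(b_rel, se_rel, n_draws)
            lo, hi = np.percentile(prods, [2.5, 97.5])
        else:
            lo = est - 1.959963984540054 * se
            hi = est + 1.959963984540054 * se
        indirect[t] = {
            "estimate": est,
            "lower": float(lo),
            "upper": float(hi),
            "se": se,
            "interval": interval,
        }

    r2c = {
        rel: r2_nakagawa(med)[1],
        "presence": r2_nakagawa(out)[1],
    }
    return SEMFit(
        diversity_metric=config.diversity,
        relatedness_var=rel,
        paths=paths,
        direct_effects=direct,
        indirect_effects=indirect,
        component_fits={"mediator": med, "outcome": out},
        r2_conditional=r2c,
        n=len(use),
        rows_dropped=dropped,
    )
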