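"""Mixed models with crossed/nested Gaussian random intercepts.

Fits Bernoulli (logit or cloglog link) and Gaussian responses with any
number of random-intercept grouping factors by maximising the Laplace
approximation to the marginal likelihood:

    log L(beta, theta) ≈ log p(y | eta(beta, u_hat))
                         − ½ u_hat' G⁻¹ u_hat − ½ log|G| − ½ log|H|

where u_hat is the conditional mode of the random effects (found by Newton
iteration), G = blockdiag(sd_g² I) and H = Z'WZ + G⁻¹ is the negative
Hessian of the joint log-density at the mode.  For a Gaussian response the
Laplace approximation is exact, so the same engine serves both the
Bernoulli occurrence models and the Gaussian mediator model of the path
analysis.

The outer optimisation runs L-BFGS-B on (beta, log sd_g, [log sigma]) with
finite-difference gradients; fixed-effect standard errors use the standard
conditional (Schur-complement) information matrix

    Var(beta) = (X'WX − X'WZ H⁻¹ Z'WX)⁻¹

evaluated at the optimum, matching the Wald machinery of lme4.

Design matrices are plain 2-D arrays or DataFrames; grouping factors are
passed as label arrays and coded internally.  Because every Z column is an
indicator, Z'WZ and Z'v are accumulated with bincount-style reductions and
the engine never materialises Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOGIT = "logit"
CLOGLOG = "cloglog"
IDENTITY = "identity"

_ETA_CLIP = 30.0
_LOG_SD_MIN, _LOG_SD_MAX = -8.0, 5.0


class DesignError(ValueError):
    pass


def _bernoulli_logit(y: np.ndarray, eta: np.ndarray):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    d1 = y - mu
    d2 = -mu * (1.0 - mu)
    return ll, d1, d2, mu


def _bernoulli_cloglog(y: np.ndarray, eta: np.ndarray):
    # mu = 1 - exp(-t), t = exp(eta); stable via expm1/log1p
    eta = np.clip(eta, -_ETA_CLIP, 3.0)  # t = e^3 ~ 20 -> mu ~ 1-2e-9
    t = np.exp(eta)
    log_mu = np.log(-np.expm1(-t))
    log_1m_mu = -t
    ll = np.sum(y * log_mu + (1.0 - y) * log_1m_mu)
    mu = -np.expm1(-t)
    # d logp/deta = y * t e^{-t}/mu - (1-y) t
    emt = np.exp(-t)
    f = t * emt / mu
    d1 = y * f - (1.0 - y) * t
    # df/deta = t * d/dt [t e^{-t}/(1-e^{-t})]
    dfdt = emt * ((1.0 - t) / mu - t * emt / mu**2)
    d2 = y * t * dfdt - (1.0 - y) * t
    return ll, d1, d2, mu


def _gaussian(y: np.ndarray, eta: np.ndarray, sigma: float):
    r = y - eta
    s2 = sigma * sigma
    ll = -0.5 * np.sum(r * r) / s2 - 0.5 * len(y) * np.log(2.0 * np.pi * s2)
    d1 = r / s2
    d2 = np.full_like(y, -1.0 / s2)
    return ll, d1, d2, eta


@dataclass
class RandomGrouping:
    name: str
    codes: np.ndarray  # 0..n_levels-1 per row
    levels: np.ndarray  # original labels


@dataclass
class MixedModelFit:
    """Result of a Laplace mixed-model fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    sd: dict[str, float]  # random-intercept SDs by grouping name
    sigma: float | None  # Gaussian residual SD (None for Bernoulli)
    loglik: float
    n: int
    family: str
    link: str
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    ranef: dict[str, pd.Series] = field(default_factory=dict)
    fixed_linpred: np.ndarray | None = None

    @property
    def variance_components(self) -> dict[str, float]:
        return {k: v * v for k, v in self.sd.items()}

    def wald_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        i = self.terms.index(term)
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.beta[i] - z * self.se[i], self.beta[i] + z * self.se[i])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.terms,
        )


def _code_groups(groups: dict[str, np.ndarray], n: int) -> list[RandomGrouping]:
    coded = []
    for name, labels in groups.items():
        labels = np.asarray(labels)
        if len(labels) != n:
            raise DesignError(f"grouping {name!r} length mismatch")
        levels, codes = np.unique(labels, return_inverse=True)
        if len(levels) < 2:
            raise DesignError(
                f"grouping {name!r} has {len(levels)} level(s); need >= 2"
            )
        coded.append(RandomGrouping(name=name, codes=codes, levels=levels))
    return coded


class _LaplaceProblem:
    def __init__(self, y, X, groupings, family, link):
        self.y = y
        self.X = X
        self.groupings = groupings
        self.family = family
        self.link = link
        self.offsets = []
        off = 0
        for g in groupings:
            self.offsets.append(off)
            off += len(g.levels)
        self.q = off
        self.u = np.zeros(self.q)
        # all-pairs code products for Z'WZ accumulation
        self._n = len(y)

    def loglik_parts(self, eta, sigma):
        if self.family == "gaussian":
            return _gaussian(self.y, eta, sigma)
        if self.link == LOGIT:
            return _bernoulli_logit(self.y, eta)
        return _bernoulli_cloglog(self.y, eta)

    def _zu(self, u):
        out = np.zeros(self._n)
        for g, off in zip(self.groupings, self.offsets):
            out += u[off + g.codes]
        return out

    def _zt(self, v):
        out = np.empty(self.q)
        for g, off in zip(self.groupings, self.offsets):
            out[off : off + len(g.levels)] = np.bincount(
                g.codes, weights=v, minlength=len(g.levels)
            )
        return out

    def _ztwz(self, w):
        H = np.zeros((self.q, self.q))
        for a, (ga, offa) in enumerate(zip(self.groupings, self.offsets)):
            na = len(ga.levels)
            H[offa : offa + na, offa : offa + na][np.diag_indices(na)] += np.bincount(
                ga.codes, weights=w, minlength=na
            )
            for gb, offb in list(zip(self.groupings, self.offsets))[a + 1 :]:
                nb = len(gb.levels)
                block = np.zeros((na, nb))
                np.add.at(block, (ga.codes, gb.codes), w)
                H[offa : offa + na, offb : offb + nb] += block
                H[offb : offb + nb, offa : offa + na] += block.T
        return H

    def _ztwx(self, w):
        p = self.X.shape[1]
        out = np.empty((self.q, p))
        for j in range(p):
            out[:, j] = self._zt(w * self.X[:, j])
        return out

    def ginv_diag(self, sds):
        d = np.empty(self.q)
        for g, off, sd in zip(self.groupings, self.offsets, sds):
            d[off : off + len(g.levels)] = 1.0 / (sd * sd)
        return d

    def solve_mode(self, beta, sds, sigma, max_iter=50, tol=1e-9):
        """Newton iteration for the conditional mode of u (warm-started)."""
        xb = self.X @ beta
        ginv = self.ginv_diag(sds)
        u = self.u.copy()
        ll, d1, d2, _ = self.loglik_parts(xb + self._zu(u), sigma)
        obj = ll - 0.5 * np.sum(ginv * u * u)
        for _ in range(max_iter):
            grad = self._zt(d1) - ginv * u
            gnorm = np.max(np.abs(grad))
            if gnorm < tol:
                break
            w = -d2
            w = np.maximum(w, 1e-10)
            H = self._ztwz(w)
            H[np.diag_indices(self.q)] += ginv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / (np.diag(H) + 1e-8)
            # backtracking line search on the joint log-density
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                ll, d1n, d2n, _ = self.loglik_parts(xb + self._zu(u_new), sigma)
                obj_new = ll - 0.5 * np.sum(ginv * u_new * u_new)
                if obj_new >= obj - 1e-12:
                    u, obj, d1, d2 = u_new, obj_new, d1n, d2n
                    break
                t *= 0.5
            else:
                break
        self.u = u
        return u, obj, d1, d2, ginv

    def laplace_nll(self, beta, sds, sigma):
        u, obj, d1, d2, ginv = self.solve_mode(beta, sds, sigma)
        w = np.maximum(-d2, 1e-10)
        H = self._ztwz(w)
        H[np.diag_indices(self.q)] += ginv
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        logdetG = -np.sum(np.log(ginv))
        return -(obj - 0.5 * logdetG - 0.5 * logdetH)


def fit_mixed_model(
    y,
    X: pd.DataFrame | np.ndarray,
    groups: dict,
    *,
    family: str = "binomial",
    link: str = LOGIT,
    tol: float = 1e-6,
    maxiter: int = 400,
    fix_sd: dict | None = None,
) -> MixedModelFit:
    """Fit a random-intercept mixed model by Laplace maximum likelihood.

    Parameters
    ----------
    y
        Response vector: 0/1 for ``family="binomial"``, real-valued for
        ``family="gaussian"``.
    X
        Fixed-effect design matrix; a DataFrame contributes column names as
        coefficient labels.  Must include an intercept column if one is
        wanted (see :func:`add_intercept`).
    groups
        Mapping of grouping-factor name to a label array (one label per
        row).  Each factor contributes one independent Gaussian random
        intercept per level.  Nested factors (basin within country) are
        expressed by passing the nested factor with globally unique labels.
    family, link
        ``binomial`` with ``logit``/``cloglog``, or ``gaussian``.
    fix_sd
        Optional mapping of grouping name to a fixed random-intercept SD
        that is held out of the optimisation (an SD pinned near zero
        reduces the model to its fixed-effects GLM).
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        terms = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if len(y) != n:
        raise DesignError("response/design length mismatch")
    if np.linalg.matrix_rank(Xm) < p:
        raise DesignError(
            "fixed-effect design matrix is rank deficient "
            "(constant or collinear predictor column)"
        )
    if family == "binomial":
        if link not in (LOGIT, CLOGLOG):
            raise DesignError(f"unknown binomial link {link!r}")
        if y.min() == y.max():
            raise DesignError("response is all-0 or all-1; nothing to fit")
    elif family == "gaussian":
        link = IDENTITY
    else:
        raise DesignError(f"unknown family {family!r}")

    groupings = _code_groups(groups, n)
    prob = _LaplaceProblem(y, Xm, groupings, family, link)
    fix_sd = fix_sd or {}
    unknown = set(fix_sd) - {grp.name for grp in groupings}
    if unknown:
        raise DesignError(f"fix_sd names unknown grouping(s): {sorted(unknown)}")
    free_idx = [i for i, grp in enumerate(groupings) if grp.name not in fix_sd]
    fixed_sds = np.array(
        [fix_sd.get(grp.name, np.nan) for grp in groupings], dtype=float
    )
    g = len(free_idx)

    # warm start from the fixed-effects-only model
    import statsmodels.api as sm

    if family == "binomial":
        smlink = sm.families.links.Logit() if link == LOGIT else sm.families.links.CLogLog()
        glm = sm.GLM(y, Xm, family=sm.families.Binomial(link=smlink))
        try:
            beta0 = glm.fit(maxiter=100).params
        except Exception:
            beta0 = np.zeros(p)
        x0 = np.concatenate([beta0, np.full(g, np.log(0.1))])
    else:
        beta0, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid_sd = max(np.std(y - Xm @ beta0, ddof=p), 1e-6)
        x0 = np.concatenate([beta0, np.full(g, np.log(0.1)), [np.log(resid_sd)]])

    def unpack(params):
        beta = params[:p]
        sds = fixed_sds.copy()
        sds[free_idx] = np.exp(np.clip(params[p : p + g], _LOG_SD_MIN, _LOG_SD_MAX))
        sds = np.maximum(sds, np.exp(_LOG_SD_MIN))
        sigma = np.exp(params[p + g]) if family == "gaussian" else None
        return beta, sds, sigma

    def objective(params):
        beta, sds, sigma = unpack(params)
        return prob.laplace_nll(beta, sds, sigma)

    bounds = [(None, None)] * p + [(_LOG_SD_MIN, _LOG_SD_MAX)] * g
    if family == "gaussian":
        bounds += [(-10.0, 10.0)]
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": tol},
    )
    beta, sds, sigma = unpack(res.x)

    # final conditional mode and Wald covariance of beta
    u, _, d1, d2, ginv = prob.solve_mode(beta, sds, sigma)
    w = np.maximum(-d2, 1e-10)
    H = prob._ztwz(w)
    H[np.diag_indices(prob.q)] += ginv
    XtWX = Xm.T @ (Xm * w[:, None])
    ZtWX = prob._ztwx(w)
    info = XtWX - ZtWX.T @ np.linalg.solve(H, ZtWX)
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))

    sd_map = {grp.name: float(s) for grp, s in zip(groupings, sds)}
    ranef = {}
    for grp, off in zip(groupings, prob.offsets):
        ranef[grp.name] = pd.Series(
            u[off : off + len(grp.levels)], index=grp.levels, name=grp.name
        )
    converged = bool(res.success) or res.status == 0
    return MixedModelFit(
        terms=terms,
        beta=beta,
        se=se,
        zvalues=zvals,
        pvalues=pvals,
        sd=sd_map,
        sigma=float(sigma) if sigma is not None else None,
        loglik=float(-res.fun),
        n=n,
        family=family,
        link=link,
        converged=converged,
        diagnostics={
            "optimizer_message": str(res.message),
            "n_obj_evals": int(res.nfev),
            "vcov_beta": vcov,
        },
        ranef=ranef,
        fixed_linpred=Xm @ beta,
    )


def add_intercept(X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    out.insert(0, "(Intercept)", 1.0)
    return out
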