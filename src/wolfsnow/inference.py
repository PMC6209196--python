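"""Candidate mixed models, AIC selection tables, and parametric bootstrap.

Two movement metrics are modeled against snowfall covariates:

* travel speed — linear mixed model on log10(m/min) of travel steps only,
  with a by-wolf random intercept and random slope over time of day
  (unstructured 2x2 covariance), fit by maximum likelihood so AIC compares
  fixed-effect structures;
* time spent travelling — logistic mixed model on the 0/1 rest/travel label
  with a by-wolf random intercept, fit by adaptive Gauss-Hermite quadrature
  (a refinement of the Laplace approximation).

The candidate set is all combinations of ``snowfall_category``,
``time_of_day`` and ``snow_depth`` plus the category-by-time interaction
(10 models). Reference levels are ``day_of_snowfall`` and ``day``, so the
intercept is the event-day daytime mean and every other category appears as a
contrast against the snowfall day. Model parameter counts K include the
variance components (LMM: 2 variances + 1 covariance + residual; GLMM: 1
variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .windows import CATEGORY_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "candidate_models",
    "build_design",
    "fit_speed_model",
    "fit_travel_model",
    "selection_table",
    "select_best",
    "parametric_bootstrap_ci",
    "back_transform",
]

CATEGORY_CONTRASTS = [c for c in CATEGORY_ORDER if c != "day_of_snowfall"]

#: The 10 candidate fixed-effect structures, in the order they are reported.
CANDIDATE_TERMS: list[tuple[frozenset, bool]] = [
    (frozenset(), False),
    (frozenset({"snow_depth"}), False),
    (frozenset({"time_of_day"}), False),
    (frozenset({"snowfall_category"}), False),
    (frozenset({"time_of_day", "snow_depth"}), False),
    (frozenset({"snowfall_category", "snow_depth"}), False),
    (frozenset({"snowfall_category", "time_of_day"}), False),
    (frozenset({"snowfall_category", "time_of_day", "snow_depth"}), False),
    (frozenset({"snowfall_category", "time_of_day"}), True),
    (frozenset({"snowfall_category", "time_of_day", "snow_depth"}), True),
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, and random structure."""

    response: str  # 'log10_speed' or 'behavior'
    terms: frozenset
    interaction: bool
    random_structure: str  # 'intercept_by_wolf' or 'intercept_and_timeofday_slope_by_wolf'

    def __post_init__(self):
        if self.interaction and not {"snowfall_category", "time_of_day"} <= self.terms:
            raise ValueError("interaction requires both snowfall_category and time_of_day")
        if self.response not in {"log10_speed", "behavior"}:
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def formula(self) -> str:
        if not self.terms:
            return "Null model"
        if self.interaction:
            parts = ["snowfall_category * time_of_day"]
            if "snow_depth" in self.terms:
                parts.append("snow_depth")
        else:
            order = ["snowfall_category", "time_of_day", "snow_depth"]
            parts = [t for t in order if t in self.terms]
        return " + ".join(parts)


@dataclass
class FitResult:
    """A fitted candidate model with everything selection and bootstrap need."""

    spec: ModelSpec
    K: int
    loglik: float
    params: pd.Series          # fixed effects, design order
    se: pd.Series
    random_effects: dict       # LMM: cov_re (2x2), scale; GLMM: sigma
    converged: bool
    n_obs: int
    _design: tuple = field(default=None, repr=False)  # (X, names, groups, y) for bootstrap

    @property
    def aic(self) -> float:
        return 2 * self.K - 2 * self.loglik


def n_fixed_coefficients(spec: ModelSpec) -> int:
    """Number of fixed-effect columns (intercept + contrasts) for a spec."""
    p = 1
    if "time_of_day" in spec.terms:
        p += 1
    if "snowfall_category" in spec.terms:
        p += len(CATEGORY_CONTRASTS)
        if spec.interaction:
            p += len(CATEGORY_CONTRASTS)
    if "snow_depth" in spec.terms:
        p += 1
    return p


def expected_K(spec: ModelSpec) -> int:
    """Parameter count K under the selection-table convention.

    Fixed coefficients plus variance components: the LMM random
    intercept-and-slope structure contributes 2 variances + 1 covariance + 1
    residual variance; the GLMM random intercept contributes 1 variance.
    """
    p = n_fixed_coefficients(spec)
    if spec.random_structure == "intercept_and_timeofday_slope_by_wolf":
        return p + 4
    return p + 1


def candidate_models(response: str) -> list[ModelSpec]:
    """The 10-model candidate set for one response.

    Speed models carry the random intercept + time-of-day slope structure;
    travel (behavior) models carry the random intercept.
    """
    random = (
        "intercept_and_timeofday_slope_by_wolf"
        if response == "log10_speed"
        else "intercept_by_wolf"
    )
    return [
        ModelSpec(response=response, terms=t, interaction=ia, random_structure=random)
        for t, ia in CANDIDATE_TERMS
    ]


def build_design(df: pd.DataFrame, terms: frozenset, interaction: bool):
    """Fixed-effects design matrix with the study's reference levels.

    Columns: intercept; ``time_of_day: night``; the six category contrasts
    against ``day_of_snowfall``; ``night x category`` interactions; and raw
    ``snow_depth`` in cm. Returns ``(X, names)``.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    night = (df["time_of_day"].to_numpy() == "night").astype(float) if "time_of_day" in df else None
    if "time_of_day" in terms:
        cols.append(night)
        names.append("time_of_day: night")
    if "snowfall_category" in terms:
        cat = df["snowfall_category"].to_numpy()
        for c in CATEGORY_CONTRASTS:
            cols.append((cat == c).astype(float))
            names.append(f"snowfall_category: {c}")
        if interaction:
            for c in CATEGORY_CONTRASTS:
                cols.append(night * (cat == c).astype(float))
                names.append(f"night x {c}")
    if "snow_depth" in terms:
        cols.append(df["depth_cm"].to_numpy(dtype=float))
        names.append("snow_depth")
    return np.column_stack(cols), names


def _prepare(df: pd.DataFrame, spec: ModelSpec):
    data = df
    if "snow_depth" in spec.terms:
        data = data[data["depth_cm"].notna()]
    if spec.response == "log10_speed":
        data = data[data["behavior"] == "travel"]
        y = data["log10_speed"].to_numpy(dtype=float)
    else:
        y = data["travel"].to_numpy(dtype=float)
    X, names = build_design(data, spec.terms, spec.interaction)
    groups = data["wolf_id"].to_numpy()
    return y, X, names, groups


# ---------------------------------------------------------------------------
# Linear mixed model (travel speed)
# ---------------------------------------------------------------------------

def _fit_lmm_robust(model: MixedLM, maxiter: int = 500,
                    methods: tuple = ("lbfgs", "powell", "nm"),
                    stop_at_first: bool = False):
    """ML fit trying several optimizers; best finite log-likelihood wins.

    MixedLM profiles the fixed effects out, so the optimization runs over the
    three variance-structure parameters only; Powell and Nelder-Mead are
    slower per step but markedly more reliable near flat or singular regions.
    With ``stop_at_first`` (bootstrap refits) the first converged finite fit
    is returned without consulting the remaining optimizers.
    """
    best, best_conv = None, False
    for method in methods:
        try:
            res = model.fit(reml=False, method=method, maxiter=maxiter)
        except Exception:  # noqa: BLE001 - try the next optimizer
            continue
        if not np.isfinite(res.llf) or not np.all(np.isfinite(res.fe_params)):
            continue  # degenerate optimum (singular covariance blow-up)
        if best is None or res.llf > best.llf + 1e-9:
            best, best_conv = res, bool(res.converged)
        elif res.converged and abs(res.llf - best.llf) < 1e-6:
            best_conv = True
        if stop_at_first and best_conv:
            break
    if best is None:
        raise RuntimeError("linear mixed model failed under every optimizer")
    return best, best_conv


def fit_speed_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """ML linear mixed model for log10 travel speed.

    Rows are restricted to travel steps (and to depth-complete cases when the
    spec includes snow depth). The random structure is a by-wolf intercept and
    time-of-day slope with unstructured covariance; K counts the fixed
    coefficients plus 3 random-effect (co)variances plus the residual
    variance.
    """
    if spec.response != "log10_speed":
        raise ValueError("fit_speed_model expects a log10_speed spec")
    y, X, names, groups = _prepare(df, spec)
    # random-effects design: intercept + night indicator (always, regardless
    # of whether night is a fixed term — the random structure is fixed by spec)
    data = df[df["behavior"] == "travel"]
    if "snow_depth" in spec.terms:
        data = data[data["depth_cm"].notna()]
    exog_re = np.column_stack([
        np.ones(len(data)),
        (data["time_of_day"].to_numpy() == "night").astype(float),
    ])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        res, converged = _fit_lmm_robust(model)

    k = expected_K(spec)
    params = pd.Series(res.fe_params, index=names)
    se = pd.Series(res.bse_fe, index=names)
    return FitResult(
        spec=spec, K=k, loglik=float(res.llf), params=params, se=se,
        random_effects={"cov_re": np.asarray(res.cov_re), "scale": float(res.scale)},
        converged=converged, n_obs=len(y), _design=(X, names, groups, y, exog_re),
    )


# ---------------------------------------------------------------------------
# Logistic mixed model (time spent travelling), adaptive Gauss-Hermite
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = hermgauss(9)


def _glmm_group_blocks(X, y, groups):
    order = np.argsort(groups, kind="mergesort")
    Xs, ys, gs = X[order], y[order], groups[order]
    uniq, starts = np.unique(gs, return_index=True)
    bounds = list(starts) + [len(gs)]
    return [(Xs[bounds[i]:bounds[i + 1]], ys[bounds[i]:bounds[i + 1]]) for i in range(len(uniq))], uniq


def _glmm_negloglik_grad(theta, blocks, n_params):
    """Negative marginal log-likelihood and gradient for the AGQ GLMM.

    ``theta`` is (beta..., log sigma); the random intercept is sigma * z with
    z standard normal. Per group the integrand mode is found by Newton steps,
    nodes are recentred and rescaled there (adaptive quadrature), and the
    gradient is the posterior expectation of the complete-data score
    (mode/scale dependence on theta is second order at quadrature accuracy).
    """
    beta = theta[:n_params]
    sigma = np.exp(theta[n_params])
    t, w = _GH_NODES, _GH_WEIGHTS
    total = 0.0
    grad = np.zeros_like(theta)
    for Xg, yg in blocks:
        eta0 = Xg @ beta
        # Newton for the mode of log f(y|z) + log phi(z)
        z = 0.0
        for _ in range(50):
            p = expit(eta0 + sigma * z)
            g1 = sigma * np.sum(yg - p) - z
            g2 = -(sigma**2) * np.sum(p * (1 - p)) - 1.0
            step = g1 / g2
            z_new = z - step
            if abs(z_new - z) < 1e-10:
                z = z_new
                break
            z = z_new
        p = expit(eta0 + sigma * z)
        tau = 1.0 / np.sqrt((sigma**2) * np.sum(p * (1 - p)) + 1.0)

        nodes = z + np.sqrt(2.0) * tau * t                    # (K,)
        eta = eta0[None, :] + sigma * nodes[:, None]          # (K, n)
        # log f(y|z_k) summed over obs, stable via logaddexp formulation
        log_f = np.sum(yg[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
        log_phi = -0.5 * nodes**2 - 0.5 * np.log(2 * np.pi)
        log_g = t**2 + log_f + log_phi
        m = log_g.max()
        s = np.sum(w * np.exp(log_g - m))
        loglik_g = np.log(s) + m + 0.5 * np.log(2.0) + np.log(tau)
        total += loglik_g

        post = w * np.exp(log_g - m) / s                      # posterior node weights
        resid = yg[None, :] - expit(eta)                      # (K, n)
        score_beta = resid @ Xg                               # (K, p)
        score_sigma = np.sum(resid, axis=1) * nodes           # (K,)
        grad[:n_params] += post @ score_beta
        grad[n_params] += sigma * np.dot(post, score_sigma)
    return -total, -grad


@dataclass
class _GLMMModel:
    """Internal handle used for warm-started refits in the bootstrap."""

    blocks: list
    group_ids: np.ndarray
    n_params: int


def _fit_glmm(y, X, groups, start=None, maxiter=400):
    blocks, uniq = _glmm_group_blocks(X, y, groups)
    p = X.shape[1]
    if start is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        start = np.concatenate([glm.params, [np.log(0.3)]])
    res = optimize.minimize(
        _glmm_negloglik_grad, start, args=(blocks, p), jac=True,
        method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    return res, blocks


def fit_travel_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Logistic mixed model (by-wolf random intercept) for P(travel).

    The marginal likelihood integrates the random intercept out with 9-point
    adaptive Gauss-Hermite quadrature; K counts the fixed coefficients plus
    the random-intercept variance. Complete separation surfaces as divergent
    coefficients and is reported via the convergence flag.
    """
    if spec.response != "behavior":
        raise ValueError("fit_travel_model expects a behavior spec")
    y, X, names, groups = _prepare(df, spec)
    res, blocks = _fit_glmm(y, X, groups)
    p = X.shape[1]
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    converged = bool(res.success) and np.all(np.abs(beta) < 50)
    if not converged:
        logger.warning("GLMM %s: %s", spec.formula, res.message)
    if np.any(np.abs(beta) > 15):
        logger.warning("GLMM %s: very large coefficients; possible complete separation", spec.formula)

    # observed-information SEs from a finite-difference Hessian of the gradient
    se = _glmm_se(res.x, blocks, p)
    k = expected_K(spec)
    return FitResult(
        spec=spec, K=k, loglik=-float(res.fun),
        params=pd.Series(beta, index=names), se=pd.Series(se[:p], index=names),
        random_effects={"sigma": sigma},
        converged=converged, n_obs=len(y), _design=(X, names, groups, y, None),
    )


def _glmm_se(theta, blocks, n_params, eps=1e-5):
    d = len(theta)
    H = np.zeros((d, d))
    for j in range(d):
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] -= eps
        _, gp = _glmm_negloglik_grad(tp, blocks, n_params)
        _, gm = _glmm_negloglik_grad(tm, blocks, n_params)
        H[:, j] = (gp - gm) / (2 * eps)
    H = (H + H.T) / 2
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        se = np.full(d, np.nan)
    return se


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """AIC selection table over converged fits, best first.

    AIC = 2K - 2 logL; Akaike weight w_i = exp(-Delta_i/2) normalized over the
    set; evidence ratio = w_best / w_i.
    """
    usable = [f for f in fits if f.converged]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.warning("excluding %d non-converged fit(s) from the selection table", dropped)
    if not usable:
        raise ValueError("no converged fits to rank")
    rows = pd.DataFrame(
        {
            "formula": [f.spec.formula for f in usable],
            "K": [f.K for f in usable],
            "logL": [f.loglik for f in usable],
            "AIC": [f.aic for f in usable],
        }
    )
    rows = rows.sort_values(["AIC", "K"], kind="mergesort").reset_index(drop=True)
    rows["delta_AIC"] = rows["AIC"] - rows["AIC"].iloc[0]
    rel = np.exp(-rows["delta_AIC"] / 2.0)
    rows["weight"] = rel / rel.sum()
    rows["evidence_ratio"] = rows["weight"].iloc[0] / rows["weight"]
    rows.insert(0, "rank", np.arange(1, len(rows) + 1))
    return rows


def akaike_weights(delta_aic) -> np.ndarray:
    """Akaike weights from a vector of AIC differences."""
    rel = np.exp(-np.asarray(delta_aic, dtype=float) / 2.0)
    return rel / rel.sum()


def select_best(table: pd.DataFrame, parsimony_window: float = 4.0) -> pd.Series:
    """Most parsimonious model among those within ``parsimony_window`` AIC.

    Nested models a few AIC units behind the leader with nearly the same
    log-likelihood gain nothing from their extra parameters, so among rows
    with delta AIC <= window the one with smallest K wins (ties on K fall
    back to smaller AIC).
    """
    if table.empty:
        raise ValueError("empty selection table")
    near = table[table["delta_AIC"] <= parsimony_window]
    near = near.sort_values(["K", "AIC"], kind="mergesort")
    return near.iloc[0]


# ---------------------------------------------------------------------------
# Parametric bootstrap and back-transformation
# ---------------------------------------------------------------------------

def back_transform(beta: float, link: str) -> float:
    """Map a link-scale coefficient to its interpretable scale.

    ``log10`` -> 10**beta (multiplicative effect on speed in m/min);
    ``logit`` -> exp(beta) (odds ratio).
    """
    if link == "log10":
        return float(10.0**beta)
    if link == "logit":
        return float(np.exp(beta))
    raise ValueError(f"unknown link {link!r}; expected 'log10' or 'logit'")


def parametric_bootstrap_ci(
    fit: FitResult,
    n_sim: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap CIs by simulating from the fitted model.

    New responses are drawn from the fitted mixed model (fresh random effects
    and, for the LMM, fresh residuals), the model is refit, and the fixed
    coefficients collected; the CI is the percentile interval of the refitted
    coefficients. Failed refits are dropped; a failure rate above 10% attaches
    a warning (``attrs['bootstrap_warning']``).

    Returns a DataFrame with link-scale estimate/CI and back-transformed
    columns (10^x for the speed model, exp(x) for the travel model).
    """
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    X, names, groups, y, exog_re = fit._design
    uniq = np.unique(groups)
    group_index = {g: np.flatnonzero(groups == g) for g in uniq}
    p = X.shape[1]
    is_lmm = fit.spec.response == "log10_speed"
    link = "log10" if is_lmm else "logit"

    beta_hat = fit.params.to_numpy()
    draws = np.full((n_sim, p), np.nan)
    failures = 0
    if is_lmm:
        cov_re = fit.random_effects["cov_re"]
        scale = fit.random_effects["scale"]
        chol = np.linalg.cholesky(cov_re + 1e-12 * np.eye(2))
        for b in range(n_sim):
            y_sim = X @ beta_hat + rng.normal(0, np.sqrt(scale), size=len(y))
            re = (chol @ rng.standard_normal((2, len(uniq)))).T  # (n_groups, 2)
            for gi, g in enumerate(uniq):
                idx = group_index[g]
                y_sim[idx] += exog_re[idx] @ re[gi]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = MixedLM(y_sim, X, groups=groups, exog_re=exog_re)
                    res, _ = _fit_lmm_robust(model, maxiter=200, methods=("lbfgs", "powell"),
                                             stop_at_first=True)
                if not np.all(np.isfinite(res.fe_params)):
                    raise ValueError("non-finite refit")
                draws[b] = res.fe_params
            except Exception:  # noqa: BLE001 - counted as a failure
                failures += 1
    else:
        sigma = fit.random_effects["sigma"]
        start = np.concatenate([beta_hat, [np.log(max(sigma, 1e-3))]])
        for b in range(n_sim):
            eta = X @ beta_hat
            re = rng.normal(0, sigma, size=len(uniq))
            for gi, g in enumerate(uniq):
                eta[group_index[g]] += re[gi]
            y_sim = (rng.random(len(y)) < expit(eta)).astype(float)
            try:
                res, _ = _fit_glmm(y_sim, X, groups, start=start, maxiter=200)
                if not res.success or not np.all(np.isfinite(res.x)):
                    raise ValueError("refit failed")
                draws[b] = res.x[:p]
            except Exception:  # noqa: BLE001
                failures += 1

    ok = ~np.isnan(draws[:, 0])
    draws = draws[ok]
    alpha = (1 - level) / 2
    lo = np.percentile(draws, 100 * alpha, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha), axis=0)

    out = pd.DataFrame(
        {
            "term": names,
            "beta": beta_hat,
            "se": fit.se.to_numpy(),
            "ci_lower": lo,
            "ci_upper": hi,
            "beta_transformed": [back_transform(v, link) for v in beta_hat],
            "ci_lower_transformed": [back_transform(v, link) for v in lo],
            "ci_upper_transformed": [back_transform(v, link) for v in hi],
        }
    )
    fail_rate = failures / n_sim
    out.attrs["n_failures"] = failures
    if fail_rate > 0.10:
        msg = f"bootstrap refit failure rate {fail_rate:.1%} exceeds 10%"
        logger.warning(msg)
        out.attrs["bootstrap_warning"] = msg
    return out
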