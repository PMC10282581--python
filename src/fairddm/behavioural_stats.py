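"""Quality filtering, logistic mixed models, and trait correlations.

The confirmatory analysis of the study is a random-intercept logistic mixed
model on the trial-level congruence code

    response ~ conflict_degree * fairness_domain
               + conflict_degree * incentive_level + (1 | participant),

fitted by maximum likelihood with the participant intercept integrated out
by adaptive Gauss-Hermite quadrature (one node is the Laplace
approximation; the default uses 15 nodes).  Wald z = beta / s.e. tests are
reported per fixed effect.  Incentive level enters as points/100 (0-5), so
coefficients read "per 100 points".

The manipulation-check model with a by-participant random slope over the
distribution-type factor is delegated to lme4 (via Rscript); a singular or
failed random-slope fit falls back to the in-package random-intercept
estimator, flagged.
"""

from __future__ import annotations

import json
import subprocess
import sys
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_expit, expit

from .synthetic_data import (
    COMPENSATION,
    CONFLICT,
    FAIRNESS_PARTNER,
    FAVOUR_OTHER,
    PUNISHMENT,
    TRAIT_SCALES,
)

__all__ = [
    "GLMMResult",
    "apply_quality_filters",
    "fit_random_intercept_logistic",
    "fit_confirmatory_glmm",
    "fit_manipulation_glmms",
    "trait_correlations",
    "congruent_rates",
]

#: Bonferroni factor for the trait correlations: five scales per group
N_TRAIT_SCALES = len(TRAIT_SCALES)


@dataclass
class GLMMResult:
    """Fixed-effect table and fit metadata of one logistic mixed model."""

    model: str
    table: pd.DataFrame  # term, estimate, se, z, p
    sigma_u: float
    n_obs: int
    loglik: float
    converged: bool
    flags: list = field(default_factory=list)

    def coef(self, term: str) -> pd.Series:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no fixed effect named {term!r}")
        return row.iloc[0]


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def apply_quality_filters(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude careless participants and strip control trials.

    A participant is excluded when they picked the dominated option in at
    least 2 of the 6 control trials, or when their mean response time is
    below 500 ms.  Excluded participants are removed entirely; control
    trials are dropped from the analysis table.  Tables without control
    trials skip the control criterion with a warning flag in the report.
    """
    df = df.copy()
    has_controls = bool((df["is_control"] == 1).any())
    if not has_controls:
        warnings.warn("no control trials found; control-failure QC skipped", stacklevel=2)
    rows = []
    excluded_ids = []
    for pid, sub in df.groupby("participant_id", sort=True):
        ctrl = sub[sub["is_control"] == 1]
        failures = int((ctrl["decision"] == FAVOUR_OTHER).sum())  # dominated option
        rts = sub["rt_s"].dropna()
        mean_rt = float(rts.mean()) if len(rts) else np.nan
        reasons = []
        if has_controls and failures >= 2:
            reasons.append("control_failures>=2")
        if np.isfinite(mean_rt) and mean_rt < 0.5:
            reasons.append("mean_rt<0.5s")
        excluded = bool(reasons)
        if excluded:
            excluded_ids.append(pid)
        rows.append(
            dict(
                participant_id=pid,
                group=sub["group"].iloc[0],
                control_failures=failures,
                mean_rt_s=mean_rt,
                excluded=excluded,
                reason=";".join(reasons),
                qc_skipped=not has_controls,
            )
        )
    report = pd.DataFrame(rows)
    clean = df[~df["participant_id"].isin(excluded_ids) & (df["is_control"] == 0)]
    return clean.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# random-intercept logistic regression by adaptive Gauss-Hermite ML
# ---------------------------------------------------------------------------


class _AGQLoglik:
    """Marginal log-likelihood of a random-intercept logistic model.

    Clusters' intercepts are integrated out with adaptive Gauss-Hermite
    quadrature centred at each cluster's posterior mode (Laplace point).
    Caches the mode vector between calls as a warm start.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, g: np.ndarray, n_quad: int = 15):
        self.y = y.astype(np.float64)
        self.X = X
        self.g = g
        self.m = int(g.max()) + 1
        self.nodes, self.weights = np.polynomial.hermite.hermgauss(n_quad)
        self.log_wstar = np.log(self.weights) + self.nodes**2
        self._u = np.zeros(self.m)

    def _cluster_loglik(self, eta_u: np.ndarray) -> np.ndarray:
        # sum_j log p(y_j | eta_j + u) per cluster, numerically stable
        s = (2.0 * self.y - 1.0) * eta_u
        return np.bincount(self.g, weights=log_expit(s), minlength=self.m)

    def __call__(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = self.X @ beta
        u = self._u.copy()
        # Newton iterations for the per-cluster posterior mode
        for _ in range(50):
            mu = expit(eta + u[self.g])
            grad = np.bincount(self.g, weights=self.y - mu, minlength=self.m) - u / sigma**2
            hess = np.bincount(self.g, weights=mu * (1.0 - mu), minlength=self.m) + 1.0 / sigma**2
            step = grad / hess
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._u = u
        mu = expit(eta + u[self.g])
        curv = np.bincount(self.g, weights=mu * (1.0 - mu), minlength=self.m) + 1.0 / sigma**2
        scale = 1.0 / np.sqrt(curv)
        # h(u) = cluster loglik + log N(u; 0, sigma^2), evaluated on shifted nodes
        h = np.empty((len(self.nodes), self.m))
        for k, x in enumerate(self.nodes):
            uk = u + np.sqrt(2.0) * scale * x
            h[k] = (
                self._cluster_loglik(eta + uk[self.g])
                - 0.5 * (uk / sigma) ** 2
                - np.log(sigma)
                - 0.5 * np.log(2.0 * np.pi)
            )
        lse = np.logaddexp.reduce(h + self.log_wstar[:, None], axis=0)
        return float(np.sum(lse + 0.5 * np.log(2.0) + np.log(scale)))


def _glm_start(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Plain logistic regression by Newton-Raphson (starting values)."""
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        mu = expit(X @ beta)
        W = mu * (1.0 - mu) + 1e-10
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H + 1e-8 * np.eye(X.shape[1]), X.T @ (y - mu))
        beta += step
        if np.max(np.abs(step)) < 1e-9:
            break
    return beta


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h
                xm = x.copy(); xm[i] -= h
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h**2
            else:
                xpp = x.copy(); xpp[i] += h; xpp[j] += h
                xpm = x.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h**2)
    return H


def fit_random_intercept_logistic(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    term_names: list[str],
    *,
    model_name: str = "glmm",
    n_quad: int = 15,
) -> GLMMResult:
    """ML fit of logit P(y=1) = X beta + u_i, u_i ~ N(0, sigma_u^2).

    Optimizes (beta, log sigma_u) by L-BFGS-B on the adaptive-quadrature
    marginal likelihood; Wald standard errors come from the numerical
    Hessian at the optimum (with sigma_u profiled out at its bound when the
    variance estimate collapses to zero).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    codes, _ = pd.factorize(np.asarray(groups))
    ll = _AGQLoglik(y, X, codes, n_quad=n_quad)
    beta0 = _glm_start(y, X)
    x0 = np.append(beta0, np.log(0.5))
    lb = np.full_like(x0, -np.inf)
    ub = np.full_like(x0, np.inf)
    lb[-1], ub[-1] = np.log(1e-5), np.log(50.0)
    nll = lambda th: -ll(th)
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    sigma_u = float(np.exp(theta[-1]))
    flags = []
    p = X.shape[1]
    at_bound = theta[-1] <= np.log(1e-5) + 1e-6
    if at_bound:
        flags.append("sigma_u_at_zero_boundary")
        fbeta = lambda b: nll(np.append(b, theta[-1]))
        H = _num_hessian(fbeta, theta[:p])
        cov = np.linalg.inv(H)
    else:
        H = _num_hessian(nll, theta)
        cov = np.linalg.inv(H)[:p, :p]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    est = theta[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    converged = bool(res.success)
    if not converged:
        flags.append(f"optimizer: {res.message}; |grad|={np.max(np.abs(res.jac)):.2e}")
    table = pd.DataFrame(
        {"term": term_names, "estimate": est, "se": se, "z": z, "p": pvals}
    )
    return GLMMResult(
        model=model_name, table=table, sigma_u=sigma_u, n_obs=len(y),
        loglik=float(-res.fun), converged=converged, flags=flags,
    )


# ---------------------------------------------------------------------------
# study-specific model builders
# ---------------------------------------------------------------------------


def _codes(df: pd.DataFrame) -> pd.DataFrame:
    """Treatment codings used throughout (aligned / compensation reference)."""
    out = pd.DataFrame(index=df.index)
    out["conflict"] = (df["conflict_degree"] == CONFLICT).astype(float)
    out["domain"] = (df["fairness_domain"] == PUNISHMENT).astype(float)
    out["incentive"] = df["incentive_level"].astype(float) / 100.0
    out["partner"] = (df["partner"] == FAIRNESS_PARTNER).astype(float)
    return out


CONFIRMATORY_TERMS = [
    "(Intercept)", "conflict_degree", "fairness_domain", "incentive_level",
    "conflict_degree:fairness_domain", "conflict_degree:incentive_level",
]


def confirmatory_design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix of the confirmatory model on fairness-partner trials."""
    sub = df[(df["partner"] == FAIRNESS_PARTNER) & (df["is_control"] == 0)]
    c = _codes(sub)
    X = np.column_stack(
        [
            np.ones(len(sub)), c["conflict"], c["domain"], c["incentive"],
            c["conflict"] * c["domain"], c["conflict"] * c["incentive"],
        ]
    )
    return sub["response"].to_numpy(float), X, sub["participant_id"].to_numpy()


def fit_confirmatory_glmm(df: pd.DataFrame, *, n_quad: int = 15) -> GLMMResult:
    """The pre-registered congruence model on fairness-partner trials only.

    response ~ conflict * domain + conflict * incentive + (1 | participant);
    baseline-partner trials are excluded, incentive is coded 0-5.
    """
    y, X, g = confirmatory_design(df)
    return fit_random_intercept_logistic(
        y, X, g, CONFIRMATORY_TERMS, model_name="confirmatory", n_quad=n_quad
    )


_R_GLMER_TEMPLATE = """
suppressMessages(library(lme4))
d <- read.csv("{data}")
d$participant_id <- factor(d$participant_id)
fit <- tryCatch(
  glmer({formula}, data = d, family = binomial,
        control = glmerControl(optimizer = "bobyqa", calc.derivs = FALSE)),
  error = function(e) e)
if (inherits(fit, "error")) {{
  cat(jsonlite::toJSON(list(error = conditionMessage(fit)), auto_unbox = TRUE))
}} else {{
  s <- summary(fit)$coefficients
  out <- list(
    term = rownames(s), estimate = s[, 1], se = s[, 2], z = s[, 3], p = s[, 4],
    singular = isSingular(fit, tol = 1e-4),
    converged = length(fit@optinfo$conv$lme4$messages) == 0,
    sigma_u = sqrt(VarCorr(fit)$participant_id[1, 1]),
    loglik = as.numeric(logLik(fit)), n = nobs(fit))
  cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
}}
"""


def _fit_glmer_r(df: pd.DataFrame, formula: str, model_name: str) -> GLMMResult | None:
    """Fit a lme4 glmer model through Rscript; None when R is unusable."""
    with tempfile.TemporaryDirectory() as tmp:
        data = Path(tmp) / "data.csv"
        df.to_csv(data, index=False)
        script = Path(tmp) / "fit.R"
        script.write_text(_R_GLMER_TEMPLATE.format(data=data, formula=formula))
        try:
            proc = subprocess.run(
                ["Rscript", "--vanilla", str(script)],
                capture_output=True, text=True, timeout=600,
            )
        except (FileNotFoundError, subprocess.TimeoutExpired) as exc:
            warnings.warn(f"Rscript unavailable for {model_name}: {exc}", stacklevel=2)
            return None
    if proc.returncode != 0 or not proc.stdout.strip():
        warnings.warn(
            f"lme4 fit failed for {model_name}: {proc.stderr[-500:]}", stacklevel=2
        )
        return None
    out = json.loads(proc.stdout)
    if "error" in out:
        warnings.warn(f"lme4 error for {model_name}: {out['error']}", stacklevel=2)
        return None
    def _vec(x):
        return np.atleast_1d(np.asarray(x, dtype=float))
    table = pd.DataFrame(
        {
            "term": np.atleast_1d(out["term"]), "estimate": _vec(out["estimate"]),
            "se": _vec(out["se"]), "z": _vec(out["z"]), "p": _vec(out["p"]),
        }
    )
    flags = ["backend=lme4"]
    if out["singular"]:
        flags.append("singular_random_effects")
    return GLMMResult(
        model=model_name, table=table, sigma_u=float(out["sigma_u"]),
        n_obs=int(out["n"]), loglik=float(out["loglik"]),
        converged=bool(out["converged"]), flags=flags,
    )


def fit_manipulation_glmms(
    df: pd.DataFrame, *, use_r_backend: bool = True, n_quad: int = 15
) -> dict[str, GLMMResult]:
    """The three manipulation-check model families (both partners included).

    1. per fairness domain: response ~ partner * conflict with a
       by-participant random slope over the distribution-type (pairing)
       factor plus a random intercept (lme4 backend; singular or failed
       fits fall back to the in-package random-intercept estimator,
       flagged);
    2. decision ~ domain * partner + (1 | participant);
    3. decision ~ domain * incentive_type + (1 | participant).
    """
    df = df[df["is_control"] == 0]
    results: dict[str, GLMMResult] = {}

    for dom in (PUNISHMENT, COMPENSATION):
        sub = df[df["fairness_domain"] == dom].copy()
        c = _codes(sub)
        name = f"manipulation_response_{dom}"
        fit = None
        if use_r_backend:
            rdf = pd.DataFrame(
                {
                    "participant_id": sub["participant_id"],
                    "response": sub["response"].astype(int),
                    "partner": c["partner"], "conflict": c["conflict"],
                    "pairing": sub["pairing"],
                }
            )
            fit = _fit_glmer_r(
                rdf,
                "response ~ partner * conflict + (1 + pairing | participant_id)",
                name,
            )
            if fit is not None and "singular_random_effects" in fit.flags:
                fit = None  # refit below with intercept-only structure
        if fit is None:
            X = np.column_stack(
                [np.ones(len(sub)), c["partner"], c["conflict"], c["partner"] * c["conflict"]]
            )
            fit = fit_random_intercept_logistic(
                sub["response"].to_numpy(float), X, sub["participant_id"].to_numpy(),
                ["(Intercept)", "partner", "conflict_degree", "partner:conflict_degree"],
                model_name=name, n_quad=n_quad,
            )
            fit.flags.append("random_intercept_only_fallback")
        results[name] = fit

    c = _codes(df)
    y_dec = (df["decision"] == FAVOUR_OTHER).to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), c["domain"], c["partner"], c["domain"] * c["partner"]]
    )
    results["manipulation_decision_partner"] = fit_random_intercept_logistic(
        y_dec, X, df["participant_id"].to_numpy(),
        ["(Intercept)", "fairness_domain", "partner", "fairness_domain:partner"],
        model_name="manipulation_decision_partner", n_quad=n_quad,
    )

    # incentive type: 1 when the group's incentivized option is favour-other
    inc_other = (
        ((df["fairness_domain"] == PUNISHMENT) & (df["conflict_degree"] == CONFLICT))
        | ((df["fairness_domain"] == COMPENSATION) & (df["conflict_degree"] != CONFLICT))
    ).astype(float)
    X = np.column_stack(
        [np.ones(len(df)), c["domain"], inc_other, c["domain"] * inc_other]
    )
    results["manipulation_decision_incentive_type"] = fit_random_intercept_logistic(
        y_dec, X, df["participant_id"].to_numpy(),
        ["(Intercept)", "fairness_domain", "incentive_type", "fairness_domain:incentive_type"],
        model_name="manipulation_decision_incentive_type", n_quad=n_quad,
    )
    return results


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------


def congruent_rates(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant fraction of congruent responses (experimental trials)."""
    sub = df[df["is_control"] == 0]
    rates = (
        sub.groupby(["participant_id", "group"], sort=True)["response"]
        .mean()
        .rename("congruent_rate")
        .reset_index()
    )
    return rates


def trait_correlations(
    rates: pd.DataFrame, traits: pd.DataFrame, *, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate per-group congruent rates with each trait scale.

    ``rates`` is the output of :func:`congruent_rates`; ``traits`` holds one
    row per participant in the same order.  Reports the uncorrected p and a
    Bonferroni-adjusted p (factor 5 = scales per group, capped at 1).
    Groups need at least 3 participants; zero-variance scales are reported
    as undefined.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if len(rates) != len(traits):
        raise ValueError("rates and traits must have one row per participant")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    traits = traits.reset_index(drop=True)
    rates = rates.reset_index(drop=True)
    for grp, idx in rates.groupby("group").groups.items():
        x = rates.loc[idx, "congruent_rate"].to_numpy()
        if len(x) < 3:
            raise ValueError(f"group {grp!r} has fewer than 3 participants")
        for scale in TRAIT_SCALES:
            t = traits.loc[idx, scale].to_numpy()
            if np.std(t) == 0 or np.std(x) == 0:
                r, p = np.nan, np.nan
                note = "undefined: zero variance"
            else:
                r, p = corr(x, t)
                note = ""
            rows.append(
                dict(
                    group=grp, scale=scale, r=r, p_uncorrected=p,
                    p_bonferroni=min(1.0, N_TRAIT_SCALES * p) if np.isfinite(p) else np.nan,
                    n=len(x), note=note,
                )
            )
    return pd.DataFrame(rows)
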