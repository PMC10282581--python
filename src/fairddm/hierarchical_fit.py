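"""Hierarchical Bayesian estimation of the drift-diffusion model space.

Subject-level diffusion parameters are drawn from group-level Normal
distributions; design covariates (conflict degree, fairness domain) act as
offsets on the drift rate (identity link) or on the relative starting point
(logistic link, keeping z in (0, 1)).  Single-factor models carry one
offset; two-factor models include the interaction column, i.e. a free group
mean per condition cell, matching the per-condition estimates of the
reference hierarchical-DDM convention (and making the domain-difference
contrast estimable).  Boundary separation and non-decision time never carry
covariates, and one t0 is estimated per subject across all conditions.

Model space (confirmatory): M0 (no covariates), V1 (v ~ conflict),
V2 (v ~ conflict + domain), Z1 (z ~ conflict), Z2 (z ~ conflict + domain).
Exploratory: ZI (z ~ trial-wise incentive level, coded 0-5, fitted per
group with v free).

Sampling is adaptive Metropolis-within-Gibbs: random-walk updates with
proposal scales tuned to a 44% acceptance rate during burn-in (frozen
afterwards), conjugate Gibbs draws for the Normal location/regression
hyper-parameters of v and logit z.  Convergence is gated on the split
Gelman-Rubin statistic (R-hat < 1.01) of the group-level parameters, with
Geweke z-scores as a secondary diagnostic.

The deviance used for the DIC conditions on the subject-level parameters
(lowest-level focus): D = -2 * sum_i log L_i(v_i, a_i, z_i, t0_i).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .ddm_core import _wfpt_lower, SERIES_EPS
from .synthetic_data import CONFLICT, FAIRNESS_PARTNER, PUNISHMENT

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "PosteriorTraces",
    "ConvergenceReport",
    "ModelFit",
    "build_model_space",
    "fit_model",
    "gelman_rubin",
    "geweke_z",
    "save_fit",
    "load_fit",
    "posterior_mean_subject_params",
]

CONFLICT_COV = "conflict_degree"
DOMAIN_COV = "fairness_domain"
INCENTIVE_COV = "incentive_level"
INTERACTION_COL = f"{CONFLICT_COV}:{DOMAIN_COV}"

RHAT_THRESHOLD = 1.01


def _design_columns(covs: tuple[str, ...]) -> tuple[str, ...]:
    """Between-subject design columns implied by a covariate set.

    When both factors are present the condition-cell structure is free
    (the reference implementation estimates one group mean per cell), so
    the interaction column is included.
    """
    cols = tuple(c for c in covs if c != INCENTIVE_COV)
    if CONFLICT_COV in cols and DOMAIN_COV in cols:
        cols = cols + (INTERACTION_COL,)
    return cols


@dataclass(frozen=True)
class ModelSpec:
    """One member of the DDM model space."""

    name: str
    v_covariates: tuple[str, ...] = ()
    z_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ok = {CONFLICT_COV, DOMAIN_COV}
        if not set(self.v_covariates) <= ok:
            raise ValueError(f"invalid v covariates {self.v_covariates}")
        if not set(self.z_covariates) <= ok | {INCENTIVE_COV}:
            raise ValueError(f"invalid z covariates {self.z_covariates}")

    @property
    def v_columns(self) -> tuple[str, ...]:
        return _design_columns(self.v_covariates)

    @property
    def z_columns(self) -> tuple[str, ...]:
        return _design_columns(self.z_covariates)

    @property
    def complexity(self) -> int:
        n = len(self.v_columns) + len(self.z_columns)
        if self.per_trial_z:
            n += 1
        return n

    @property
    def per_trial_z(self) -> bool:
        return INCENTIVE_COV in self.z_covariates


MODEL_SPECS = {
    "M0": ModelSpec("M0"),
    "V1": ModelSpec("V1", v_covariates=(CONFLICT_COV,)),
    "V2": ModelSpec("V2", v_covariates=(CONFLICT_COV, DOMAIN_COV)),
    "Z1": ModelSpec("Z1", z_covariates=(CONFLICT_COV,)),
    "Z2": ModelSpec("Z2", z_covariates=(CONFLICT_COV, DOMAIN_COV)),
    "ZI": ModelSpec("ZI", z_covariates=(INCENTIVE_COV,)),
}


def build_model_space(exploratory: bool = False) -> list[ModelSpec]:
    """The confirmatory five-model space, plus ZI when exploratory."""
    space = [MODEL_SPECS[n] for n in ("M0", "V1", "V2", "Z1", "Z2")]
    if exploratory:
        space.append(MODEL_SPECS["ZI"])
    return space


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 5000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.draws < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid MCMC settings")


@dataclass
class PosteriorTraces:
    """Ordered posterior samples per parameter, shaped (chains, draws)."""

    samples: dict[str, np.ndarray]
    burn_in: int

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, order preserved within chain."""
        return self.samples[name].reshape(-1)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[name]


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    geweke: dict[str, float] = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD


@dataclass
class ModelFit:
    """Posterior traces plus deviance summaries for one model."""

    spec: ModelSpec
    traces: PosteriorTraces
    dbar: float           # mean posterior deviance
    d_at_mean: float      # deviance at the posterior mean of subject params
    convergence: ConvergenceReport
    settings: MCMCSettings
    subject_ids: list
    group_label: str | None = None

    @property
    def p_d(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.p_d

    @property
    def converged(self) -> bool:
        return self.convergence.converged


# ---------------------------------------------------------------------------
# likelihood kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _subject_loglik(rt, upper, lvl, v, a, zl, t0, wz, eps):
    """WFPT log-likelihood of one subject's trials.

    z varies per trial through the logistic link on zl + wz * incentive
    (wz = 0 for all confirmatory models).
    """
    total = 0.0
    for i in range(rt.shape[0]):
        x = zl + wz * lvl[i]
        if x > 35.0:
            x = 35.0
        elif x < -35.0:
            x = -35.0
        z = 1.0 / (1.0 + np.exp(-x))
        if upper[i]:
            d = _wfpt_lower(rt[i], -v, a, 1.0 - z, t0, eps)
        else:
            d = _wfpt_lower(rt[i], v, a, z, t0, eps)
        if d <= 0.0:
            return -np.inf
        total += np.log(d)
    return total


# ---------------------------------------------------------------------------
# priors (weakly informative, reference hierarchical-DDM convention)
# ---------------------------------------------------------------------------

PRIORS = {
    "mu_v": (0.0, 2.0),
    "beta_v": (0.0, 2.0),
    "mu_a": (1.5, 0.75),
    "mu_zl": (0.0, 1.0),     # logit scale; z mean 0.5
    "beta_z": (0.0, 1.0),
    "mu_t0": (0.4, 0.2),
    "w_z": (0.0, 1.0),
    "sigma_halfnormal_scale": 0.5,
}


def _log_halfnormal(s: float, scale: float) -> float:
    if s <= 0:
        return -np.inf
    return -0.5 * (s / scale) ** 2


def _log_truncnorm(x: float, mu: float, sd: float) -> float:
    """log density of N(mu, sd) truncated to (0, inf)."""
    if x <= 0:
        return -np.inf
    lz = stats.norm.logsf(0.0, loc=mu, scale=sd)
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - lz


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _SubjectData:
    pid: object
    rt: np.ndarray
    upper: np.ndarray
    lvl: np.ndarray      # incentive level coded 0-5
    x_v: np.ndarray      # covariate row for v
    x_z: np.ndarray      # covariate row for z (between-subject part)
    min_rt: float


def _covariate_row(sub: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
    conflict = 1.0 if sub["conflict_degree"].iloc[0] == CONFLICT else 0.0
    domain = 1.0 if sub["fairness_domain"].iloc[0] == PUNISHMENT else 0.0
    lookup = {CONFLICT_COV: conflict, DOMAIN_COV: domain, INTERACTION_COL: conflict * domain}
    return np.asarray([lookup[c] for c in columns])


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> list[_SubjectData]:
    df = data[
        (data["partner"] == FAIRNESS_PARTNER)
        & (data["is_control"] == 0)
        & data["rt_s"].notna()
    ]
    if df.empty:
        raise ValueError("no usable fairness-partner trials with RTs in the data")
    subjects = []
    for pid, sub in df.groupby("participant_id", sort=True):
        rt = sub["rt_s"].to_numpy(np.float64)
        subjects.append(
            _SubjectData(
                pid=pid,
                rt=rt,
                upper=sub["response"].to_numpy(np.int64).astype(np.bool_),
                lvl=sub["incentive_level"].to_numpy(np.float64) / 100.0,
                x_v=_covariate_row(sub, spec.v_columns),
                x_z=_covariate_row(sub, spec.z_columns),
                min_rt=float(rt.min()),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _AdaptiveScale:
    """Robbins-Monro proposal-scale adaptation toward 44% acceptance."""

    def __init__(self, n: int, init: float):
        self.log_s = np.full(n, np.log(init))
        self.batch = 1

    def scales(self) -> np.ndarray:
        return np.exp(self.log_s)

    def adapt(self, acc_rate: np.ndarray) -> None:
        self.log_s += (acc_rate - 0.44) / np.sqrt(self.batch)
        self.batch += 1


def _gibbs_regression(
    values: np.ndarray, W: np.ndarray, sigma: float, prior_sds: np.ndarray, rng
) -> np.ndarray:
    """Conjugate draw of Normal regression coefficients with N(0, sd^2) priors."""
    prec = W.T @ W / sigma**2 + np.diag(1.0 / prior_sds**2)
    cov = np.linalg.inv(prec)
    mean = cov @ (W.T @ values) / sigma**2
    return rng.multivariate_normal(mean, cov)


def _run_chain(
    subjects: list[_SubjectData],
    spec: ModelSpec,
    settings: MCMCSettings,
    chain_seed: int,
    keep_every: int,
):
    rng = np.random.default_rng(chain_seed)
    n = len(subjects)
    kv = len(spec.v_columns)
    kz = len(spec.z_columns)
    Wv = np.column_stack([np.ones(n)] + [np.array([s.x_v[j] for s in subjects]) for j in range(kv)])
    Wz = np.column_stack([np.ones(n)] + [np.array([s.x_z[j] for s in subjects]) for j in range(kz)])

    # data-informed initial values, jittered per chain
    p_hat = np.array([s.upper.mean() for s in subjects]).clip(0.05, 0.95)
    v = 2.0 * (p_hat - 0.5) + rng.normal(0, 0.2, n)
    a = np.full(n, 1.5) + rng.normal(0, 0.1, n)
    zl = rng.normal(0, 0.1, n)
    t0 = np.array([min(0.6 * s.min_rt, 0.3) for s in subjects]) + rng.uniform(0, 0.02, n)
    wz = 0.0
    gamma_v = np.zeros(1 + kv); gamma_v[0] = v.mean()
    gamma_z = np.zeros(1 + kz)
    sig = {"v": 0.3, "a": 0.3, "zl": 0.3, "t0": 0.1}

    def subj_ll(i, vi, ai, zli, t0i, wzi):
        s = subjects[i]
        if ai <= 0 or t0i <= 0 or t0i >= s.min_rt:
            return -np.inf
        return _subject_loglik(s.rt, s.upper, s.lvl, vi, ai, zli, t0i, wzi, SERIES_EPS)

    cur_ll = np.array([subj_ll(i, v[i], a[i], zl[i], t0[i], wz) for i in range(n)])
    if not np.all(np.isfinite(cur_ll)):
        # enlarge boundaries until every subject has positive density
        for i in range(n):
            while not np.isfinite(cur_ll[i]):
                a[i] += 0.3
                t0[i] *= 0.7
                cur_ll[i] = subj_ll(i, v[i], a[i], zl[i], t0[i], wz)

    names = ["v", "a", "zl", "t0"]
    scales = {p: _AdaptiveScale(n, 0.3 if p != "t0" else 0.05) for p in names}
    wz_scale = _AdaptiveScale(1, 0.1)
    hyper_scale = _AdaptiveScale(6, 0.1)  # sigma_v, sigma_zl, mu_a, sigma_a, mu_t0, sigma_t0
    acc = {p: np.zeros(n) for p in names}
    acc_wz = np.zeros(1)
    acc_hyper = np.zeros(6)

    n_iter = settings.burn_in + settings.draws * keep_every
    n_keep = settings.draws
    out = {
        "mu_v": np.empty(n_keep), "sigma_v": np.empty(n_keep),
        "mu_a": np.empty(n_keep), "sigma_a": np.empty(n_keep),
        "mu_zl": np.empty(n_keep), "sigma_zl": np.empty(n_keep),
        "mu_t0": np.empty(n_keep), "sigma_t0": np.empty(n_keep),
        "deviance": np.empty(n_keep),
    }
    for c in spec.v_columns:
        out[f"beta_v[{c}]"] = np.empty(n_keep)
    for c in spec.z_columns:
        out[f"beta_z[{c}]"] = np.empty(n_keep)
    if spec.per_trial_z:
        out["w_z"] = np.empty(n_keep)
    subj_out = {p: np.empty((n_keep, n)) for p in names}

    sigma_v, sigma_zl = 0.3, 0.3
    mu_a, sigma_a = 1.5, 0.3
    mu_t0, sigma_t0 = float(np.mean(t0)), 0.1
    adapt_block = 25
    kept = 0

    for it in range(n_iter):
        adapting = it < settings.burn_in
        # --- subject-level updates -------------------------------------
        prior_mean_v = Wv @ gamma_v
        prior_mean_z = Wz @ gamma_z
        for p in names:
            sc = scales[p].scales()
            for i in range(n):
                prop = {"v": v[i], "a": a[i], "zl": zl[i], "t0": t0[i]}
                prop[p] = prop[p] + sc[i] * rng.standard_normal()
                new_ll = subj_ll(i, prop["v"], prop["a"], prop["zl"], prop["t0"], wz)
                if not np.isfinite(new_ll):
                    continue
                if p == "v":
                    dprior = (
                        -0.5 * ((prop["v"] - prior_mean_v[i]) / sigma_v) ** 2
                        + 0.5 * ((v[i] - prior_mean_v[i]) / sigma_v) ** 2
                    )
                elif p == "a":
                    dprior = _log_truncnorm(prop["a"], mu_a, sigma_a) - _log_truncnorm(
                        a[i], mu_a, sigma_a
                    )
                elif p == "zl":
                    dprior = (
                        -0.5 * ((prop["zl"] - prior_mean_z[i]) / sigma_zl) ** 2
                        + 0.5 * ((zl[i] - prior_mean_z[i]) / sigma_zl) ** 2
                    )
                else:
                    dprior = _log_truncnorm(prop["t0"], mu_t0, sigma_t0) - _log_truncnorm(
                        t0[i], mu_t0, sigma_t0
                    )
                if np.log(rng.random()) < new_ll - cur_ll[i] + dprior:
                    v[i], a[i], zl[i], t0[i] = prop["v"], prop["a"], prop["zl"], prop["t0"]
                    cur_ll[i] = new_ll
                    acc[p][i] += 1.0

        # --- incentive weight on z (per-trial covariate) ----------------
        if spec.per_trial_z:
            wp = wz + wz_scale.scales()[0] * rng.standard_normal()
            new_lls = np.array([subj_ll(i, v[i], a[i], zl[i], t0[i], wp) for i in range(n)])
            if np.all(np.isfinite(new_lls)):
                m, sd = PRIORS["w_z"]
                dprior = -0.5 * ((wp - m) / sd) ** 2 + 0.5 * ((wz - m) / sd) ** 2
                if np.log(rng.random()) < new_lls.sum() - cur_ll.sum() + dprior:
                    wz = wp
                    cur_ll = new_lls
                    acc_wz[0] += 1.0

        # --- group-level updates ----------------------------------------
        gamma_v = _gibbs_regression(
            v, Wv, sigma_v, np.array([PRIORS["mu_v"][1]] + [PRIORS["beta_v"][1]] * kv), rng
        )
        gamma_z = _gibbs_regression(
            zl, Wz, sigma_zl, np.array([PRIORS["mu_zl"][1]] + [PRIORS["beta_z"][1]] * kz), rng
        )

        hs = hyper_scale.scales()
        hn = PRIORS["sigma_halfnormal_scale"]

        def mh_sigma(idx, sigma, resid):
            prop = sigma * np.exp(hs[idx] * rng.standard_normal())
            logr = (
                np.sum(stats.norm.logpdf(resid, 0.0, prop))
                - np.sum(stats.norm.logpdf(resid, 0.0, sigma))
                + _log_halfnormal(prop, hn) - _log_halfnormal(sigma, hn)
                + np.log(prop) - np.log(sigma)  # log-scale proposal Jacobian
            )
            if np.log(rng.random()) < logr:
                acc_hyper[idx] += 1.0
                return prop
            return sigma

        sigma_v = mh_sigma(0, sigma_v, v - Wv @ gamma_v)
        sigma_zl = mh_sigma(1, sigma_zl, zl - Wz @ gamma_z)

        def mh_truncated_pair(idx_mu, mu, sigma, vals, prior_mu):
            """Joint-ish MH: location then scale, truncated-normal population."""
            m0, s0 = prior_mu
            prop = mu + hs[idx_mu] * rng.standard_normal()
            logr = (
                sum(_log_truncnorm(x, prop, sigma) for x in vals)
                - sum(_log_truncnorm(x, mu, sigma) for x in vals)
                - 0.5 * ((prop - m0) / s0) ** 2 + 0.5 * ((mu - m0) / s0) ** 2
            )
            if np.log(rng.random()) < logr:
                acc_hyper[idx_mu] += 1.0
                mu = prop
            props = sigma * np.exp(hs[idx_mu + 1] * rng.standard_normal())
            logr = (
                sum(_log_truncnorm(x, mu, props) for x in vals)
                - sum(_log_truncnorm(x, mu, sigma) for x in vals)
                + _log_halfnormal(props, hn) - _log_halfnormal(sigma, hn)
                + np.log(props) - np.log(sigma)
            )
            if np.log(rng.random()) < logr:
                acc_hyper[idx_mu + 1] += 1.0
                sigma = props
            return mu, sigma

        mu_a, sigma_a = mh_truncated_pair(2, mu_a, sigma_a, a, PRIORS["mu_a"])
        mu_t0, sigma_t0 = mh_truncated_pair(4, mu_t0, sigma_t0, t0, PRIORS["mu_t0"])

        # --- adaptation --------------------------------------------------
        if adapting and (it + 1) % adapt_block == 0:
            for p in names:
                scales[p].adapt(acc[p] / adapt_block)
                acc[p][:] = 0.0
            wz_scale.adapt(acc_wz / adapt_block)
            acc_wz[:] = 0.0
            hyper_scale.adapt(acc_hyper / adapt_block)
            acc_hyper[:] = 0.0

        # --- recording ---------------------------------------------------
        if not adapting and (it - settings.burn_in + 1) % keep_every == 0:
            out["mu_v"][kept] = gamma_v[0]
            for j, c in enumerate(spec.v_columns):
                out[f"beta_v[{c}]"][kept] = gamma_v[1 + j]
            out["sigma_v"][kept] = sigma_v
            out["mu_zl"][kept] = gamma_z[0]
            for j, c in enumerate(spec.z_columns):
                out[f"beta_z[{c}]"][kept] = gamma_z[1 + j]
            out["sigma_zl"][kept] = sigma_zl
            out["mu_a"][kept] = mu_a
            out["sigma_a"][kept] = sigma_a
            out["mu_t0"][kept] = mu_t0
            out["sigma_t0"][kept] = sigma_t0
            if spec.per_trial_z:
                out["w_z"][kept] = wz
            out["deviance"][kept] = -2.0 * float(cur_ll.sum())
            for p, arr in zip(names, (v, a, zl, t0)):
                subj_out[p][kept] = arr
            kept += 1

    return out, subj_out


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    settings: MCMCSettings = MCMCSettings(),
    *,
    store_subject_traces: bool = False,
) -> ModelFit:
    """Fit one hierarchical DDM to a trial table by MCMC.

    Uses fairness-partner, non-control trials with recorded RTs.  For the
    exploratory ZI model, pass the data of a single group.  Non-convergence
    (any group-level R-hat >= 1.01) flags the result and emits a warning; it
    is never silent.
    """
    if spec.per_trial_z and data["group"].nunique() > 1:
        raise ValueError("the ZI model is fitted per group; pass one group's data")
    subjects = _prepare(data, spec)
    rng = np.random.default_rng(settings.seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=settings.chains)
    chain_group, chain_subj = [], []
    for cs in chain_seeds:
        out, subj_out = _run_chain(subjects, spec, settings, int(cs), settings.thin)
        chain_group.append(out)
        chain_subj.append(subj_out)

    samples = {
        k: np.stack([c[k] for c in chain_group]) for k in chain_group[0] if k != "deviance"
    }
    deviance = np.stack([c["deviance"] for c in chain_group])
    samples["deviance"] = deviance
    n = len(subjects)
    mean_subj = {
        p: np.mean([c[p] for c in chain_subj], axis=(0, 1)) for p in ("v", "a", "zl", "t0")
    }
    if store_subject_traces:
        for p in ("v", "a", "zl", "t0"):
            arr = np.stack([c[p] for c in chain_subj])  # (chains, draws, n)
            for i in range(n):
                samples[f"{p}_subj[{subjects[i].pid}]"] = arr[:, :, i]

    wz_mean = float(np.mean(samples["w_z"])) if spec.per_trial_z else 0.0
    d_at_mean = 0.0
    for i, s in enumerate(subjects):
        ll = _subject_loglik(
            s.rt, s.upper, s.lvl, mean_subj["v"][i], mean_subj["a"][i],
            mean_subj["zl"][i], mean_subj["t0"][i], wz_mean, SERIES_EPS,
        )
        d_at_mean += -2.0 * ll

    traces = PosteriorTraces(samples=samples, burn_in=settings.burn_in)
    group_par = [k for k in samples if k != "deviance" and "subj" not in k]
    report = gelman_rubin(traces, parameters=group_par)
    if not report.converged:
        warnings.warn(
            f"model {spec.name}: max R-hat {report.max_rhat:.4f} >= {RHAT_THRESHOLD}; "
            "treat posterior summaries with caution",
            stacklevel=2,
        )
    glabel = data["group"].iloc[0] if data["group"].nunique() == 1 else None
    return ModelFit(
        spec=spec,
        traces=traces,
        dbar=float(deviance.mean()),
        d_at_mean=float(d_at_mean),
        convergence=report,
        settings=settings,
        subject_ids=[s.pid for s in subjects],
        group_label=glabel,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(
    traces: PosteriorTraces, parameters: list[str] | None = None, *, with_geweke: bool = False
) -> ConvergenceReport:
    """Split Gelman-Rubin potential scale reduction per parameter.

    Requires >= 2 chains of equal post-burn-in length.  Geweke z-scores
    (first 10% vs last 50% of each pooled chain) are added on request.
    """
    if traces.n_chains < 2:
        raise ValueError("R-hat needs at least 2 chains")
    names = parameters if parameters is not None else list(traces.samples)
    lengths = {traces.samples[k].shape[1] for k in names}
    if len(lengths) != 1:
        raise ValueError("chains must have equal length")
    rhat = {}
    geweke = {}
    for k in names:
        arr = traces.samples[k]
        if np.allclose(arr.var(axis=1), 0):
            rhat[k] = 1.0  # degenerate constant chains
        else:
            rhat[k] = float(az.rhat(az.convert_to_dataset(arr), method="split")["x"].values)
        if with_geweke:
            geweke[k] = float(np.mean([geweke_z(chain) for chain in arr]))
    return ConvergenceReport(rhat=rhat, geweke=geweke)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    n = len(chain)
    a = chain[: int(first * n)]
    b = chain[int((1.0 - last) * n):]
    def _se(x):
        ess = max(float(az.ess(az.convert_to_dataset(x[None, :]))["x"]), 2.0)
        return float(np.var(x, ddof=1) / ess)
    denom = np.sqrt(_se(a) + _se(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def posterior_mean_subject_params(fit: ModelFit) -> pd.DataFrame:
    """Posterior-mean v, a, z, t0 per subject (needs stored subject traces)."""
    rows = []
    for pid in fit.subject_ids:
        try:
            rows.append(
                dict(
                    participant_id=pid,
                    v=float(fit.traces.pooled(f"v_subj[{pid}]").mean()),
                    a=float(fit.traces.pooled(f"a_subj[{pid}]").mean()),
                    z=float(1.0 / (1.0 + np.exp(-fit.traces.pooled(f"zl_subj[{pid}]").mean()))),
                    t0=float(fit.traces.pooled(f"t0_subj[{pid}]").mean()),
                )
            )
        except KeyError as exc:
            raise KeyError(
                "subject traces were not stored; refit with store_subject_traces=True"
            ) from exc
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk format: long CSV of traces + JSON run summary
# ---------------------------------------------------------------------------


def save_fit(fit: ModelFit, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in fit.traces.samples.items():
        for chain in range(arr.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": chain,
                        "iteration": np.arange(arr.shape[1]),
                        "value": arr[chain],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(d / f"traces_{fit.spec.name}.csv", index=False)
    summary = {
        "model": fit.spec.name,
        "v_covariates": list(fit.spec.v_covariates),
        "z_covariates": list(fit.spec.z_covariates),
        "dic": fit.dic, "dbar": fit.dbar, "pd": fit.p_d, "d_at_mean": fit.d_at_mean,
        "max_rhat": fit.convergence.max_rhat, "converged": fit.converged,
        "rhat": fit.convergence.rhat,
        "settings": {
            "chains": fit.settings.chains, "draws": fit.settings.draws,
            "burn_in": fit.settings.burn_in, "thin": fit.settings.thin,
            "seed": fit.settings.seed,
        },
        "subject_ids": [str(s) for s in fit.subject_ids],
        "group_label": fit.group_label,
    }
    (d / f"summary_{fit.spec.name}.json").write_text(json.dumps(summary, indent=1))


def load_fit(directory, name: str) -> ModelFit:
    d = Path(directory)
    summary = json.loads((d / f"summary_{name}.json").read_text())
    long = pd.read_csv(d / f"traces_{name}.csv")
    samples = {}
    for pname, sub in long.groupby("parameter", sort=False):
        chains = [g.sort_values("iteration")["value"].to_numpy() for _, g in sub.groupby("chain")]
        samples[pname] = np.stack(chains)
    st = summary["settings"]
    spec = ModelSpec(
        summary["model"],
        v_covariates=tuple(summary["v_covariates"]),
        z_covariates=tuple(summary["z_covariates"]),
    )
    traces = PosteriorTraces(samples=samples, burn_in=st["burn_in"])
    return ModelFit(
        spec=spec, traces=traces, dbar=summary["dbar"], d_at_mean=summary["d_at_mean"],
        convergence=ConvergenceReport(rhat=summary["rhat"]),
        settings=MCMCSettings(**st), subject_ids=summary["subject_ids"],
        group_label=summary["group_label"],
    )
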