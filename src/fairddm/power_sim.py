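"""Simulation-based power analysis for the confirmatory logistic GLMM.

Replicates the study's sample-size planning: simulate complete four-group
studies from a logistic generative model — expected probability of a
decision in favour of the other 65% in the compensation groups and 45% in
the punishment groups, with the trial-wise incentive (coded level/100,
0-5) pushing toward the group's incentivized option with weight 0.25 in
the conflict punishment group and 0.15 in the other three groups — then
fit

    response ~ conflict_degree * fairness_domain
               + conflict_degree * incentive_level + (1 | participant)

to each simulated study and count how often each fixed effect reaches
p < alpha.  Power is that fraction with a Clopper-Pearson 95% interval.

The generative model draws independent Bernoulli responses per trial with
no participant random intercept (sigma_u = 0 by default): the analysis
model estimates the intercept variance, the generator does not add one.
This reconstruction is forced by the published interval arithmetic of the
original simulation — the domain x conflict interaction is a
between-subject double difference over four groups of 30, and any
appreciable generative intercept s.d. would cap its power far below the
reported level — so between-subject heterogeneity is treated as an
analysis-model, not a data-generating, feature.  It remains configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import synthetic_data as sd
from .behavioural_stats import (
    CONFIRMATORY_TERMS,
    fit_random_intercept_logistic,
)

__all__ = ["PowerConfig", "PowerResult", "run_power", "simulate_power_study"]


@dataclass(frozen=True)
class PowerConfig:
    """Generative and analysis settings of one power run."""

    n_per_group: int = 30
    trials_per_participant: int = 120
    base_prob: dict = field(
        default_factory=lambda: {sd.COMPENSATION: 0.65, sd.PUNISHMENT: 0.45}
    )
    incentive_weight: dict = field(
        default_factory=lambda: {"conflict_punishment": 0.25, "default": 0.15}
    )
    sigma_u: float = 0.0
    alpha: float = 0.05
    n_sims: int = 100
    seed: int = 0
    n_quad: int = 9

    def __post_init__(self) -> None:
        for p in self.base_prob.values():
            if not 0.0 < p < 1.0:
                raise ValueError("base probabilities must lie in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class PowerResult:
    """Power per fixed effect with binomial confidence intervals."""

    table: pd.DataFrame  # term, power, ci_low, ci_high, n_used
    n_sims: int
    n_dropped: int
    config: PowerConfig

    def power(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "power"])


def _template_trials(trials_per_participant: int, rng: np.random.Generator) -> list:
    """Fairness-partner trial template with balanced incentive levels.

    For the standard 120 the full generated design is used; other counts
    cycle levels x pairings round-robin.
    """
    if trials_per_participant == 120:
        trials = sd.generate_decision_trials(sd.GROUPS[0], rng)
        return [
            t for t in trials if t.partner == sd.FAIRNESS_PARTNER and not t.is_control
        ]
    out = []
    combos = [(lv, pg) for lv in sd.INCENTIVE_LEVELS for pg in sd.PAIRINGS]
    for k in range(trials_per_participant):
        lv, pg = combos[k % len(combos)]
        out.append(sd._experimental_trial(sd.FAIRNESS_PARTNER, lv, pg, rng))
    return out


def simulate_power_study(
    config: PowerConfig, template: list, rng: np.random.Generator
) -> pd.DataFrame:
    """One simulated study: trial-level congruence table for all 4 groups."""
    rows = []
    pid = 0
    for group in sd.GROUPS:
        base = config.base_prob[group.fairness_domain]
        w = config.incentive_weight.get(group.name, config.incentive_weight["default"])
        for _ in range(config.n_per_group):
            pid += 1
            u = rng.normal(0.0, config.sigma_u) if config.sigma_u > 0 else 0.0
            dec = sd.simulate_participant_logistic(group, template, base, w, u, rng)
            for t, d in zip(template, dec):
                decision = sd.FAVOUR_OTHER if d == 1 else sd.FAVOUR_SELF
                rows.append(
                    (
                        pid, group.name, group.fairness_domain, group.conflict_degree,
                        t.partner, t.incentive_level, 0,
                        sd.code_congruence(decision, group),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "fairness_domain", "conflict_degree",
            "partner", "incentive_level", "is_control", "response",
        ],
    )


def run_power(config: PowerConfig = PowerConfig()) -> PowerResult:
    """Estimate power for every fixed effect of the confirmatory model.

    Each simulated study is analysed with the adaptive-quadrature ML GLMM;
    studies whose fit does not converge are dropped from the numerator and
    denominator but counted and reported.  Fully reproducible for a given
    seed.
    """
    rng = np.random.default_rng(config.seed)
    template = _template_trials(config.trials_per_participant, rng)
    terms = [t for t in CONFIRMATORY_TERMS if t != "(Intercept)"]
    hits = {t: 0 for t in terms}
    used = 0
    dropped = 0
    from .behavioural_stats import confirmatory_design

    for _ in range(config.n_sims):
        df = simulate_power_study(config, template, rng)
        y, X, g = confirmatory_design(df)
        fit = fit_random_intercept_logistic(
            y, X, g, CONFIRMATORY_TERMS, model_name="confirmatory", n_quad=config.n_quad
        )
        if not fit.converged:
            dropped += 1
            continue
        used += 1
        tab = fit.table.set_index("term")
        for t in terms:
            if tab.loc[t, "p"] < config.alpha:
                hits[t] += 1

    rows = []
    for t in terms:
        k = hits[t]
        lo, hi = proportion_confint(k, max(used, 1), alpha=0.05, method="beta")
        rows.append(
            dict(term=t, power=k / used if used else np.nan, ci_low=lo, ci_high=hi, n_used=used)
        )
    return PowerResult(
        table=pd.DataFrame(rows), n_sims=config.n_sims, n_dropped=dropped, config=config
    )


def power_with(config: PowerConfig, **overrides) -> PowerResult:
    """Convenience: rerun with selected settings replaced."""
    return run_power(replace(config, **overrides))
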