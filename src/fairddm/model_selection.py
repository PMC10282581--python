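"""DIC model comparison, model averaging, and posterior hypothesis tests.

Models are compared by the deviance information criterion

    DIC = Dbar + pD,    pD = Dbar - D(theta_bar),

with the deviance conditioned on the subject-level parameters.  A more
complex model is selected outright when its DIC is at least 10 lower than
every competitor (lower DIC = better out-of-sample fit; the boundary case
of exactly 10 counts as selected); otherwise all models within 10 DIC of
the minimum form a model-averaging set whose traces are pooled with
weights proportional to exp(-delta_DIC / 2).

Directional hypotheses are evaluated as posterior exceedance
probabilities: the fraction of paired posterior draws in which one
parameter exceeds another, "significant" above 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchical_fit import ModelFit
from .synthetic_data import ALIGNED, COMPENSATION, CONFLICT, PUNISHMENT

__all__ = [
    "SelectionResult",
    "HypothesisOutcome",
    "compute_dic",
    "select_model",
    "averaging_weights",
    "average_models",
    "exceedance",
    "cell_traces",
    "evaluate_hypotheses",
]

DIC_RULE_MARGIN = 10.0
EXCEEDANCE_THRESHOLD = 0.95

#: the four design cells as (conflict_degree, fairness_domain)
CELLS = (
    (ALIGNED, PUNISHMENT),
    (CONFLICT, PUNISHMENT),
    (ALIGNED, COMPENSATION),
    (CONFLICT, COMPENSATION),
)


def compute_dic(deviance: np.ndarray, d_at_mean: float) -> dict[str, float]:
    """DIC components from a posterior deviance trace.

    pD = Dbar - D(theta_bar); DIC = Dbar + pD.  The identity
    DIC = 2 Dbar - D(theta_bar) holds exactly by construction.
    """
    deviance = np.asarray(deviance, dtype=float).reshape(-1)
    if deviance.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(deviance.mean())
    p_d = dbar - float(d_at_mean)
    return {"dbar": dbar, "d_at_mean": float(d_at_mean), "pd": p_d, "dic": dbar + p_d}


@dataclass
class SelectionResult:
    """Winning model(s) and the delta-DIC table."""

    winners: list[ModelFit]
    delta_table: pd.DataFrame
    averaged: bool
    fits: list[ModelFit] = field(repr=False, default_factory=list)

    @property
    def winner_names(self) -> list[str]:
        return [f.spec.name for f in self.winners]


def select_model(fits: list[ModelFit]) -> SelectionResult:
    """Apply the delta-DIC-10 rule with model-averaging fallback.

    The single minimum-DIC model wins outright when all competitors are at
    least 10 DIC above it; otherwise every model within 10 DIC of the
    minimum enters the averaging set.  The result is invariant to the
    order in which fits are supplied.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least 2 fits")
    fits = sorted(fits, key=lambda f: (f.dic, f.spec.name))
    dic_min = fits[0].dic
    table = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "dic": [f.dic for f in fits],
            "pd": [f.p_d for f in fits],
            "delta_dic": [f.dic - dic_min for f in fits],
            "complexity": [f.spec.complexity for f in fits],
        }
    )
    winners = [f for f in fits if f.dic - dic_min < DIC_RULE_MARGIN]
    return SelectionResult(
        winners=winners, delta_table=table, averaged=len(winners) > 1, fits=list(fits)
    )


def averaging_weights(dics: np.ndarray) -> np.ndarray:
    """Normalized exp(-delta_DIC / 2) model weights."""
    dics = np.asarray(dics, dtype=float)
    w = np.exp(-(dics - dics.min()) / 2.0)
    return w / w.sum()


def average_models(
    member_traces: list[np.ndarray],
    dics: list[float] | np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pool one parameter's traces across an averaging set.

    Draw-by-draw, a member model is sampled with probability proportional
    to exp(-delta_DIC / 2) and contributes its value at that draw, so the
    pooled trace has the members' common length.  A member that lacks the
    parameter must be passed as its null-effect trace (e.g. a constant
    zero effect), which is how covariate-free models enter comparisons.
    """
    if len(member_traces) == 0:
        raise ValueError("empty averaging set")
    if len(member_traces) == 1:
        return np.asarray(member_traces[0])
    lengths = {len(t) for t in member_traces}
    if len(lengths) != 1:
        raise ValueError("member traces must have equal length")
    if rng is None:
        rng = np.random.default_rng(0)
    n = lengths.pop()
    w = averaging_weights(np.asarray(dics))
    pick = rng.choice(len(member_traces), size=n, p=w)
    stacked = np.stack([np.asarray(t) for t in member_traces])
    return stacked[pick, np.arange(n)]


def exceedance(trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """P(A > B): fraction of paired posterior draws with A above B."""
    a = np.asarray(trace_a, dtype=float).reshape(-1)
    b = np.asarray(trace_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError(f"trace lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty traces")
    return float(np.mean(a > b))


# ---------------------------------------------------------------------------
# condition-level parameter traces
# ---------------------------------------------------------------------------


def cell_traces(fit: ModelFit, parameter: str) -> dict[tuple[str, str], np.ndarray]:
    """Per-design-cell posterior traces of v or z implied by one model.

    Cells are (conflict_degree, fairness_domain) pairs.  Covariates the
    model omits contribute no offset, so covariate-free models yield
    identical traces in every cell (their null effect).  z is returned on
    the natural (0, 1) scale through the logistic link.
    """
    if parameter == "v":
        base = fit.traces.pooled("mu_v").copy()
        prefix, cols = "beta_v", fit.spec.v_columns
    elif parameter == "z":
        base = fit.traces.pooled("mu_zl").copy()
        prefix, cols = "beta_z", fit.spec.z_columns
    else:
        raise ValueError("parameter must be 'v' or 'z'")
    out = {}
    for conflict, domain in CELLS:
        eta = base.copy()
        ind = {
            "conflict_degree": conflict == CONFLICT,
            "fairness_domain": domain == PUNISHMENT,
            "conflict_degree:fairness_domain": conflict == CONFLICT and domain == PUNISHMENT,
        }
        for c in cols:
            if ind[c]:
                eta = eta + fit.traces.pooled(f"{prefix}[{c}]")
        if parameter == "z":
            eta = 1.0 / (1.0 + np.exp(-eta))
        out[(conflict, domain)] = eta
    return out


@dataclass
class HypothesisOutcome:
    """One directional posterior test at the 95% exceedance threshold."""

    label: str
    probability: float | None
    confirmed: bool
    evaluable: bool
    note: str = ""


def _pooled_cells(result: SelectionResult, parameter: str, rng) -> dict | None:
    """Model-averaged cell traces with the member drawn jointly per draw.

    One member model is picked per posterior draw and supplies ALL four
    cells of that draw, preserving the within-draw contrast structure; a
    covariate-free member therefore contributes exactly tied cells (its
    null effect).
    """
    members = []
    for f in result.winners:
        try:
            members.append(cell_traces(f, parameter))
        except KeyError:
            return None
    lengths = {len(m[CELLS[0]]) for m in members}
    if len(lengths) != 1:
        raise ValueError("winning fits must share trace length for averaging")
    n = lengths.pop()
    if len(members) == 1:
        return members[0]
    w = averaging_weights(np.asarray([f.dic for f in result.winners]))
    pick = rng.choice(len(members), size=n, p=w)
    idx = np.arange(n)
    return {
        cell: np.stack([m[cell] for m in members])[pick, idx] for cell in CELLS
    }


def evaluate_hypotheses(
    result: SelectionResult, rng: np.random.Generator | None = None
) -> dict[str, HypothesisOutcome]:
    """The three decision-process hypotheses on the winning model(s).

    H4 (drift): conflicting incentives slow the fairness-congruent
    accumulation — requires a V model among the winners and
    P(v_aligned > v_conflict) > 95%.
    H5 (bias): conflicting incentives shift the start away from the
    congruent option — a Z model among the winners and
    P(z_aligned > z_conflict) > 95%.
    H6 (domain difference): the conflict effect differs between punishment
    and compensation — V2 and/or Z2 among the winners and the double
    difference (aligned - conflict, punishment vs compensation) exceeding
    zero with > 95% probability in either direction, on v or z.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    winners = result.winner_names
    has_v = any(n.startswith("V") for n in winners)
    has_z = any(n.startswith("Z") for n in winners)
    has_two_cov = any(n in ("V2", "Z2") for n in winners)
    out: dict[str, HypothesisOutcome] = {}

    pooled = {}
    for par in ("v", "z"):
        try:
            pooled[par] = _pooled_cells(result, par, rng)
        except (ValueError, KeyError):
            pooled[par] = None

    def aligned_vs_conflict(par: str) -> float | None:
        cells = pooled[par]
        if cells is None:
            return None
        aligned = 0.5 * (cells[(ALIGNED, PUNISHMENT)] + cells[(ALIGNED, COMPENSATION)])
        conflict = 0.5 * (cells[(CONFLICT, PUNISHMENT)] + cells[(CONFLICT, COMPENSATION)])
        return exceedance(aligned, conflict)

    for label, par, gate, gate_txt in (
        ("H4", "v", has_v, "a V model among the winners"),
        ("H5", "z", has_z, "a Z model among the winners"),
    ):
        p = aligned_vs_conflict(par)
        if p is None:
            out[label] = HypothesisOutcome(
                label, None, False, False, f"not evaluable: {par} traces unavailable"
            )
            continue
        confirmed = gate and p > EXCEEDANCE_THRESHOLD
        note = "" if gate else f"requires {gate_txt}"
        out[label] = HypothesisOutcome(label, p, confirmed, True, note)

    # H6: double difference, either direction, on v and/or z
    probs = {}
    for par in ("v", "z"):
        cells = pooled[par]
        if cells is None:
            continue
        d = (cells[(ALIGNED, PUNISHMENT)] - cells[(CONFLICT, PUNISHMENT)]) - (
            cells[(ALIGNED, COMPENSATION)] - cells[(CONFLICT, COMPENSATION)]
        )
        # ties (models without the contrast contribute d = 0 exactly) count
        # toward neither direction
        p_pun = exceedance(d, np.zeros_like(d))
        p_comp = exceedance(np.zeros_like(d), d)
        probs[par] = max(p_pun, p_comp)
    if not probs:
        out["H6"] = HypothesisOutcome("H6", None, False, False, "not evaluable")
    else:
        par_best = max(probs, key=probs.get)
        p = probs[par_best]
        confirmed = has_two_cov and p > EXCEEDANCE_THRESHOLD
        note = f"largest directional probability on {par_best}; " + (
            "" if has_two_cov else "requires V2 or Z2 among the winners"
        )
        out["H6"] = HypothesisOutcome("H6", p, confirmed, True, note.strip("; "))
    return out
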