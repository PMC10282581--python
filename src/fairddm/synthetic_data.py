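"""Experimental design generator and synthetic participants.

The study this package models is a third-party dictator-game experiment with
four between-subject groups crossing *fairness domain* (punishment: the
decision partner is a prior norm violator; compensation: the partner is the
prior victim) with *conflict degree* (the trial-wise monetary incentive
rewards either the fairness-congruent or the fairness-incongruent option).
Each participant first observes 20 allocation decisions of an unfair
allocator (80% in favour of the self), then makes 240 binary allocation
decisions (120 toward the fairness partner, 120 toward an uninvolved
baseline partner) plus 6 hidden control trials and 12 practice trials.

This module generates that full design and simulates participants' choices
and response times under either a drift-diffusion or a logistic generative
model, plus questionnaire trait scores coupled to behaviour through a
Gaussian copula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from numba import njit

from .ddm_core import DDMParameters, absorption_probability  # noqa: F401

__all__ = [
    "PUNISHMENT",
    "COMPENSATION",
    "ALIGNED",
    "CONFLICT",
    "FAVOUR_SELF",
    "FAVOUR_OTHER",
    "FAIRNESS_PARTNER",
    "BASELINE",
    "GroupCondition",
    "GROUPS",
    "AllocationOption",
    "Trial",
    "ObservationTrial",
    "BehavResponse",
    "PayoutInput",
    "Session",
    "generate_allocation_option",
    "generate_decision_trials",
    "generate_observation_phase",
    "generate_practice_trials",
    "generate_session",
    "code_congruence",
    "decode_congruence",
    "compute_payout",
    "simulate_participant_ddm",
    "simulate_participant_logistic",
    "simulate_traits",
    "simulate_study",
    "write_trials",
    "read_trials",
    "load_config",
    "save_config",
    "TRIAL_COLUMNS",
]

# ---------------------------------------------------------------------------
# factor levels
# ---------------------------------------------------------------------------

PUNISHMENT = "punishment"
COMPENSATION = "compensation"
ALIGNED = "aligned"
CONFLICT = "conflict"
FAVOUR_SELF = "favour_self"
FAVOUR_OTHER = "favour_other"
FAIRNESS_PARTNER = "fairness_partner"
BASELINE = "baseline"

UNFAIR_VS_EQUAL = "unfair_vs_equal"
HYPERFAIR_VS_EQUAL = "hyperfair_vs_equal"
CONTROL_PAIRING = "control"
PAIRINGS = (UNFAIR_VS_EQUAL, HYPERFAIR_VS_EQUAL)

INCENTIVE_LEVELS = (0, 100, 200, 300, 400, 500)
POT_TOTALS = tuple(range(500, 701, 10))
POINTS_PER_EURO_RATE = 0.005  # 100 points = 0.50 EUR
SHOW_UP_FEE = 3.0  # EUR
DECISION_DEADLINE = 4.0  # s

#: self-share bands per distribution category (target ratio +/- 5 points)
CATEGORY_BANDS = {
    "unfair": (0.65, 0.75),
    "equal": (0.45, 0.55),
    "hyperfair": (0.25, 0.35),
}


@dataclass(frozen=True)
class GroupCondition:
    """One cell of the 2 x 2 between-subject design.

    The incentivized decision type is fully determined by the two factors:
    conflicting incentives reward the fairness-incongruent option, aligned
    incentives the congruent one.
    """

    fairness_domain: str
    conflict_degree: str

    def __post_init__(self) -> None:
        if self.fairness_domain not in (PUNISHMENT, COMPENSATION):
            raise ValueError(f"unknown fairness domain {self.fairness_domain!r}")
        if self.conflict_degree not in (ALIGNED, CONFLICT):
            raise ValueError(f"unknown conflict degree {self.conflict_degree!r}")

    @property
    def incentivized_decision(self) -> str:
        # punishment: congruent = favour_self; compensation: congruent = favour_other
        if self.fairness_domain == PUNISHMENT:
            return FAVOUR_OTHER if self.conflict_degree == CONFLICT else FAVOUR_SELF
        return FAVOUR_SELF if self.conflict_degree == CONFLICT else FAVOUR_OTHER

    @property
    def congruent_decision(self) -> str:
        return FAVOUR_SELF if self.fairness_domain == PUNISHMENT else FAVOUR_OTHER

    @property
    def name(self) -> str:
        return f"{self.conflict_degree}_{self.fairness_domain}"


#: the four experimental groups
GROUPS = (
    GroupCondition(PUNISHMENT, CONFLICT),
    GroupCondition(PUNISHMENT, ALIGNED),
    GroupCondition(COMPENSATION, ALIGNED),
    GroupCondition(COMPENSATION, CONFLICT),
)

GROUPS_BY_NAME = {g.name: g for g in GROUPS}


@dataclass(frozen=True)
class AllocationOption:
    """A split of a 500-700 point pot between the decider and the partner."""

    points_self: int
    points_other: int
    category: str

    @property
    def total(self) -> int:
        return self.points_self + self.points_other

    @property
    def self_share(self) -> float:
        return self.points_self / self.total


@dataclass(frozen=True)
class Trial:
    """One decision-task trial.

    ``option_favour_self`` / ``option_favour_other`` are the two displayed
    splits; which distribution category occupies which slot follows from the
    pairing.  For control trials the slot labelled ``option_favour_self``
    holds the option that weakly dominates for BOTH players.
    """

    partner: str
    incentive_level: int
    pairing: str
    option_favour_self: AllocationOption
    option_favour_other: AllocationOption
    is_control: bool = False
    is_practice: bool = False


@dataclass(frozen=True)
class ObservationTrial:
    pairing: str
    allocator_decision: str


@dataclass(frozen=True)
class BehavResponse:
    """One simulated response: chosen option, congruence code, RT (s)."""

    decision: str
    response: int
    rt: float


@dataclass(frozen=True)
class PayoutInput:
    """One drawn trial entering the payout equation."""

    points_self: int
    incentive: int
    decision_type: str
    incentivized_type: str


@dataclass
class Session:
    """All trials of one participant, by phase."""

    group: GroupCondition
    practice: list = field(default_factory=list)
    observation: list = field(default_factory=list)
    decision: list = field(default_factory=list)  # experimental + control, shuffled

    @property
    def n_experimental(self) -> int:
        return sum(1 for t in self.decision if not t.is_control)

    @property
    def n_control(self) -> int:
        return sum(1 for t in self.decision if t.is_control)

    @property
    def n_total(self) -> int:
        return len(self.practice) + len(self.observation) + len(self.decision)


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------


def generate_allocation_option(
    category: str, total: int, rng: np.random.Generator
) -> AllocationOption:
    """Draw one split of ``total`` points for a distribution category.

    The self-share is uniform in the category band (target ratio 70:30,
    50:50 or 30:70, jittered by +/-5 percentage points); points are integers
    summing to the total.
    """
    if category not in CATEGORY_BANDS:
        raise ValueError(f"unknown category {category!r}")
    if total not in POT_TOTALS:
        raise ValueError(f"total must be in 500..700 step 10, got {total}")
    lo, hi = CATEGORY_BANDS[category]
    share = rng.uniform(lo, hi)
    points_self = int(round(share * total))
    # rounding can nudge the share just outside the band at the edges
    points_self = int(np.clip(points_self, math.ceil(lo * total), math.floor(hi * total)))
    return AllocationOption(points_self, total - points_self, category)


def _experimental_trial(partner: str, level: int, pairing: str, rng) -> Trial:
    # pot totals of the two options are drawn independently
    t1 = int(rng.choice(POT_TOTALS))
    t2 = int(rng.choice(POT_TOTALS))
    if pairing == UNFAIR_VS_EQUAL:
        opt_self = generate_allocation_option("unfair", t1, rng)
        opt_other = generate_allocation_option("equal", t2, rng)
    elif pairing == HYPERFAIR_VS_EQUAL:
        opt_self = generate_allocation_option("equal", t1, rng)
        opt_other = generate_allocation_option("hyperfair", t2, rng)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return Trial(partner, level, pairing, opt_self, opt_other)


def _control_trial(partner: str, rng: np.random.Generator) -> Trial:
    """One attention-check trial: the first option dominates for both players."""
    base = generate_allocation_option("equal", int(rng.choice(POT_TOTALS)), rng)
    delta = int(rng.integers(50, 151))
    dominated = AllocationOption(base.points_self - delta, base.points_other - delta, "equal")
    return Trial(partner, 0, CONTROL_PAIRING, base, dominated, is_control=True)


def generate_decision_trials(group: GroupCondition, rng: np.random.Generator) -> list[Trial]:
    """The shuffled decision phase: 240 experimental + 6 control trials.

    Per partner each of the 6 incentive levels meets each of the 2
    distribution pairings exactly 10 times (10 x 2 x 6 = 120 trials per
    partner).
    """
    trials: list[Trial] = []
    for partner in (FAIRNESS_PARTNER, BASELINE):
        for level in INCENTIVE_LEVELS:
            for pairing in PAIRINGS:
                for _ in range(10):
                    trials.append(_experimental_trial(partner, level, pairing, rng))
    for i in range(6):
        partner = FAIRNESS_PARTNER if i % 2 == 0 else BASELINE
        trials.append(_control_trial(partner, rng))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def generate_observation_phase(rng: np.random.Generator) -> list[ObservationTrial]:
    """20 observed allocator decisions: per pairing 8 selfish, 2 generous."""
    trials = []
    for pairing in PAIRINGS:
        trials += [ObservationTrial(pairing, FAVOUR_SELF)] * 8
        trials += [ObservationTrial(pairing, FAVOUR_OTHER)] * 2
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def generate_practice_trials(rng: np.random.Generator) -> list[Trial]:
    """12 practice trials (6 observation-phase, 6 decision-task style).

    Practice trials are flagged and never enter any analysis table.
    """
    out = []
    for i in range(12):
        pairing = PAIRINGS[i % 2]
        t = _experimental_trial(BASELINE, 0, pairing, rng)
        out.append(
            Trial(t.partner, t.incentive_level, t.pairing, t.option_favour_self,
                  t.option_favour_other, is_practice=True)
        )
    return out


def generate_session(group: GroupCondition, rng: np.random.Generator) -> Session:
    """One participant's full session: 12 practice + 20 observation + 246 decisions."""
    return Session(
        group=group,
        practice=generate_practice_trials(rng),
        observation=generate_observation_phase(rng),
        decision=generate_decision_trials(group, rng),
    )


# ---------------------------------------------------------------------------
# congruence coding and payout
# ---------------------------------------------------------------------------


def code_congruence(decision: str, group: GroupCondition) -> int:
    """1 if the decision is the fairness-congruent option for this group.

    Congruent means favour-self toward the norm violator (punishment
    domain) and favour-other toward the victim (compensation domain).
    """
    if decision not in (FAVOUR_SELF, FAVOUR_OTHER):
        raise ValueError(f"unknown decision {decision!r}")
    return int(decision == group.congruent_decision)


def decode_congruence(response: int, group: GroupCondition) -> str:
    """Inverse of :func:`code_congruence`."""
    if response not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {response!r}")
    congruent = group.congruent_decision
    other = FAVOUR_OTHER if congruent == FAVOUR_SELF else FAVOUR_SELF
    return congruent if response == 1 else other


def compute_payout(drawn: list[PayoutInput]) -> tuple[np.ndarray, float]:
    """Euros per drawn trial and the session total (incl. 3 EUR show-up fee).

    A drawn trial pays (points_self + incentive) * 0.005 EUR when the chosen
    decision type matches the group's incentivized type, else
    points_self * 0.005 EUR.
    """
    per_trial = np.empty(len(drawn))
    for i, p in enumerate(drawn):
        if p.points_self < 0 or p.incentive < 0:
            raise ValueError("points and incentive must be non-negative")
        pts = p.points_self
        if p.decision_type == p.incentivized_type:
            pts += p.incentive
        per_trial[i] = pts * POINTS_PER_EURO_RATE
    return per_trial, SHOW_UP_FEE + float(per_trial.sum())


# ---------------------------------------------------------------------------
# response simulators
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sim_ddm_trials(v, a, z, t0, dt, deadline, seed):
    """One diffusion path per trial; redraw while rt exceeds the deadline."""
    np.random.seed(seed)
    n = v.shape[0]
    rts = np.empty(n)
    upper = np.empty(n, dtype=np.bool_)
    sdt = np.sqrt(dt)
    for i in range(n):
        while True:
            x = z[i] * a[i]
            t = 0.0
            hit = False
            done = False
            while not done:
                xn = x + v[i] * dt + sdt * np.random.randn()
                t += dt
                if xn >= a[i]:
                    hit, done = True, True
                elif xn <= 0.0:
                    hit, done = False, True
                elif np.random.rand() < np.exp(-2.0 * (a[i] - x) * (a[i] - xn) / dt):
                    hit, done = True, True
                elif np.random.rand() < np.exp(-2.0 * x * xn / dt):
                    hit, done = False, True
                else:
                    x = xn
            rt = t + t0[i]
            if rt <= deadline:
                rts[i] = rt
                upper[i] = hit
                break
    return rts, upper


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


def simulate_participant_ddm(
    group: GroupCondition,
    trials: list[Trial],
    params: DDMParameters | dict,
    rng: np.random.Generator,
    *,
    z_incentive_weight: float = 0.0,
    control_accuracy: float = 0.98,
    dt: float = 1e-3,
) -> list[BehavResponse]:
    """Simulate one participant's choices/RTs from a Wiener diffusion.

    Upper-boundary absorption maps to the fairness-congruent option
    (response = 1).  ``params`` is a single parameter set or a mapping from
    partner label to parameters.  ``z_incentive_weight`` adds a per-trial
    shift on the logit of the relative start, coded incentive-level/100
    (the generative counterpart of the exploratory bias model).  Responses
    slower than the 4 s deadline are re-drawn, mirroring the task's repeat
    loop.  Control trials are answered with the mutually dominant option at
    ``control_accuracy`` and a lognormal RT.
    """
    if isinstance(params, DDMParameters):
        per_partner = {FAIRNESS_PARTNER: params, BASELINE: params}
    else:
        per_partner = dict(params)
    for p in per_partner.values():
        p.validate()

    task = [(i, t) for i, t in enumerate(trials) if not t.is_control]
    n = len(task)
    v = np.empty(n)
    a = np.empty(n)
    z = np.empty(n)
    t0 = np.empty(n)
    for j, (_, t) in enumerate(task):
        p = per_partner[t.partner]
        v[j], a[j], t0[j] = p.v, p.a, p.t0
        zl = _logit(p.z) + z_incentive_weight * (t.incentive_level / 100.0)
        z[j] = float(_sigmoid(zl))
    seed = int(rng.integers(0, 2**31 - 1))
    rts, upper = _sim_ddm_trials(v, a, z, t0, dt, DECISION_DEADLINE, seed)

    out: list[BehavResponse | None] = [None] * len(trials)
    for j, (i, t) in enumerate(task):
        resp = int(upper[j])
        out[i] = BehavResponse(decode_congruence(resp, group), resp, float(rts[j]))
    for i, t in enumerate(trials):
        if t.is_control:
            correct = rng.random() < control_accuracy
            decision = FAVOUR_SELF if correct else FAVOUR_OTHER  # dominant sits in the self slot
            rt = float(np.clip(rng.lognormal(-0.2, 0.3), 0.35, DECISION_DEADLINE))
            out[i] = BehavResponse(decision, code_congruence(decision, group), rt)
    return out  # type: ignore[return-value]


def simulate_participant_logistic(
    group: GroupCondition,
    trials: list[Trial],
    base_prob: float,
    incentive_weight: float,
    subject_effect: float,
    rng: np.random.Generator,
    *,
    control_accuracy: float = 0.98,
) -> np.ndarray:
    """Binary choices from the logistic generative model.

    The probability of deciding in favour of the other follows

        logit P(favour_other) = logit(base_prob)
                                + w * (incentive/100) * s + subject_effect,

    with s = +1 when the group's incentivized option is favour-other and
    s = -1 otherwise, i.e. the incentive pushes toward the incentivized
    option with weight ``w`` per 100 points.  Returns one 0/1 decision per
    trial (1 = favour_other); control trials pick the dominant (self-slot)
    option with ``control_accuracy``.
    """
    if not 0.0 < base_prob < 1.0:
        raise ValueError(f"base_prob must be in (0, 1), got {base_prob}")
    sign = 1.0 if group.incentivized_decision == FAVOUR_OTHER else -1.0
    out = np.empty(len(trials), dtype=np.int64)
    for i, t in enumerate(trials):
        if t.is_control:
            out[i] = int(rng.random() >= control_accuracy)  # 0 = dominant self-slot
            continue
        eta = _logit(base_prob) + incentive_weight * (t.incentive_level / 100.0) * sign
        eta += subject_effect
        out[i] = int(rng.random() < _sigmoid(eta))
    return out


#: synthetic questionnaire scale locations/spreads (mimic the named
#: instruments' ranges; not validated psychometrics)
TRAIT_SCALES = {
    "anger": (18.0, 5.0),
    "altruism": (3.5, 0.7),
    "js_observer": (2.5, 1.0),
    "js_victim": (2.5, 1.0),
    "js_perpetrator": (2.5, 1.0),
}


def simulate_traits(
    n: int,
    coupling: float,
    behaviour_summary: np.ndarray | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-participant trait scores, optionally coupled to behaviour.

    ``js_perpetrator`` is built through a Gaussian copula so that its
    population correlation with the standardized per-participant congruent
    rate equals ``coupling``; the remaining scales are independent noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    cols = {}
    for name, (mu, sd) in TRAIT_SCALES.items():
        if name == "js_perpetrator" and coupling != 0.0 and behaviour_summary is not None:
            b = np.asarray(behaviour_summary, dtype=float)
            if b.shape[0] != n:
                raise ValueError("behaviour_summary length must equal n")
            sb = b.std()
            zb = (b - b.mean()) / (sb if sb > 0 else 1.0)
            latent = coupling * zb + math.sqrt(1.0 - coupling**2) * rng.standard_normal(n)
            cols[name] = mu + sd * latent
        else:
            cols[name] = mu + sd * rng.standard_normal(n)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# study-level simulation and I/O
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "participant_id", "group", "fairness_domain", "conflict_degree", "partner",
    "trial_index", "incentive_level", "pairing",
    "points_self_opt1", "points_other_opt1", "points_self_opt2", "points_other_opt2",
    "is_control", "decision", "response", "rt_s",
]

#: default generative diffusion parameters for the study conditions:
#: drift toward the congruent boundary = base + domain bonus (punishment is
#: the more efficient domain) + conflict penalty + norm-activation bonus for
#: the fairness partner; boundary, start and non-decision time shared across
#: conditions within subject.
DDM_GENERATIVE = {
    "v_base": 0.6,
    "v_conflict_effect": -0.8,
    "v_punishment_effect": 0.3,
    "v_partner_effect": 0.15,
    "v_subject_sd": 0.3,
    "a_mean": 1.6,
    "a_sd": 0.15,
    "z_logit_sd": 0.2,
    "z_conflict_effect": 0.0,   # logit-scale start-point shifts by condition
    "z_punishment_effect": 0.0,
    "z_incentive_weight": 0.0,  # per-trial logit shift per 100 incentive points
    "t0_mean": 0.35,
    "t0_sd": 0.05,
}

#: default logistic generative parameters (decision scale, favour-other)
LOGISTIC_GENERATIVE = {
    "base_prob": {COMPENSATION: 0.65, PUNISHMENT: 0.45},
    "incentive_weight": {"conflict_punishment": 0.25, "default": 0.15},
    "sigma_u": 1.0,
    "partner_effect": 0.15,  # toward the congruent option, fairness partner only
}


def _group_mean_v(group: GroupCondition, partner: str, g: dict) -> float:
    v = g["v_base"]
    if group.fairness_domain == PUNISHMENT:
        v += g["v_punishment_effect"]
    if group.conflict_degree == CONFLICT:
        v += g["v_conflict_effect"]
    if partner == FAIRNESS_PARTNER:
        v += g["v_partner_effect"]
    return v


def simulate_study(
    n_per_group: int = 30,
    model: str = "ddm",
    seed: int = 0,
    *,
    groups: tuple[GroupCondition, ...] = GROUPS,
    ddm_params: dict | None = None,
    logistic_params: dict | None = None,
    n_careless_per_group: int = 0,
    control_accuracy: float = 0.98,
) -> pd.DataFrame:
    """Simulate the complete four-group study as a trial-level table.

    ``model`` selects the generative process: "ddm" produces choices and
    RTs from a Wiener diffusion with condition-dependent drift; "logistic"
    produces binary choices (RT left missing) from the logistic model.
    ``n_careless_per_group`` appends extra participants who fail control
    trials at chance and respond fast (for exercising the quality filters).
    Identical seeds yield identical tables.
    """
    if model not in ("ddm", "logistic"):
        raise ValueError(f"model must be 'ddm' or 'logistic', got {model!r}")
    rng = np.random.default_rng(seed)
    gpar = {**DDM_GENERATIVE, **(ddm_params or {})}
    lpar = {**LOGISTIC_GENERATIVE, **(logistic_params or {})}
    rows = []
    pid = 0
    for group in groups:
        for j in range(n_per_group + n_careless_per_group):
            careless = j >= n_per_group
            pid += 1
            session = generate_session(group, rng)
            trials = session.decision
            if model == "ddm":
                dv_subj = rng.normal(0.0, gpar["v_subject_sd"])
                a_i = max(0.5, rng.normal(gpar["a_mean"], gpar["a_sd"]))
                zl_i = rng.normal(0.0, gpar["z_logit_sd"])
                if group.conflict_degree == CONFLICT:
                    zl_i += gpar["z_conflict_effect"]
                if group.fairness_domain == PUNISHMENT:
                    zl_i += gpar["z_punishment_effect"]
                z_i = float(_sigmoid(zl_i))
                t0_i = float(np.clip(rng.normal(gpar["t0_mean"], gpar["t0_sd"]), 0.1, 1.0))
                params = {
                    p: DDMParameters(_group_mean_v(group, p, gpar) + dv_subj, a_i, z_i, t0_i)
                    for p in (FAIRNESS_PARTNER, BASELINE)
                }
                acc = 0.5 if careless else control_accuracy
                responses = simulate_participant_ddm(
                    group, trials, params, rng, control_accuracy=acc,
                    z_incentive_weight=gpar["z_incentive_weight"],
                )
                if careless:
                    responses = [BehavResponse(r.decision, r.response, 0.3) for r in responses]
                decision = [r.decision for r in responses]
                response = [r.response for r in responses]
                rt = [r.rt for r in responses]
            else:
                u_i = rng.normal(0.0, lpar["sigma_u"])
                w = lpar["incentive_weight"].get(
                    group.name, lpar["incentive_weight"]["default"]
                )
                base = lpar["base_prob"][group.fairness_domain]
                # norm-activation bonus toward the congruent option, fairness partner only
                bonus = lpar["partner_effect"] * (
                    1.0 if group.congruent_decision == FAVOUR_OTHER else -1.0
                )
                decision, response, rt = [], [], []
                dec_bin = np.empty(len(trials), dtype=np.int64)
                for part, shift in ((FAIRNESS_PARTNER, bonus), (BASELINE, 0.0)):
                    sub = [t for t in trials if t.partner == part]
                    idx = [i for i, t in enumerate(trials) if t.partner == part]
                    bp = float(_sigmoid(_logit(base) + shift))
                    acc = 0.5 if careless else control_accuracy
                    d = simulate_participant_logistic(
                        group, sub, bp, w, u_i, rng, control_accuracy=acc
                    )
                    dec_bin[idx] = d
                for i, t in enumerate(trials):
                    dec = FAVOUR_OTHER if dec_bin[i] == 1 else FAVOUR_SELF
                    decision.append(dec)
                    response.append(code_congruence(dec, group))
                    rt.append(np.nan)
            for k, t in enumerate(trials):
                rows.append(
                    (
                        pid, group.name, group.fairness_domain, group.conflict_degree,
                        t.partner, k, t.incentive_level, t.pairing,
                        t.option_favour_self.points_self, t.option_favour_self.points_other,
                        t.option_favour_other.points_self, t.option_favour_other.points_other,
                        int(t.is_control), decision[k], response[k], rt[k],
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV; missing RTs become empty fields."""
    df.to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table misses columns: {missing}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
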