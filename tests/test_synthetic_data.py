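"""Design generation, congruence coding, payouts, and participant simulators."""

import io
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fairddm import ddm_core as dc
from fairddm import synthetic_data as sd


GROUP = sd.GROUPS_BY_NAME
PUN_CONFLICT = GROUP["conflict_punishment"]
PUN_ALIGNED = GROUP["aligned_punishment"]
COMP_CONFLICT = GROUP["conflict_compensation"]
COMP_ALIGNED = GROUP["aligned_compensation"]


class TestGroupCondition:
    @pytest.mark.parametrize(
        "group,expected",
        [
            (PUN_CONFLICT, sd.FAVOUR_OTHER),
            (PUN_ALIGNED, sd.FAVOUR_SELF),
            (COMP_ALIGNED, sd.FAVOUR_OTHER),
            (COMP_CONFLICT, sd.FAVOUR_SELF),
        ],
    )
    def test_incentivized_decision_follows_design(self, group, expected):
        """Conflicting incentives reward the fairness-incongruent option."""
        assert group.incentivized_decision == expected

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            sd.GroupCondition("revenge", sd.ALIGNED)
        with pytest.raises(ValueError):
            sd.GroupCondition(sd.PUNISHMENT, "maybe")


class TestAllocationOptions:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        category=st.sampled_from(["unfair", "equal", "hyperfair"]),
        total=st.sampled_from(sd.POT_TOTALS),
        seed=st.integers(0, 10_000),
    )
    def test_generated_options_stay_in_band(self, category, total, seed):
        opt = sd.generate_allocation_option(category, total, np.random.default_rng(seed))
        lo, hi = sd.CATEGORY_BANDS[category]
        assert opt.points_self + opt.points_other == total
        assert opt.points_self >= 0 and opt.points_other >= 0
        assert lo <= opt.self_share <= hi
        assert isinstance(opt.points_self, int)

    @pytest.mark.parametrize(
        "category,points_self,points_other",
        [("unfair", 449, 201), ("equal", 283, 277), ("hyperfair", 192, 488)],
    )
    def test_published_example_splits_are_valid(self, category, points_self, points_other):
        """The task's worked example splits fall inside the jitter bands."""
        total = points_self + points_other
        assert total in sd.POT_TOTALS
        lo, hi = sd.CATEGORY_BANDS[category]
        assert lo <= points_self / total <= hi

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.generate_allocation_option("generous", 500, rng)
        with pytest.raises(ValueError):
            sd.generate_allocation_option("equal", 505, rng)
        with pytest.raises(ValueError):
            sd.generate_allocation_option("equal", 710, rng)


@pytest.fixture(scope="module")
def decision_trials():
    return sd.generate_decision_trials(PUN_CONFLICT, np.random.default_rng(2))


@pytest.fixture(scope="module")
def aligned_trials():
    return sd.generate_decision_trials(PUN_ALIGNED, np.random.default_rng(4))


@pytest.fixture(scope="module")
def comp_trials():
    return sd.generate_decision_trials(COMP_ALIGNED, np.random.default_rng(4))


class TestDecisionTrials:
    def test_trial_counts(self, decision_trials):
        assert len(decision_trials) == 246
        assert sum(t.is_control for t in decision_trials) == 6
        per_partner = Counter(t.partner for t in decision_trials if not t.is_control)
        assert per_partner[sd.FAIRNESS_PARTNER] == 120
        assert per_partner[sd.BASELINE] == 120

    def test_design_cells_balanced(self, decision_trials):
        cells = Counter(
            (t.partner, t.incentive_level, t.pairing) for t in decision_trials if not t.is_control
        )
        assert len(cells) == 2 * 6 * 2
        assert set(cells.values()) == {10}

    def test_pairing_assigns_categories(self, decision_trials):
        for t in decision_trials:
            if t.is_control:
                continue
            if t.pairing == sd.UNFAIR_VS_EQUAL:
                assert t.option_favour_self.category == "unfair"
                assert t.option_favour_other.category == "equal"
            else:
                assert t.option_favour_self.category == "equal"
                assert t.option_favour_other.category == "hyperfair"

    def test_control_trials_dominate_for_both_players(self, decision_trials):
        for t in decision_trials:
            if not t.is_control:
                continue
            dom, sub = t.option_favour_self, t.option_favour_other
            assert dom.points_self >= sub.points_self + 50
            assert dom.points_other >= sub.points_other + 50


class TestObservationPhase:
    def test_composition(self, rng):
        obs = sd.generate_observation_phase(rng)
        assert len(obs) == 20
        assert sum(o.allocator_decision == sd.FAVOUR_SELF for o in obs) == 16
        for pairing in sd.PAIRINGS:
            sub = [o for o in obs if o.pairing == pairing]
            assert len(sub) == 10
            assert sum(o.allocator_decision == sd.FAVOUR_OTHER for o in sub) == 2


class TestSession:
    def test_trial_count_conservation(self, rng):
        """practice (12) + observation (20) + experimental (240) + control (6)."""
        ses = sd.generate_session(COMP_ALIGNED, rng)
        assert len(ses.practice) == 12
        assert len(ses.observation) == 20
        assert ses.n_experimental == 240
        assert ses.n_control == 6
        assert ses.n_total == 278
        assert all(t.is_practice for t in ses.practice)


class TestCongruenceCoding:
    @pytest.mark.parametrize(
        "decision,group,expected",
        [
            (sd.FAVOUR_SELF, PUN_CONFLICT, 1),
            (sd.FAVOUR_SELF, PUN_ALIGNED, 1),
            (sd.FAVOUR_SELF, COMP_ALIGNED, 0),
            (sd.FAVOUR_OTHER, COMP_CONFLICT, 1),
            (sd.FAVOUR_OTHER, PUN_ALIGNED, 0),
        ],
    )
    def test_coding(self, decision, group, expected):
        assert sd.code_congruence(decision, group) == expected

    @pytest.mark.parametrize("group", sd.GROUPS)
    @pytest.mark.parametrize("decision", [sd.FAVOUR_SELF, sd.FAVOUR_OTHER])
    def test_decode_inverts_code(self, group, decision):
        assert sd.decode_congruence(sd.code_congruence(decision, group), group) == decision

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.code_congruence("abstain", PUN_ALIGNED)
        with pytest.raises(ValueError):
            sd.decode_congruence(2, PUN_ALIGNED)


class TestPayout:
    def test_incentive_paid_only_when_types_match(self):
        per, total = sd.compute_payout(
            [sd.PayoutInput(449, 500, sd.FAVOUR_SELF, sd.FAVOUR_SELF)]
        )
        assert per[0] == pytest.approx(4.745)
        per2, _ = sd.compute_payout(
            [sd.PayoutInput(449, 500, sd.FAVOUR_SELF, sd.FAVOUR_OTHER)]
        )
        assert per2[0] == pytest.approx(2.245)
        assert total == pytest.approx(3.0 + 4.745)

    def test_zero_case(self):
        per, total = sd.compute_payout([sd.PayoutInput(0, 0, sd.FAVOUR_SELF, sd.FAVOUR_SELF)])
        assert per[0] == 0.0
        assert total == pytest.approx(3.0)

    def test_negative_points_rejected(self):
        with pytest.raises(ValueError):
            sd.compute_payout([sd.PayoutInput(-1, 0, sd.FAVOUR_SELF, sd.FAVOUR_SELF)])

    def test_monotone_in_incentive(self):
        """Non-decreasing in incentive when types match, constant otherwise."""
        matched = [
            sd.compute_payout([sd.PayoutInput(300, inc, sd.FAVOUR_SELF, sd.FAVOUR_SELF)])[1]
            for inc in sd.INCENTIVE_LEVELS
        ]
        assert all(b > a for a, b in zip(matched, matched[1:]))
        mismatched = [
            sd.compute_payout([sd.PayoutInput(300, inc, sd.FAVOUR_SELF, sd.FAVOUR_OTHER)])[1]
            for inc in sd.INCENTIVE_LEVELS
        ]
        assert len(set(mismatched)) == 1


class TestDDMSimulator:
    def test_driftless_unbiased_is_symmetric(self, aligned_trials, rng):
        params = sd.DDMParameters(0.0, 1.8, 0.5, 0.3)
        resp = sd.simulate_participant_ddm(PUN_ALIGNED, aligned_trials, params, rng)
        frac = np.mean([r.response for r, t in zip(resp, aligned_trials) if not t.is_control])
        mc_se = np.sqrt(0.25 / 240)
        assert frac == pytest.approx(0.5, abs=3 * mc_se)

    def test_congruent_fraction_matches_absorption(self, aligned_trials, rng):
        params = sd.DDMParameters(1.0, 2.0, 0.5, 0.3)
        resp = sd.simulate_participant_ddm(PUN_ALIGNED, aligned_trials, params, rng)
        frac = np.mean([r.response for r, t in zip(resp, aligned_trials) if not t.is_control])
        p = dc.absorption_probability(params)
        mc_se = np.sqrt(p * (1 - p) / 240)
        assert frac == pytest.approx(p, abs=3 * mc_se)

    def test_rts_respect_deadline_and_t0(self, aligned_trials, rng):
        params = sd.DDMParameters(0.2, 2.5, 0.5, 0.4)
        resp = sd.simulate_participant_ddm(PUN_ALIGNED, aligned_trials, params, rng)
        rts = np.array([r.rt for r, t in zip(resp, aligned_trials) if not t.is_control])
        assert rts.max() <= 4.0
        assert rts.min() > params.t0

    def test_invalid_boundary_rejected(self, aligned_trials, rng):
        with pytest.raises(ValueError):
            sd.simulate_participant_ddm(
                PUN_ALIGNED, aligned_trials, sd.DDMParameters(1.0, -1.0, 0.5, 0.3), rng
            )


class TestLogisticSimulator:
    @pytest.mark.parametrize("base", [0.65, 0.45])
    def test_base_rate_recovered_without_incentive(self, comp_trials, base, rng):
        dec = sd.simulate_participant_logistic(COMP_ALIGNED, comp_trials, base, 0.0, 0.0, rng)
        mask = np.array([not t.is_control for t in comp_trials])
        mc_se = np.sqrt(base * (1 - base) / mask.sum())
        assert dec[mask].mean() == pytest.approx(base, abs=3 * mc_se)

    def test_large_subject_effect_saturates(self, comp_trials, rng):
        dec = sd.simulate_participant_logistic(COMP_ALIGNED, comp_trials, 0.5, 0.0, 50.0, rng)
        mask = np.array([not t.is_control for t in comp_trials])
        assert dec[mask].mean() == 1.0

    def test_incentive_pushes_toward_incentivized_option(self, comp_trials, rng):
        # aligned compensation: favour-other incentivized; weight raises the rate
        high = [t for t in comp_trials if not t.is_control and t.incentive_level == 500]
        dec = sd.simulate_participant_logistic(COMP_ALIGNED, high, 0.5, 0.5, 0.0, rng)
        assert dec.mean() > 0.8  # logit 2.5 -> p = 0.924

    def test_invalid_base_prob(self, comp_trials, rng):
        with pytest.raises(ValueError):
            sd.simulate_participant_logistic(COMP_ALIGNED, comp_trials, 1.0, 0.0, 0.0, rng)


class TestTraits:
    def test_record_shape(self, rng):
        tr = sd.simulate_traits(30, 0.0, None, rng)
        assert tr.shape == (30, 5)
        assert list(tr.columns) == list(sd.TRAIT_SCALES)
        assert np.isfinite(tr.to_numpy()).all()

    def test_zero_coupling_uncorrelated(self, rng):
        n = 4000
        b = rng.random(n)
        tr = sd.simulate_traits(n, 0.0, b, rng)
        r = np.corrcoef(tr["js_perpetrator"], b)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_copula_coupling_recovered(self, rng):
        n = 10_000
        b = rng.random(n)
        tr = sd.simulate_traits(n, 0.5, b, rng)
        r = np.corrcoef(tr["js_perpetrator"], b)[0, 1]
        assert 0.45 <= r <= 0.55


class TestStudyTable:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        sd.write_trials(sd.simulate_study(n_per_group=2, model="logistic", seed=77), a)
        sd.write_trials(sd.simulate_study(n_per_group=2, model="logistic", seed=77), b)
        assert a.read_bytes() == b.read_bytes()

    def test_logistic_model_leaves_rt_missing(self, small_logistic_study):
        assert small_logistic_study["rt_s"].isna().all()
        text = io.StringIO()
        sd.write_trials(small_logistic_study, text)
        line = text.getvalue().splitlines()[1]
        assert line.endswith(",")  # missing RT is an empty trailing field

    def test_roundtrip_preserves_table(self, tmp_path, small_ddm_study):
        path = tmp_path / "t.csv"
        sd.write_trials(small_ddm_study, path)
        back = sd.read_trials(path)
        assert list(back.columns) == sd.TRIAL_COLUMNS
        pd.testing.assert_frame_equal(
            back, small_ddm_study, check_exact=False, atol=1e-6
        )

    def test_reader_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"participant_id": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="misses columns"):
            sd.read_trials(path)

    def test_every_generated_option_passes_band_checks(self, small_ddm_study):
        df = small_ddm_study[small_ddm_study["is_control"] == 0]
        for s, o, cats in (
            ("points_self_opt1", "points_other_opt1", ("unfair", "equal")),
            ("points_self_opt2", "points_other_opt2", ("equal", "hyperfair")),
        ):
            total = df[s] + df[o]
            assert total.isin(sd.POT_TOTALS).all()
            share = df[s] / total
            lo = min(sd.CATEGORY_BANDS[c][0] for c in cats)
            hi = max(sd.CATEGORY_BANDS[c][1] for c in cats)
            assert share.between(lo, hi).all()
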