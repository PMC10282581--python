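"""Quality filters, logistic mixed models, and trait correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fairddm import behavioural_stats as bs
from fairddm import synthetic_data as sd


def _qc_frame(rows):
    """Minimal trial table for QC tests: (pid, is_control, decision, rt)."""
    return pd.DataFrame(
        [
            dict(
                participant_id=pid, group="aligned_punishment",
                fairness_domain="punishment", conflict_degree="aligned",
                partner=sd.FAIRNESS_PARTNER, trial_index=i, incentive_level=0,
                pairing="unfair_vs_equal", points_self_opt1=350, points_other_opt1=150,
                points_self_opt2=250, points_other_opt2=250,
                is_control=ctrl, decision=dec, response=1, rt_s=rt,
            )
            for pid, trials in rows.items()
            for i, (ctrl, dec, rt) in enumerate(trials)
        ]
    )


class TestQualityFilters:
    def test_exclusion_rules(self):
        ok = [(0, sd.FAVOUR_SELF, 1.2)] * 6
        df = _qc_frame(
            {
                # fails 2 of 6 controls -> excluded
                1: [(1, sd.FAVOUR_OTHER, 1.0)] * 2 + [(1, sd.FAVOUR_SELF, 1.0)] * 4 + ok,
                # mean RT 0.4 s -> excluded
                2: [(1, sd.FAVOUR_SELF, 0.4)] * 6 + [(0, sd.FAVOUR_SELF, 0.4)] * 6,
                # 1 control failure, slow enough -> retained
                3: [(1, sd.FAVOUR_OTHER, 1.0)] + [(1, sd.FAVOUR_SELF, 1.0)] * 5 + ok,
            }
        )
        clean, report = bs.apply_quality_filters(df)
        rep = report.set_index("participant_id")
        assert rep.loc[1, "excluded"] and "control" in rep.loc[1, "reason"]
        assert rep.loc[2, "excluded"] and "rt" in rep.loc[2, "reason"]
        assert not rep.loc[3, "excluded"]
        assert set(clean["participant_id"]) == {3}
        assert (clean["is_control"] == 0).all()

    def test_missing_controls_skip_with_warning(self):
        df = _qc_frame({1: [(0, sd.FAVOUR_SELF, 1.0)] * 6})
        with pytest.warns(UserWarning, match="control"):
            clean, report = bs.apply_quality_filters(df)
        assert report["qc_skipped"].all()
        assert len(clean) == 6

    def test_careless_participants_caught_in_simulated_study(self):
        df = sd.simulate_study(
            n_per_group=2, model="logistic", seed=41, n_careless_per_group=1
        )
        _, report = bs.apply_quality_filters(df)
        assert report["excluded"].sum() >= 3  # control failures at chance


def _simulate_cluster_data(rng, n_groups, m, beta, sigma_u, x_fn):
    g = np.repeat(np.arange(n_groups), m)
    X = x_fn(rng, n_groups * m)
    u = rng.normal(0, sigma_u, n_groups)
    y = (rng.random(len(g)) < expit(X @ beta + u[g])).astype(float)
    return y, X, g


class TestRandomInterceptLogistic:
    def test_reduces_to_plain_logistic_without_clustering(self, rng):
        """sigma_u = 0 data: estimates match ordinary logistic regression."""
        import statsmodels.api as smapi

        beta = np.array([0.3, -0.8])
        y, X, g = _simulate_cluster_data(
            rng, 40, 50, beta, 0.0,
            lambda r, n: np.column_stack([np.ones(n), r.standard_normal(n)]),
        )
        mine = bs.fit_random_intercept_logistic(y, X, g, ["b0", "b1"])
        ref = smapi.Logit(y, X).fit(disp=0)
        assert np.max(np.abs(mine.table["estimate"].to_numpy() - ref.params)) < 1e-3

    def test_matches_lme4_oracle(self, small_logistic_study):
        """Independent cross-check of the adaptive-quadrature ML fit against
        glmer on the same random-intercept model."""
        sub = small_logistic_study[
            (small_logistic_study["fairness_domain"] == "punishment")
            & (small_logistic_study["is_control"] == 0)
        ]
        c = bs._codes(sub)
        X = np.column_stack(
            [np.ones(len(sub)), c["partner"], c["conflict"], c["partner"] * c["conflict"]]
        )
        mine = bs.fit_random_intercept_logistic(
            sub["response"].to_numpy(float), X, sub["participant_id"].to_numpy(),
            ["(Intercept)", "partner", "conflict", "partner:conflict"],
        )
        rdf = pd.DataFrame(
            {
                "participant_id": sub["participant_id"],
                "response": sub["response"].astype(int),
                "partner": c["partner"], "conflict": c["conflict"],
            }
        )
        oracle = bs._fit_glmer_r(
            rdf, "response ~ partner * conflict + (1 | participant_id)", "oracle"
        )
        assert oracle is not None, "lme4 backend unavailable"
        assert np.max(
            np.abs(mine.table["estimate"].to_numpy() - oracle.table["estimate"].to_numpy())
        ) < 2e-3
        assert np.max(
            np.abs(mine.table["se"].to_numpy() - oracle.table["se"].to_numpy())
        ) < 2e-3
        assert mine.sigma_u == pytest.approx(oracle.sigma_u, abs=5e-3)

    def test_wald_z_consistent_with_estimate_and_se(self, rng):
        y, X, g = _simulate_cluster_data(
            rng, 20, 40, np.array([0.2, 0.5]), 0.5,
            lambda r, n: np.column_stack([np.ones(n), r.standard_normal(n)]),
        )
        res = bs.fit_random_intercept_logistic(y, X, g, ["b0", "b1"])
        np.testing.assert_allclose(
            res.table["z"], res.table["estimate"] / res.table["se"], atol=1e-6
        )
        assert res.n_obs == len(y)


class TestConfirmatoryModel:
    def test_uses_only_fairness_partner_trials(self, small_logistic_study):
        res = bs.fit_confirmatory_glmm(small_logistic_study)
        n_expected = (
            (small_logistic_study["partner"] == sd.FAIRNESS_PARTNER)
            & (small_logistic_study["is_control"] == 0)
        ).sum()
        assert res.n_obs == n_expected
        assert res.table["term"].tolist() == bs.CONFIRMATORY_TERMS

    def test_full_study_has_14400_observations(self):
        """120 participants x 120 fairness-partner trials enter the model."""
        # fully attentive participants: the study recruited until 120 passed QC
        df = sd.simulate_study(n_per_group=30, model="logistic", seed=1, control_accuracy=1.0)
        clean, report = bs.apply_quality_filters(df)
        assert not report["excluded"].any()
        res = bs.fit_confirmatory_glmm(clean, n_quad=5)
        assert res.n_obs == 14_400

    def test_conflict_incentive_interaction_is_negative(self, small_logistic_study):
        """Under the study's generative model, larger conflicting incentives
        reduce congruent responding."""
        res = bs.fit_confirmatory_glmm(small_logistic_study)
        assert res.coef("conflict_degree:incentive_level")["estimate"] < 0


class TestManipulationModels:
    def test_strong_incentive_type_effect_detected(self, rng):
        rows = []
        for gi, group in enumerate(sd.GROUPS):
            p_other = 0.8 if group.incentivized_decision == sd.FAVOUR_OTHER else 0.2
            for j in range(6):
                pid = gi * 6 + j
                dec = rng.random(80) < p_other
                for k, d in enumerate(dec):
                    rows.append(
                        dict(
                            participant_id=pid, group=group.name,
                            fairness_domain=group.fairness_domain,
                            conflict_degree=group.conflict_degree,
                            partner=sd.FAIRNESS_PARTNER if k % 2 else sd.BASELINE,
                            incentive_level=0, pairing="unfair_vs_equal",
                            is_control=0,
                            decision=sd.FAVOUR_OTHER if d else sd.FAVOUR_SELF,
                            response=0, rt_s=np.nan,
                        )
                    )
        df = pd.DataFrame(rows)
        res = bs.fit_manipulation_glmms(df, use_r_backend=False)
        inc = res["manipulation_decision_incentive_type"].coef("incentive_type")
        assert inc["estimate"] > 0
        assert inc["p"] < 0.05

    def test_partner_effect_null_calibration(self, rng):
        """Identical behaviour toward both partners keeps the partner
        coefficient non-significant in most replicates."""
        hits = 0
        reps = 10
        for _ in range(reps):
            g = np.repeat(np.arange(16), 120)
            partner = np.tile(np.repeat([0.0, 1.0], 60), 16)
            y = (rng.random(len(g)) < 0.5).astype(float)
            X = np.column_stack([np.ones(len(g)), partner])
            res = bs.fit_random_intercept_logistic(y, X, g, ["(Intercept)", "partner"])
            if abs(res.coef("partner")["z"]) >= 1.96:
                hits += 1
        assert hits <= 2

    def test_singular_slope_falls_back_to_intercept_only(self, small_logistic_study):
        """Data generated with no distribution-type slope variance yields a
        singular lme4 fit, triggering the flagged intercept-only refit."""
        res = bs.fit_manipulation_glmms(small_logistic_study, use_r_backend=True)
        for dom in ("punishment", "compensation"):
            fit = res[f"manipulation_response_{dom}"]
            assert fit.converged
            # either the slope model was estimable or the flagged fallback ran
            assert ("backend=lme4" in fit.flags) or (
                "random_intercept_only_fallback" in fit.flags
            )


class TestTraitCorrelations:
    def _rates(self, n_per_group, rng):
        rows = []
        for g in sd.GROUPS:
            for j in range(n_per_group):
                rows.append(
                    dict(participant_id=len(rows), group=g.name,
                         congruent_rate=rng.random())
                )
        return pd.DataFrame(rows)

    def test_bonferroni_factor_is_five(self, rng):
        rates = self._rates(10, rng)
        traits = sd.simulate_traits(len(rates), 0.0, None, rng)
        out = bs.trait_correlations(rates, traits)
        ok = out["p_uncorrected"].notna()
        np.testing.assert_allclose(
            out.loc[ok, "p_bonferroni"],
            np.minimum(1.0, 5 * out.loc[ok, "p_uncorrected"]),
        )

    def test_coupled_scale_survives_correction(self, rng):
        rates = self._rates(30, rng)
        traits = sd.simulate_traits(
            len(rates), 0.6, rates["congruent_rate"].to_numpy(), rng
        )
        out = bs.trait_correlations(rates, traits)
        perp = out[out["scale"] == "js_perpetrator"]
        assert (perp["p_bonferroni"] < 0.05).all()

    def test_independent_traits_rarely_significant(self, rng):
        rates = self._rates(30, rng)
        traits = sd.simulate_traits(len(rates), 0.0, None, rng)
        out = bs.trait_correlations(rates, traits)
        assert (out["p_uncorrected"] < 0.05).sum() <= 4  # of 20 tests

    def test_zero_variance_trait_reported_undefined(self, rng):
        rates = self._rates(5, rng)
        traits = sd.simulate_traits(len(rates), 0.0, None, rng)
        traits["anger"] = 10.0
        out = bs.trait_correlations(rates, traits)
        anger = out[out["scale"] == "anger"]
        assert anger["r"].isna().all()
        assert (anger["note"] == "undefined: zero variance").all()

    def test_too_few_participants_rejected(self, rng):
        rates = self._rates(2, rng)
        traits = sd.simulate_traits(len(rates), 0.0, None, rng)
        with pytest.raises(ValueError, match="fewer than 3"):
            bs.trait_correlations(rates, traits)

    def test_spearman_available(self, rng):
        rates = self._rates(8, rng)
        traits = sd.simulate_traits(len(rates), 0.0, None, rng)
        out = bs.trait_correlations(rates, traits, method="spearman")
        assert len(out) == 20
        with pytest.raises(ValueError):
            bs.trait_correlations(rates, traits, method="kendall")
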